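"""Core data containers shared across the analysis stages.

Arrays follow the (trials, channels_or_sources, samples) convention
throughout; metadata (subject, condition, window) rides along as plain
attributes so every downstream table can be traced back to its origin.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Brodmann areas conventionally used for whole-cortex parcellations
#: (42 per hemisphere; areas 12, 14-16, 26 and >47 are not distinguished
#: cytoarchitectonically on the human cortical surface).
BRODMANN_AREAS = (
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 13, 17, 18, 19, 20, 21, 22, 23,
    24, 25, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39, 40, 41,
    42, 43, 44, 45, 46, 47,
)


def default_roi_labels(n_rois: int = 84) -> list[str]:
    """Labels like ``"9L"``/``"44R"`` for the 84-area parcellation.

    Left-hemisphere areas come first.  For ROI counts other than 84 a
    generic ``"S<i>"`` scheme is used.
    """
    if n_rois == 2 * len(BRODMANN_AREAS):
        return [f"{ba}L" for ba in BRODMANN_AREAS] + [f"{ba}R" for ba in BRODMANN_AREAS]
    return [f"S{i}" for i in range(n_rois)]


@dataclass
class LeadField:
    """Channels x sources gain matrix with average-reference-centered columns."""

    gain: np.ndarray
    roi_labels: list[str]
    electrode_positions: np.ndarray | None = None
    source_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("leadfield gain must be 2-D (channels x sources)")
        if self.gain.shape[1] != len(self.roi_labels):
            raise ValueError("number of ROI labels must match gain columns")
        norms = np.linalg.norm(self.gain, axis=0)
        if np.any(norms == 0):
            raise ValueError("leadfield contains an all-zero column")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class EpochSet:
    """Epoched multichannel data: ``data`` is (trials, channels, samples)."""

    data: np.ndarray
    sampling_rate: float
    window_tag: str  # "baseline" | "sdp"
    channel_labels: Sequence[str] | None = None
    subject: int | None = None
    condition: str | None = None
    band_state: str = "raw"  # "raw" | "filtered"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials, channels, samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, data: np.ndarray, **updates) -> "EpochSet":
        kwargs = dict(
            sampling_rate=self.sampling_rate,
            window_tag=self.window_tag,
            channel_labels=self.channel_labels,
            subject=self.subject,
            condition=self.condition,
            band_state=self.band_state,
        )
        kwargs.update(updates)
        return EpochSet(data=data, **kwargs)


@dataclass
class RawRecording:
    """Continuous multichannel recording with an event list and aux traces."""

    samples: np.ndarray  # channels x time, microvolts
    sampling_rate: float
    channel_labels: Sequence[str] | None = None
    events: pd.DataFrame | None = None  # columns: time_s, label
    aux: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.events is not None and len(self.events) > 1:
            t = np.asarray(self.events["time_s"], dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError("events must be sorted by time")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class CrossSpectra:
    """Trial- and bin-averaged Hermitian cross-spectral matrix for one band."""

    matrix: np.ndarray  # complex, n_rois x n_rois
    band: tuple[float, float]
    n_trials: int
    n_bins: int
    window_tag: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=complex)
        if not np.allclose(self.matrix, self.matrix.conj().T, atol=1e-9):
            raise ValueError("cross-spectral matrix must be Hermitian")


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative (or baseline-normalized) 84x84 connectivity."""

    values: np.ndarray
    band: tuple[float, float]
    normalization: str = "absolute"  # "absolute" | "event_related"
    condition: str | None = None
    window_tag: str | None = None
    roi_labels: list[str] | None = None
    flagged_entries: np.ndarray | None = None  # bool mask of floored baselines

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity must be a square matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("connectivity must be symmetric")
        if self.normalization == "absolute":
            if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-9):
                raise ValueError("absolute connectivity values must lie in [0, 1]")
        if self.roi_labels is None:
            self.roi_labels = default_roi_labels(self.values.shape[0])

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]
    metric: str

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows for n leaves")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("linkage heights must be non-decreasing")

    def to_newick(self) -> str:
        from scipy.cluster.hierarchy import to_tree

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return rec(to_tree(self.linkage)) + ";"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["cluster_a", "cluster_b", "height", "size"]
        )


@dataclass
class NetworkPartition:
    """Assignment of ROIs to K groups, with the dendrogram it came from."""

    labels: np.ndarray  # int group index per ROI, 0..K-1
    K: int
    dendrogram: Dendrogram | None = None
    cut_rule: str = "maxclust"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("partition labels must be a vector")
        if len(np.unique(self.labels)) != self.K:
            raise ValueError("partition must have exactly K non-empty groups")

    def groups(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == g) for g in range(self.K)]


@dataclass
class GroupConnectivityStats:
    """Intra-group and inter-group-pair connectivity sums."""

    intra: dict[int, float]
    inter: dict[tuple[int, int], float]

    def total(self) -> float:
        return sum(self.intra.values()) + sum(self.inter.values())


@dataclass
class PermutationResult:
    """Observed statistics and family-wise corrected p-values."""

    statistic: np.ndarray
    p_corrected: np.ndarray
    n_permutations: int
    scheme: str  # "exhaustive" | "monte_carlo"
    seed: int | None
    alpha: float = 0.05
    stat_name: str = "t"
    flags: dict | None = None
    variable_names: list[str] | None = None

    def significant(self) -> np.ndarray:
        return np.asarray(self.p_corrected) < self.alpha

    def to_frame(self) -> pd.DataFrame:
        names = self.variable_names or [
            f"v{i}" for i in range(len(np.atleast_1d(self.statistic)))
        ]
        return pd.DataFrame(
            {
                "variable": names,
                self.stat_name: np.atleast_1d(self.statistic),
                "p_corrected": np.atleast_1d(self.p_corrected),
            }
        )
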