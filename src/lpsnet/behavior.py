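"""Response-time extraction from the EMG channel and the RT <->
event-related clustering-coefficient correlation analysis.

The verbal-response onset is read off the facial EMG trace: band-pass
1-25 Hz, rectify, smooth, then detect the first sustained excursion
above a baseline-derived threshold.  Onset criterion: envelope exceeds
``baseline mean + k * baseline SD`` continuously for at least
``min_duration`` (defaults k=3, 100 ms).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import PermutationResult
from .preprocessing import bandpass_filter
from .stats import max_stat_spearman

__all__ = [
    "emg_envelope",
    "detect_response_onset",
    "minmax_normalize",
    "rt_correlation_analysis",
]


def emg_envelope(
    emg: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (1.0, 25.0),
    smooth_s: float = 0.05,
) -> np.ndarray:
    """Band-pass (1-25 Hz), rectify, and smooth with a 50 ms moving average.

    The filter and the moving average are applied causally (forward
    only): a zero-phase or centered variant would smear burst energy
    backwards in time and bias onset detection early.
    """
    from scipy import signal as sps

    x = np.asarray(emg, dtype=float)
    if x.size == 0:
        raise ValueError("empty EMG trace")
    sos = sps.butter(4, [band[0], band[1]], btype="bandpass", fs=sampling_rate, output="sos")
    rect = np.abs(sps.sosfilt(sos, x))
    width = max(int(round(smooth_s * sampling_rate)), 1)
    kernel = np.ones(width) / width
    return sps.lfilter(kernel, [1.0], rect)


def detect_response_onset(
    envelope: np.ndarray,
    sampling_rate: float,
    baseline_window: tuple[float, float],
    search_start: float | None = None,
    k: float = 3.0,
    min_duration: float = 0.1,
) -> float | None:
    """First sustained supra-threshold excursion of the envelope.

    Returns the onset time in seconds, or None if the envelope never
    exceeds ``baseline mean + k * SD`` for ``min_duration`` continuously
    after ``search_start`` (default: the end of the baseline window).
    """
    env = np.asarray(envelope, dtype=float)
    b0, b1 = baseline_window
    i0, i1 = int(round(b0 * sampling_rate)), int(round(b1 * sampling_rate))
    if i1 <= i0 or i0 < 0 or i1 > env.size:
        raise ValueError("invalid baseline window")
    if search_start is None:
        search_start = b1
    s0 = int(round(search_start * sampling_rate))
    if s0 < i1:
        raise ValueError("baseline window must precede the search window")
    base = env[i0:i1]
    thr = base.mean() + k * base.std()
    above = env >= thr
    need = max(int(round(min_duration * sampling_rate)), 1)
    run = 0
    for idx in range(s0, env.size):
        if above[idx]:
            run += 1
            if run >= need:
                return (idx - need + 1) / sampling_rate
        else:
            run = 0
    return None


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map to [0, 1] across entries; constant input is an error."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize constant values")
    return (v - lo) / (hi - lo)


def rt_correlation_analysis(
    behavior_table: pd.DataFrame,
    event_related_clustering: np.ndarray,
    condition: str,
    subjects: np.ndarray | None = None,
    n_perm: int = 49_999,
    seed: int | None = 0,
    alpha: float = 0.05,
    roi_labels: list[str] | None = None,
) -> PermutationResult:
    """Correlate per-subject mean RT with each ROI's event-related
    clustering coefficient under max-statistic correction.

    ``event_related_clustering`` is subjects x ROIs for the given
    condition; per-subject mean RTs are taken from ``behavior_table``
    (columns subject, condition, response_time).  Both sides are
    min-max normalized across subjects before the rank correlation —
    a monotone rescaling that leaves every Spearman rho unchanged.
    """
    ec = np.atleast_2d(np.asarray(event_related_clustering, dtype=float))
    sel = behavior_table[behavior_table["condition"] == condition]
    mean_rt = sel.groupby("subject", sort=True)["response_time"].mean()
    if subjects is None:
        subjects = mean_rt.index.to_numpy()
    rt = mean_rt.loc[list(subjects)].to_numpy(dtype=float)
    if rt.size < 4:
        raise ValueError("correlation analysis needs at least 4 subjects")
    if ec.shape[0] != rt.size:
        raise ValueError("clustering-coefficient rows must match subjects")
    rt_n = minmax_normalize(rt)
    spans = ec.max(axis=0) - ec.min(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ec_n = np.where(
            spans[None, :] > 0,
            (ec - ec.min(axis=0, keepdims=True)) / np.where(spans[None, :] > 0, spans[None, :], 1.0),
            ec,
        )
    return max_stat_spearman(
        rt_n, ec_n, n_perm=n_perm, seed=seed, alpha=alpha, variable_names=roi_labels
    )
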