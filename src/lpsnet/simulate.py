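"""Ground-truthed synthetic study generator.

Emulates the structure of an event-related EEG connectivity study:
subjects x conditions x trials, each trial carrying a 2-s pre-stimulus
baseline window and a 2-s stimulus-delivery (SDP) window, with

* 84 cortical ROI source time series organized in four coupled groups.
  Each group owns a latent narrowband (upper-alpha) process; every node
  reproduces its group latent at a node-specific positive lag, on top of
  a 1/f background.  Because the coupling is strictly lagged, a
  lagged-phase-synchronization estimator can see it while remaining
  blind to instantaneous volume conduction.
* Condition- and window-dependent modulation of within-group and
  between-group coupling gains (the planted "event-related" contrast).
* Instantaneous mixing to scalp channels through a toy spherical
  leadfield, plus optional blink (EOG) and muscle-burst (EMG) artifacts
  with dedicated reference channels.
* Behavioral response times linked to one target ROI's per-subject
  network engagement, and a synthetic rectified-EMG trace whose burst
  onset encodes the response time.

All latent signals are synthesized in the frequency domain: the group
latents occupy exactly the configured band, lags are applied as exact
``exp(-2*pi*i*f*tau)`` phase factors, and the background has a 1/f power
spectrum.  This makes the expected coherency between any two nodes
available in closed form (:func:`analytic_pair_coherency`), which the
estimator tests use as an independent oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numpy.fft import irfft, rfftfreq
from scipy.special import hyp2f1

from .containers import LeadField, default_roi_labels

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_leadfield",
    "simulate_source_epochs",
    "project_to_channels",
    "inject_artifacts",
    "simulate_behavior",
    "analytic_pair_coherency",
    "analytic_pair_lps",
]

DEFAULT_CONDITIONS = ("WE-IL", "WE-IT", "NE-IL", "NE-IT")
WINDOWS = ("baseline", "sdp")


def _default_partition(n_rois: int, n_groups: int = 4) -> tuple[tuple[int, ...], ...]:
    bounds = np.linspace(0, n_rois, n_groups + 1).astype(int)
    return tuple(
        tuple(range(bounds[g], bounds[g + 1])) for g in range(n_groups)
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic study.

    The defaults mirror the emulated study design: 16 subjects, four
    conditions (two tasks x instructed lying / truth-telling), 25 trials
    per condition, 64 channels at 250 Hz, 84 ROIs in four groups, and an
    upper-alpha analysis band of 10-12 Hz.  The planted effect raises the
    between-group coupling of ``planted_pairs`` in the SDP window of the
    instructed-lying conditions by ``planted_scale``.
    """

    n_subjects: int = 16
    n_trials: int = 25
    n_channels: int = 64
    n_rois: int = 84
    sampling_rate: float = 250.0
    epoch_duration: float = 2.0
    band: tuple[float, float] = (10.0, 12.0)
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    partition: tuple[tuple[int, ...], ...] | None = None
    lag_range: tuple[float, float] = (0.008, 0.040)  # seconds, strictly > 0
    coupling_within: float = 1.0
    coupling_between: float = 0.25
    amplitude_jitter: float = 0.2
    #: SDP between-group coupling multiplier for the planted group pairs,
    #: applied in conditions whose name contains ``planted_condition_tag``.
    #: Groups 0 and 2 occupy diametrically opposite cortical patches in
    #: the default leadfield, so the planted contrast is not confounded
    #: with inverse crosstalk between neighboring groups.
    planted_pairs: tuple[tuple[int, int], ...] = ((0, 2),)
    planted_scale: float = 2.5
    planted_condition_tag: str = "IL"
    #: extra per-(condition, group) SDP within-group multipliers
    sdp_within_scale: Mapping[tuple[str, int], float] = field(default_factory=dict)
    snr_db: float = 10.0
    #: in-band SNR of the RT-target ROI at engagement 1.  Kept near 0 dB so
    #: that per-subject engagement (which scales the target's band-limited
    #: signal against a fixed noise floor) moves its phase coupling over a
    #: usable range instead of saturating.
    target_snr_db: float = 0.0
    #: blink and EMG-burst rates, events per second
    artifact_rates: tuple[float, float] = (0.25, 0.1)
    #: (target ROI index, RT slope s per unit engagement, RT noise SD s).
    #: ROI 80 is area 44R (right inferior frontal gyrus) in the default
    #: 84-area labelling.  The defaults plant an RT <-> engagement
    #: correlation of ~0.98; combined with the engagement -> estimated
    #: event-related clustering coefficient chain (~0.9 at 25 trials)
    #: this leaves a planted correlation of roughly 0.8-0.85 between the
    #: response time and the target ROI's measured coefficient.
    rt_link: tuple[int, float, float] = (80, 1.0, 0.05)
    #: exponent of the engagement -> band-signal-amplitude mapping for the
    #: target hub (supralinear: small excitability differences produce
    #: larger power differences)
    engagement_exponent: float = 3.0
    rt_intercept: float = 0.8
    engagement_sd: float = 0.35
    #: optional per-subject multiplicative spread of ALL node amplitudes
    #: in the SDP window (noise floors stay fixed), emulating global
    #: subject differences in event-related band-power modulation.  Off by
    #: default: it is deliberately absent from the planted-link conditions,
    #: where it would act as correlated noise on every network metric.
    sdp_modulation_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1 or self.n_rois < 2:
            raise ValueError("non-positive study dimensions")
        if self.n_channels < 2:
            raise ValueError("need at least two channels")
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < low < high")
        if self.sampling_rate <= 2 * hi:
            raise ValueError("sampling rate must exceed twice the band's high edge")
        if not (0 < self.lag_range[0] <= self.lag_range[1]):
            raise ValueError("coupling lags must be strictly positive")
        part = self.partition
        if part is None:
            object.__setattr__(self, "partition", _default_partition(self.n_rois))
            part = self.partition
        flat = [i for g in part for i in g]
        if sorted(flat) != list(range(self.n_rois)):
            raise ValueError("partition sets must be disjoint and cover all ROIs")
        if not (0 <= self.rt_link[0] < self.n_rois):
            raise ValueError("rt_link target ROI out of range")

    @property
    def n_groups(self) -> int:
        return len(self.partition)

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.sampling_rate))

    @property
    def roi_labels(self) -> list[str]:
        return default_roi_labels(self.n_rois)


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery oracles."""

    partition: tuple[tuple[int, ...], ...]
    node_group: np.ndarray  # group index per ROI
    amplitudes: np.ndarray  # per-node latent gain a_i
    node_lags: np.ndarray  # per-node lag tau_i, seconds
    group_lags: np.ndarray  # per group-pair lag, seconds (symmetric)
    target_lags: np.ndarray  # RT-target hub: one lag per group latent, seconds
    #: between-group latent mixing gain per (condition, window): G x G, zero diag
    between_gain: dict[tuple[str, str], np.ndarray]
    #: within-group amplitude scale per (condition, window): length G
    within_scale: dict[tuple[str, str], np.ndarray]
    engagement: np.ndarray  # per-subject latent engagement of the target ROI
    sdp_modulation: np.ndarray  # per-subject global SDP amplitude factor
    conditions: tuple[str, ...]
    target_roi: int
    planted_pairs: tuple[tuple[int, int], ...]
    rts: pd.DataFrame | None = None

    def group_coupling_matrix(self, condition: str, window: str) -> np.ndarray:
        """Symmetric G x G matrix of latent mixing gains (zero diagonal)."""
        return self.between_gain[(condition, window)].copy()

    def mean_between_coupling(self, g: int, h: int, condition: str, window: str) -> float:
        return float(self.between_gain[(condition, window)][g, h])


def make_leadfield(
    n_channels: int = 64,
    n_sources: int = 84,
    spread: float = 0.25,
    seed: int = 0,
    n_clusters: int = 4,
) -> LeadField:
    """Toy spherical leadfield with Gaussian-topography columns.

    Electrodes sit on a fixed Fibonacci layout covering the upper unit
    hemisphere.  Sources are placed at seeded random positions on the
    upper portion of the unit sphere (cortex sits under the electrode
    cap), organized into ``n_clusters`` spatially compact, well-separated
    clusters of consecutive column indices: functional sub-networks are
    distinct anatomical systems, and the generator's default ROI groups
    are index blocks, so index-adjacent sources belong together
    spatially.  Pass ``n_clusters=1`` for an unstructured layout.
    Column ``j`` is ``exp(-||e_c - s_j||^2 / (2 spread^2))``, centered to
    zero mean across channels so that the forward model is consistent
    with average-reference data.
    """
    if n_channels < 2 or n_sources < 1:
        raise ValueError("non-positive leadfield dimensions")
    if spread <= 0:
        raise ValueError("spread must be positive")
    elec = _fibonacci_hemisphere(n_channels)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(901,)))
    # cluster centers: evenly spaced in azimuth at mid elevation
    az = 2 * np.pi * np.arange(n_clusters) / n_clusters + np.pi / n_clusters
    centers = np.column_stack(
        [np.cos(az) * np.cos(0.7), np.sin(az) * np.cos(0.7), np.full(n_clusters, np.sin(0.7))]
    )
    sizes = np.diff(np.linspace(0, n_sources, n_clusters + 1).astype(int))
    for _ in range(100):
        chunks = []
        for c, size in zip(centers, sizes):
            pts = c[None, :] + 0.35 * rng.standard_normal((size, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts[:, 2] = np.abs(pts[:, 2])  # keep sources under the cap
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            chunks.append(pts[np.argsort(-pts[:, 2])])
        src = np.vstack(chunks)
        d2 = ((elec[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
        gain = np.exp(-d2 / (2.0 * spread**2))
        gain = gain - gain.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(gain, axis=0)
        if np.all(norms > 1e-10):
            gain = gain / norms
            break
    else:  # pragma: no cover - essentially unreachable
        raise RuntimeError("could not generate a non-degenerate leadfield")
    return LeadField(
        gain=gain,
        roi_labels=default_roi_labels(n_sources),
        electrode_positions=elec,
        source_positions=src,
    )


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform electrode layout on the upper hemisphere."""
    k = np.arange(n)
    z = k / max(n - 1, 1)  # 0 .. 1
    r = np.sqrt(np.clip(1 - z**2, 0, 1))
    golden = np.pi * (3 - np.sqrt(5))
    theta = golden * k
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # sort front (positive y) to back so "frontal" channels come first
    return pts[np.argsort(-pts[:, 1])]


# ---------------------------------------------------------------------------
# source simulation
# ---------------------------------------------------------------------------

def _structural_truth(config: SimConfig) -> GroundTruth:
    """Draw the per-study structural randomness (fixed across epochs)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    G = config.n_groups
    node_group = np.empty(config.n_rois, dtype=int)
    for g, members in enumerate(config.partition):
        node_group[list(members)] = g
    amplitudes = config.coupling_within * (
        1.0 + config.amplitude_jitter * (rng.random(config.n_rois) - 0.5) * 2
    )
    lo, hi = config.lag_range
    node_lags = rng.uniform(lo, hi, size=config.n_rois)
    # between-group (driver->receiver) lag: a quarter cycle at band
    # center, so the directed coupling sits in the quadrature component
    # the lagged-phase measure sees regardless of the node-lag draws
    quarter_cycle = 1.0 / (4.0 * 0.5 * (config.band[0] + config.band[1]))
    group_lags = np.full((G, G), np.clip(quarter_cycle, lo, hi))
    np.fill_diagonal(group_lags, 0.0)
    # hub lags offset by a quarter cycle at band center from the typical
    # node lag, so the hub's coupling sits mostly in the quadrature
    # (lag-visible) component
    quarter = 1.0 / (4.0 * 0.5 * (config.band[0] + config.band[1]))
    target_lags = 0.5 * (lo + hi) + quarter + rng.uniform(-0.25, 0.25, size=G) * (hi - lo)

    between = {}
    within = {}
    for cond in config.conditions:
        base_B = np.full((G, G), config.coupling_between, dtype=float)
        np.fill_diagonal(base_B, 0.0)
        sdp_B = base_B.copy()
        if config.planted_condition_tag in cond:
            for g, h in config.planted_pairs:
                sdp_B[g, h] *= config.planted_scale
                sdp_B[h, g] *= config.planted_scale
        between[(cond, "baseline")] = base_B
        between[(cond, "sdp")] = sdp_B
        w_base = np.ones(G)
        w_sdp = np.ones(G)
        for (c, g), s in config.sdp_within_scale.items():
            if c == cond:
                w_sdp[g] *= s
        within[(cond, "baseline")] = w_base
        within[(cond, "sdp")] = w_sdp

    engagement = 1.0 + config.engagement_sd * rng.standard_normal(config.n_subjects)
    engagement = np.clip(engagement, 0.2, None)
    sdp_modulation = 1.0 + config.sdp_modulation_sd * rng.standard_normal(
        config.n_subjects
    )
    sdp_modulation = np.clip(sdp_modulation, 0.3, None)

    return GroundTruth(
        partition=config.partition,
        node_group=node_group,
        amplitudes=amplitudes,
        node_lags=node_lags,
        group_lags=group_lags,
        target_lags=target_lags,
        between_gain=between,
        within_scale=within,
        engagement=engagement,
        sdp_modulation=sdp_modulation,
        conditions=config.conditions,
        target_roi=config.rt_link[0],
        planted_pairs=config.planted_pairs,
    )


def _band_bins(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    freqs = rfftfreq(config.n_samples, 1.0 / config.sampling_rate)
    lo, hi = config.band
    idx = np.flatnonzero((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))
    if idx.size == 0:
        raise ValueError("band contains no Fourier bins at this epoch length")
    return idx, freqs


def _node_coefficients(
    config: SimConfig,
    gt: GroundTruth,
    condition: str,
    window: str,
    subject: int | None,
    freqs_band: np.ndarray,
) -> np.ndarray:
    """Complex mixing coefficients c[i, g, k]: node i's weight on latent g at bin k."""
    G = config.n_groups
    B = gt.between_gain[(condition, window)]
    wscale = gt.within_scale[(condition, window)]
    omega = 2j * np.pi * freqs_band  # (k,)
    # Directed latent-level coupling: the lower-indexed group drives the
    # higher-indexed one, Y_h = Z_h + B[g,h] e^{-i w tau_gh} Z_g for g < h.
    # A symmetric bidirectional mixture with a shared lag would contribute
    # 2 B cos(w tau) to the cross-spectrum - purely real, hence invisible
    # to a lagged-phase measure; the driver->receiver asymmetry keeps the
    # planted coupling in the imaginary part where LPS can see it.
    latent_mix = np.zeros((G, G, freqs_band.size), dtype=complex)
    for g in range(G):
        latent_mix[g, g] = 1.0
        for h in range(g):
            if B[h, g] != 0:
                latent_mix[g, h] = B[h, g] * np.exp(-omega * gt.group_lags[h, g])
        # unit-power normalization: raising the between-group gain must
        # not inflate the receiver group's own signal power (which would
        # raise its INTRA-group coherence as a side effect)
        norm = np.sqrt((np.abs(latent_mix[g]) ** 2).sum(axis=0))
        latent_mix[g] /= norm
    amps = gt.amplitudes.copy()
    if window == "sdp" and subject is not None:
        amps = amps * gt.sdp_modulation[subject]
        amps[gt.target_roi] *= (
            gt.engagement[subject] ** config.engagement_exponent
        )
    coeff = np.empty((config.n_rois, G, freqs_band.size), dtype=complex)
    for i in range(config.n_rois):
        g = gt.node_group[i]
        node_phase = np.exp(-omega * gt.node_lags[i])
        coeff[i] = amps[i] * wscale[g] * node_phase * latent_mix[g]
    # The RT-target ROI is a hub: it carries every group's latent (with a
    # per-group lag), not only its own group's, so its engagement
    # modulates coupling to the whole network - the quantity a clustering
    # coefficient summarizes.  Its own group keeps the dominant share so
    # the node still clusters with its anatomical group.
    t = gt.target_roi
    own = gt.node_group[t]
    w_own = 0.75
    w_cross = np.sqrt((1.0 - w_own**2) / max(G - 1, 1))
    hub = np.zeros((G, freqs_band.size), dtype=complex)
    for h in range(G):
        w = w_own if h == own else w_cross
        hub[h] = w * np.exp(-omega * gt.target_lags[h])
    coeff[t] = amps[t] * wscale[own] * hub
    return coeff


def _noise_scale(
    config: SimConfig, coeff_ref: np.ndarray, freqs: np.ndarray, band_idx: np.ndarray
) -> np.ndarray:
    """Per-node 1/f noise normalization A_i fixing the in-band SNR.

    Computed from the reference (engagement = 1) signal coefficients, so
    a subject's engagement changes the target ROI's signal against a
    *fixed* noise floor — engagement must move the effective SNR, and
    with it the measurable phase coupling, to be recoverable at all.
    """
    sig_band_power = (np.abs(coeff_ref) ** 2).sum(axis=1).sum(axis=1)  # per node
    inv_f_band = (1.0 / freqs[band_idx]).sum()
    snr = np.full(config.n_rois, config.snr_db)
    snr[config.rt_link[0]] = config.target_snr_db
    return sig_band_power * 10.0 ** (-snr / 10.0) / inv_f_band


def simulate_source_epochs(
    config: SimConfig,
    subjects: Iterable[int] | None = None,
    conditions: Iterable[str] | None = None,
) -> tuple[dict[tuple[int, str, str], np.ndarray], GroundTruth]:
    """Generate per-trial ROI source arrays for every requested cell.

    Returns a dict keyed by ``(subject, condition, window)`` whose values
    are ``(n_trials, n_rois, n_samples)`` arrays, plus the
    :class:`GroundTruth` describing what was planted.  Deterministic for
    a given config (every epoch's noise stream is addressed by subject,
    condition, window and trial indices).
    """
    gt = _structural_truth(config)
    band_idx, freqs = _band_bins(config)
    f_band = freqs[band_idx]
    n = config.n_samples
    n_bins_total = freqs.size
    pos_idx = np.arange(1, n_bins_total)  # all nonzero-frequency bins
    inv_f = 1.0 / freqs[pos_idx]

    subjects = list(range(config.n_subjects)) if subjects is None else list(subjects)
    conditions = list(config.conditions) if conditions is None else list(conditions)

    out: dict[tuple[int, str, str], np.ndarray] = {}
    G = config.n_groups
    for s in subjects:
        for cond in conditions:
            c_idx = config.conditions.index(cond)
            for w_idx, window in enumerate(WINDOWS):
                coeff = _node_coefficients(config, gt, cond, window, s, f_band)
                coeff_ref = _node_coefficients(config, gt, cond, window, None, f_band)
                A = _noise_scale(config, coeff_ref, freqs, band_idx)
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        config.seed, spawn_key=(1, s, c_idx, w_idx)
                    )
                )
                T = config.n_trials
                # group latents: (T, G, n_band_bins), unit power per bin
                Z = (
                    rng.standard_normal((T, G, f_band.size))
                    + 1j * rng.standard_normal((T, G, f_band.size))
                ) / np.sqrt(2.0)
                sig = np.einsum("igk,tgk->tik", coeff, Z)
                spec = np.zeros((T, config.n_rois, n_bins_total), dtype=complex)
                spec[:, :, band_idx] = sig
                noise = (
                    rng.standard_normal((T, config.n_rois, pos_idx.size))
                    + 1j * rng.standard_normal((T, config.n_rois, pos_idx.size))
                ) / np.sqrt(2.0)
                spec[:, :, pos_idx] += noise * np.sqrt(
                    A[None, :, None] * inv_f[None, None, :]
                )
                out[(s, cond, window)] = irfft(spec, n=n, axis=2)
    return out, gt


def project_to_channels(
    source_epochs: np.ndarray,
    leadfield: LeadField,
    sensor_noise_db: float = 20.0,
    seed: int = 0,
) -> np.ndarray:
    """Instantaneous forward projection plus white sensor noise.

    ``sensor_noise_db`` is the per-channel signal-to-sensor-noise ratio in
    dB; the mixing itself is strictly zero-lag (volume conduction).
    """
    x = np.asarray(source_epochs, dtype=float)
    if x.ndim != 3 or x.shape[1] != leadfield.n_sources:
        raise ValueError("source epochs must be (trials, n_sources, samples)")
    chans = np.tensordot(leadfield.gain, x, axes=([1], [1])).transpose(1, 0, 2)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    sigma = chans.std() * 10.0 ** (-sensor_noise_db / 20.0)
    return chans + sigma * rng.standard_normal(chans.shape)


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def _blink_waveform(fs: float, rng: np.random.Generator) -> np.ndarray:
    """Single blink transient: ~300 ms raised-cosine bump (< 4 Hz energy)."""
    dur = rng.uniform(0.25, 0.40)
    t = np.arange(int(dur * fs)) / fs
    return np.sin(np.pi * t / dur) ** 2


def _emg_burst(fs: float, rng: np.random.Generator) -> np.ndarray:
    """Broadband burst with near-zero lag-1 autocorrelation."""
    dur = rng.uniform(0.2, 0.5)
    n = int(dur * fs)
    burst = rng.standard_normal(n)
    window = np.hanning(n)
    return burst * window


def inject_artifacts(
    clean_eeg: np.ndarray,
    sampling_rate: float,
    blink_rate: float = 0.25,
    emg_rate: float = 0.1,
    seed: int = 0,
    electrode_positions: np.ndarray | None = None,
    blink_gain: float = 8.0,
    emg_gain: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Add blink and muscle-burst artifacts to channel epochs.

    Returns ``(contaminated, eog_channel, emg_channel)`` where the aux
    channels are (trials, samples) reference traces containing the pure
    artifact waveforms plus 1% measurement noise.  With both rates zero
    the EEG is returned unchanged (bit-identical).
    """
    x = np.asarray(clean_eeg, dtype=float)
    if x.ndim != 3:
        raise ValueError("clean EEG must be (trials, channels, samples)")
    T, C, N = x.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    eog = np.zeros((T, N))
    emg = np.zeros((T, N))
    if blink_rate == 0 and emg_rate == 0:
        ref_noise = 1e-12 * rng.standard_normal((2, T, N))
        return x.copy(), eog + ref_noise[0], emg + ref_noise[1]

    scale = x.std()
    dirty = x.copy()
    dur_s = N / sampling_rate

    if electrode_positions is not None:
        front = np.array([0.0, 0.9, 0.43])
        d2 = ((electrode_positions - front) ** 2).sum(axis=1)
        blink_topo = np.exp(-d2 / 0.5)
    else:
        blink_topo = np.exp(-np.arange(C) / (C / 6.0))
    blink_topo = blink_topo / blink_topo.max()

    for t in range(T):
        n_blinks = rng.poisson(blink_rate * dur_s)
        for _ in range(n_blinks):
            w = _blink_waveform(sampling_rate, rng) * blink_gain * scale
            start = rng.integers(0, max(N - len(w), 1))
            sl = slice(start, start + len(w))
            w = w[: N - start]
            dirty[t, :, sl] += blink_topo[:, None] * w[None, :]
            eog[t, sl] += w
        n_bursts = rng.poisson(emg_rate * dur_s)
        for _ in range(n_bursts):
            w = _emg_burst(sampling_rate, rng) * emg_gain * scale
            start = rng.integers(0, max(N - len(w), 1))
            sl = slice(start, start + len(w))
            w = w[: N - start]
            center = rng.integers(0, C)
            if electrode_positions is not None:
                d2 = ((electrode_positions - electrode_positions[center]) ** 2).sum(axis=1)
                topo = np.exp(-d2 / 0.15)
            else:
                topo = np.exp(-np.abs(np.arange(C) - center) / 3.0)
            dirty[t, :, sl] += topo[:, None] * w[None, :]
            emg[t, sl] += w
    eog += 0.01 * scale * rng.standard_normal((T, N))
    emg += 0.01 * scale * rng.standard_normal((T, N))
    return dirty, eog, emg


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    ground_truth: GroundTruth,
    config: SimConfig,
    stimulus_offset_s: float = 2.5,
    trial_jitter_sd: float = 0.05,
) -> tuple[pd.DataFrame, dict[tuple[int, str], dict]]:
    """Response times tied to the target ROI's planted engagement.

    Per subject and condition the mean response time is
    ``intercept + slope * (engagement - 1) + noise``; per-trial times add
    small jitter.  Also returns, per (subject, condition), a synthetic
    EMG trace whose broadband burst starts ``RT`` seconds after the
    stimulus offset, for exercising the response-onset detector.
    """
    target, slope, noise_sd = config.rt_link
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(4,)))
    rows = []
    traces: dict[tuple[int, str], dict] = {}
    fs = config.sampling_rate
    for s in range(config.n_subjects):
        for cond in config.conditions:
            e = ground_truth.engagement[s]
            for _ in range(100):
                rt = config.rt_intercept + slope * (e - 1.0) + noise_sd * rng.standard_normal()
                if rt > 0:
                    break
            else:
                raise RuntimeError(
                    "could not draw a positive response time in 100 attempts"
                )
            for tr in range(config.n_trials):
                jit = trial_jitter_sd * rng.standard_normal()
                rows.append((s, cond, tr, max(rt + jit, 0.05)))
            # synthetic rectified-EMG trace: quiet until offset + RT, then burst
            total = stimulus_offset_s + rt + 1.0
            n = int(round(total * fs))
            trace = 0.05 * rng.standard_normal(n)
            onset = int(round((stimulus_offset_s + rt) * fs))
            burst_len = min(int(0.4 * fs), n - onset)
            trace[onset : onset + burst_len] += rng.standard_normal(burst_len)
            traces[(s, cond)] = {
                "trace": trace,
                "stimulus_offset_s": stimulus_offset_s,
                "true_rt": rt,
            }
    table = pd.DataFrame(rows, columns=["subject", "condition", "trial", "response_time"])
    ground_truth.rts = (
        table.groupby(["subject", "condition"], sort=False)["response_time"]
        .mean()
        .reset_index()
    )
    return table, traces


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------

def gaussian_phase_coherency(gamma: np.ndarray) -> np.ndarray:
    """E[e^{i(phi1-phi2)}] for jointly circular-Gaussian spectra.

    For complex Gaussian coefficient pairs with coherency ``gamma`` the
    expected phase-only cross term is
    ``(pi/4) * gamma * 2F1(1/2, 1/2; 2; |gamma|^2)``.
    """
    gamma = np.asarray(gamma, dtype=complex)
    mod2 = np.clip(np.abs(gamma) ** 2, 0.0, 1.0)
    return (np.pi / 4.0) * gamma * hyp2f1(0.5, 0.5, 2.0, mod2)


def analytic_pair_coherency(
    config: SimConfig,
    gt: GroundTruth,
    i: int,
    j: int,
    condition: str,
    window: str = "sdp",
    subject: int | None = None,
) -> np.ndarray:
    """True coherency gamma(f) between nodes i and j at each band bin."""
    band_idx, freqs = _band_bins(config)
    f_band = freqs[band_idx]
    coeff = _node_coefficients(config, gt, condition, window, subject, f_band)
    coeff_ref = _node_coefficients(config, gt, condition, window, None, f_band)
    A = _noise_scale(config, coeff_ref, freqs, band_idx)
    s_ij = (coeff[i] * coeff[j].conj()).sum(axis=0)
    s_ii = (np.abs(coeff[i]) ** 2).sum(axis=0) + A[i] / f_band
    s_jj = (np.abs(coeff[j]) ** 2).sum(axis=0) + A[j] / f_band
    return s_ij / np.sqrt(s_ii * s_jj)


def analytic_pair_lps(
    config: SimConfig,
    gt: GroundTruth,
    i: int,
    j: int,
    condition: str,
    window: str = "sdp",
    subject: int | None = None,
) -> float:
    """Large-sample value of the phase-only LPS estimator for one pair.

    Mirrors the estimator exactly: expected phase-only cross term per
    band bin, averaged across bins, then the lagged-phase formula
    ``Im(rho)^2 / (1 - Re(rho)^2)``.
    """
    gamma = analytic_pair_coherency(config, gt, i, j, condition, window, subject)
    rho = gaussian_phase_coherency(gamma).mean()
    denom = 1.0 - rho.real**2
    if denom <= 1e-12:
        return 0.0
    return float(rho.imag**2 / denom)
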