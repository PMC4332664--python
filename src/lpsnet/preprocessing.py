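"""EEG cleaning chain: band-pass filtering, common-average referencing,
SOBI-based ocular artifact removal, BSS-CCA muscle artifact removal, and
epoch extraction.

Both blind-source-separation steps can run per trial (the default, to
track slow nonstationarity of artifact topographies) or on the trial
concatenation (statistically stronger when topographies are stable).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import EpochSet, RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "bandpass_filter",
    "rereference_common_average",
    "sobi_decompose",
    "remove_eog_components",
    "bsscca_remove_emg",
    "extract_epochs",
    "reject_noisy_trials",
]


def bandpass_filter(
    data: np.ndarray,
    low_hz: float,
    high_hz: float,
    sampling_rate: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass applied along the last axis.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    attenuation and cancels phase distortion, which matters downstream:
    a phase-shifting filter would corrupt lagged-phase estimates.
    """
    nyq = sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyq})"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def rereference_common_average(epochs: EpochSet | np.ndarray) -> EpochSet | np.ndarray:
    """Subtract the instantaneous mean across channels (idempotent)."""
    arr = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs, dtype=float)
    ch_axis = arr.ndim - 2
    if arr.shape[ch_axis] < 2:
        raise ValueError("common-average reference needs at least two channels")
    out = arr - arr.mean(axis=ch_axis, keepdims=True)
    if isinstance(epochs, EpochSet):
        return epochs.copy_with(out)
    return out


# ---------------------------------------------------------------------------
# SOBI
# ---------------------------------------------------------------------------

def _lagged_covariances(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Symmetrized time-lagged covariance matrices of channels x samples data."""
    n = x.shape[1]
    mats = np.empty((lags.size, x.shape[0], x.shape[0]))
    for k, lag in enumerate(lags):
        c = x[:, : n - lag] @ x[:, lag:].T / (n - lag)
        mats[k] = 0.5 * (c + c.T)
    return mats


def joint_diagonalize(
    mats: np.ndarray, tol: float = 1e-8, max_sweeps: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Approximate joint diagonalization of symmetric matrices by Givens sweeps.

    Jacobi-like iteration: for each index pair the rotation angle
    ``theta = atan2(y, x + sqrt(x^2 + y^2)) / 2`` (with ``x, y`` from the
    pair's 2x2 sub-blocks accumulated over all matrices) minimizes the
    off-diagonal energy.  Stops when no rotation in a sweep exceeds
    ``tol``.  Returns (orthogonal V, rotated matrices) with
    ``V.T @ M @ V`` approximately diagonal.
    """
    M = np.array(mats, dtype=float, copy=True)
    if M.ndim == 2:
        M = M[None]
    _, d, _ = M.shape
    V = np.eye(d)
    for _ in range(max_sweeps):
        biggest = 0.0
        for p in range(d - 1):
            for q in range(p + 1, d):
                # 2x2 criterion matrix over h_k = (Mpp - Mqq, 2 Mpq)
                a = M[:, p, p] - M[:, q, q]
                b = 2.0 * M[:, p, q]
                gx = np.sum(a * a)
                gxy = np.sum(a * b)
                gyy = np.sum(b * b)
                # (a, b) rotates by 2*theta, so the optimal theta is half the
                # principal-eigenvector angle phi of [[gx, gxy], [gxy, gyy]],
                # itself atan2(2 gxy, gx - gyy) / 2
                theta = 0.25 * np.arctan2(2.0 * gxy, gx - gyy)
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) <= tol:
                    continue
                biggest = max(biggest, abs(s))
                rot_p = c * M[:, :, p] + s * M[:, :, q]
                rot_q = -s * M[:, :, p] + c * M[:, :, q]
                M[:, :, p], M[:, :, q] = rot_p, rot_q
                rot_p = c * M[:, p, :] + s * M[:, q, :]
                rot_q = -s * M[:, p, :] + c * M[:, q, :]
                M[:, p, :], M[:, q, :] = rot_p, rot_q
                vp = c * V[:, p] + s * V[:, q]
                vq = -s * V[:, p] + c * V[:, q]
                V[:, p], V[:, q] = vp, vq
        if biggest <= tol:
            break
    return V, M


def offdiag_energy(mats: np.ndarray) -> float:
    """Sum of squared off-diagonal entries — the joint-diagonalization objective."""
    M = np.asarray(mats)
    if M.ndim == 2:
        M = M[None]
    mask = ~np.eye(M.shape[1], dtype=bool)
    return float(np.sum(M[:, mask] ** 2))


def sobi_decompose(
    data: np.ndarray,
    lags: np.ndarray | None = None,
    tol: float = 1e-8,
    rank_rtol: float = 1e-10,
    n_components: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Second-order blind identification of channels x samples data.

    Whitens the data, joint-diagonalizes lagged covariance matrices
    (default lags 1..50 samples, covering alpha-period delays at 250 Hz)
    by iterative Givens rotations, and returns ``(mixing, sources)`` with
    ``data ~ mixing @ sources``.  Deterministic.  If the channel
    covariance is rank deficient the dimension is reduced with a warning.

    ``n_components`` restricts the separation to the strongest principal
    subspace.  On short single-trial epochs a full-rank decomposition is
    badly over-parameterized (64 components from 500 samples) and smears
    high-variance artifacts across components; 15-25 components keeps
    blinks compact.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be channels x samples")
    if lags is None:
        lags = np.arange(1, 51)
    lags = np.asarray(lags, dtype=int)
    if lags.size == 0 or np.any(lags < 1):
        raise ValueError("lag set must be nonempty with positive lags")
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    keep = evals > rank_rtol * evals.max()
    if not np.all(keep):
        logger.warning(
            "rank-deficient covariance: reducing %d -> %d dimensions",
            x.shape[0], int(keep.sum()),
        )
    if n_components is not None and keep.sum() > n_components:
        order = np.argsort(evals)[::-1]
        top = order[:n_components]
        keep = np.zeros_like(keep)
        keep[top] = True
    evals, evecs = evals[keep], evecs[:, keep]
    whitener = evecs / np.sqrt(evals)  # channels x rank; W.T @ x is white
    z = whitener.T @ x
    mats = _lagged_covariances(z, lags)
    V, _ = joint_diagonalize(mats, tol=tol)
    sources = V.T @ z
    mixing = np.linalg.pinv(whitener.T) @ V  # channels x rank
    return mixing, sources


def _apply_component_removal(
    trial: np.ndarray, mixing: np.ndarray, sources: np.ndarray, drop: np.ndarray
) -> np.ndarray:
    kept = ~drop
    return mixing[:, kept] @ sources[kept]


def remove_eog_components(
    epochs: EpochSet,
    eog_channel: np.ndarray,
    threshold: float = 0.7,
    lags: np.ndarray | None = None,
    per_trial: bool = True,
    fallback_most_correlated: bool = False,
    n_components: int | None = 20,
) -> EpochSet:
    """Zero SOBI components correlating with the EOG reference.

    Components whose absolute correlation with the EOG trace reaches
    ``threshold`` are removed and the data reconstructed from the rest.
    If none reaches it, the input is returned unchanged (with a log
    notice) unless ``fallback_most_correlated`` forces removal of the
    single best-correlated component.
    """
    eog = np.atleast_2d(np.asarray(eog_channel, dtype=float))
    if eog.shape[-1] != epochs.n_samples:
        raise ValueError("EOG reference must be aligned with the epoch samples")
    if per_trial:
        cleaned = np.empty_like(epochs.data)
        for t in range(epochs.n_trials):
            ref = eog[t] if eog.shape[0] == epochs.n_trials else eog[0]
            cleaned[t] = _remove_eog_single(
                epochs.data[t], ref, threshold, lags, fallback_most_correlated,
                n_components,
            )
        return epochs.copy_with(cleaned)
    T, C, N = epochs.data.shape
    concat = epochs.data.transpose(1, 0, 2).reshape(C, T * N)
    ref = (eog if eog.shape[0] == T else np.repeat(eog, T, axis=0)).reshape(T * N)
    cleaned = _remove_eog_single(
        concat, ref, threshold, lags, fallback_most_correlated, n_components
    )
    return epochs.copy_with(cleaned.reshape(C, T, N).transpose(1, 0, 2))


def _remove_eog_single(
    trial: np.ndarray,
    ref: np.ndarray,
    threshold: float,
    lags: np.ndarray | None,
    fallback: bool,
    n_components: int | None = 20,
) -> np.ndarray:
    mixing, sources = sobi_decompose(trial, lags=lags, n_components=n_components)
    ref_c = ref - ref.mean()
    denom = np.linalg.norm(ref_c)
    if denom == 0:
        return trial
    src_c = sources - sources.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(src_c, axis=1)
    norms[norms == 0] = np.inf
    corr = np.abs(src_c @ ref_c) / (norms * denom)
    drop = corr >= threshold
    if not drop.any():
        if fallback:
            drop[np.argmax(corr)] = True
        else:
            logger.info(
                "no SOBI component reached |r| >= %.2f with EOG (max %.3f); unchanged",
                threshold, corr.max(),
            )
            return trial
    mean = trial.mean(axis=1, keepdims=True)
    return _apply_component_removal(trial, mixing, sources, drop) + mean


def bsscca_remove_emg(
    epochs: EpochSet,
    autocorr_threshold: float = 0.85,
    per_trial: bool = True,
) -> EpochSet:
    """Remove low-autocorrelation (muscle-like) BSS-CCA components.

    Canonical correlation between the data and its one-sample-delayed
    copy yields components ordered by lag-1 autocorrelation; broadband
    EMG bursts land in the low-autocorrelation tail and are discarded.
    Band-limited cortical rhythms (e.g. 10-12 Hz at 250 Hz, lag-1
    autocorrelation ~cos(2*pi*11/250) ~ 0.96) survive a 0.85 threshold.
    """
    if not (0 < autocorr_threshold < 1):
        raise ValueError("autocorrelation threshold must lie in (0, 1)")
    if epochs.n_samples < 2:
        raise ValueError("epochs must have at least 2 samples")
    if per_trial:
        cleaned = np.empty_like(epochs.data)
        for t in range(epochs.n_trials):
            cleaned[t] = _bsscca_single(epochs.data[t], autocorr_threshold)
        return epochs.copy_with(cleaned)
    T, C, N = epochs.data.shape
    concat = epochs.data.transpose(1, 0, 2).reshape(C, T * N)
    cleaned = _bsscca_single(concat, autocorr_threshold)
    return epochs.copy_with(cleaned.reshape(C, T, N).transpose(1, 0, 2))


def _bsscca_single(trial: np.ndarray, threshold: float) -> np.ndarray:
    mean = trial.mean(axis=1, keepdims=True)
    x = trial - mean
    a, b = x[:, :-1], x[:, 1:]

    def whiten(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cov = m @ m.T / m.shape[1]
        evals, evecs = np.linalg.eigh(cov)
        keep = evals > 1e-12 * evals.max()
        return evecs[:, keep] / np.sqrt(evals[keep]), evecs[:, keep] * np.sqrt(evals[keep])

    wa, wa_inv = whiten(a)
    wb, _ = whiten(b)
    cross = (wa.T @ a) @ (wb.T @ b).T / a.shape[1]
    u, svals, _ = np.linalg.svd(cross)
    unmix = u.T @ wa.T  # components x channels, ordered by canonical corr
    sources = unmix @ x
    keep = svals >= threshold
    if keep.all():
        return trial
    recon = np.linalg.pinv(unmix)[:, keep] @ sources[keep]
    return recon + mean


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

@dataclass
class WindowSpec:
    """Analysis windows relative to stimulus onset, in seconds."""

    baseline: tuple[float, float] = (-2.0, 0.0)
    sdp: tuple[float, float] = (0.0, 2.0)


def extract_epochs(
    recording: RawRecording,
    events: pd.DataFrame | None = None,
    window_spec: WindowSpec | None = None,
    event_label: str = "stimulus_on",
) -> tuple[EpochSet, EpochSet, list[dict]]:
    """Cut baseline and SDP epochs around each stimulus-onset event.

    The baseline is the last 2 s of the 3-s fixation (ending at stimulus
    onset) and the SDP window is the first 2 s after onset.  Trials whose
    windows fall outside the recording are dropped and logged; the drop
    log is returned alongside the two epoch sets.
    """
    spec = window_spec or WindowSpec()
    ev = events if events is not None else recording.events
    if ev is None:
        raise ValueError("no events supplied")
    onsets = ev.loc[ev["label"] == event_label, "time_s"].to_numpy(dtype=float)
    fs = recording.sampling_rate
    n_total = recording.samples.shape[1]
    n_win = int(round((spec.baseline[1] - spec.baseline[0]) * fs))
    n_sdp = int(round((spec.sdp[1] - spec.sdp[0]) * fs))
    base_list, sdp_list, dropped = [], [], []
    for k, t0 in enumerate(onsets):
        b0 = int(round((t0 + spec.baseline[0]) * fs))
        s0 = int(round((t0 + spec.sdp[0]) * fs))
        if b0 < 0 or s0 + n_sdp > n_total:
            reason = "window outside recording"
            dropped.append({"trial": k, "onset_s": float(t0), "reason": reason})
            logger.info("dropping trial %d at %.3f s: %s", k, t0, reason)
            continue
        base_list.append(recording.samples[:, b0 : b0 + n_win])
        sdp_list.append(recording.samples[:, s0 : s0 + n_sdp])
    def build(chunks: list[np.ndarray], tag: str, n: int) -> EpochSet:
        data = np.stack(chunks) if chunks else np.empty((0, recording.samples.shape[0], n))
        return EpochSet(
            data=data,
            sampling_rate=fs,
            window_tag=tag,
            channel_labels=recording.channel_labels,
        )
    return build(base_list, "baseline", n_win), build(sdp_list, "sdp", n_sdp), dropped


def reject_noisy_trials(
    epochs: EpochSet, z_threshold: float = 5.0
) -> tuple[EpochSet, list[dict]]:
    """Drop trials whose residual amplitude is far outside the batch.

    Even after de-noising, occasional trials (gross movement) remain
    unusable; a trial is rejected when its peak absolute amplitude
    exceeds the across-trial median by more than ``z_threshold`` robust
    standard deviations (median absolute deviation scaled by 1.4826).
    Returns the surviving epochs and a log of dropped trials.
    """
    peaks = np.abs(epochs.data).max(axis=(1, 2))
    med = np.median(peaks)
    mad = np.median(np.abs(peaks - med)) * 1.4826
    if mad == 0:
        return epochs, []
    z = (peaks - med) / mad
    keep = z <= z_threshold
    dropped = [
        {"trial": int(t), "peak_z": float(z[t])} for t in np.flatnonzero(~keep)
    ]
    for entry in dropped:
        logger.info("rejecting trial %d (peak z=%.1f)", entry["trial"], entry["peak_z"])
    return epochs.copy_with(epochs.data[keep]), dropped
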