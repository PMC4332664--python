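"""Band-limited lagged phase synchronization and event-related indices.

The estimator works on phase-only (unit-modulus) Fourier coefficients:
per trial, the discrete Fourier coefficient of each ROI at each band bin
is normalized to unit modulus; cross products are averaged over trials,
then over the band's bins, giving a pairwise phase coherency ``rho``.
The lagged phase synchronization

    LPS = Im(rho)^2 / (1 - Re(rho)^2)

discards the instantaneous (real) part of the coupling, so any purely
zero-lag mixture — volume conduction, linear inverse crosstalk — is
invisible to it, while genuinely lagged coupling is not.
"""
from __future__ import annotations

import numpy as np
from numpy.fft import rfft, rfftfreq

from .containers import ConnectivityMatrix, CrossSpectra, EpochSet

__all__ = [
    "band_cross_spectra",
    "lagged_phase_synchronization",
    "event_related_index",
]


def band_cross_spectra(
    source_epochs: EpochSet | np.ndarray,
    band: tuple[float, float],
    sampling_rate: float | None = None,
    phase_only: bool = True,
    window_tag: str | None = None,
    condition: str | None = None,
) -> CrossSpectra:
    """Trial- and bin-averaged cross-spectral matrix in one band.

    With ``phase_only`` (the default) each Fourier coefficient is divided
    by its modulus before the cross products are formed — the phase
    synchronization variant.  Set it to False for amplitude-weighted
    coherency (each trial's cross product normalized by the geometric
    mean of band power).
    """
    if isinstance(source_epochs, EpochSet):
        data = source_epochs.data
        fs = source_epochs.sampling_rate
        window_tag = window_tag or source_epochs.window_tag
        condition = condition or source_epochs.condition
    else:
        data = np.asarray(source_epochs, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for bare arrays")
        fs = sampling_rate
    if data.ndim != 3:
        raise ValueError("source epochs must be (trials, rois, samples)")
    n_trials, n_rois, n = data.shape
    if n_trials < 1:
        raise ValueError("need at least one trial")
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError("band must lie strictly inside (0, Nyquist)")
    freqs = rfftfreq(n, 1.0 / fs)
    bins = np.flatnonzero((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))
    if bins.size == 0:
        raise ValueError("band contains no Fourier bins at this epoch length")
    coeffs = rfft(data, axis=2)[:, :, bins]  # trials x rois x bins
    if phase_only:
        mod = np.abs(coeffs)
        with np.errstate(invalid="ignore", divide="ignore"):
            coeffs = np.where(mod > 0, coeffs / np.where(mod > 0, mod, 1.0), 0.0)
        cross = np.einsum("tik,tjk->ijk", coeffs, coeffs.conj()) / n_trials
    else:
        cross = np.einsum("tik,tjk->ijk", coeffs, coeffs.conj()) / n_trials
        power = np.einsum("tik,tik->ik", coeffs, coeffs.conj()).real / n_trials
        norm = np.sqrt(power[:, None, :] * power[None, :, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            cross = np.where(norm > 0, cross / np.where(norm > 0, norm, 1.0), 0.0)
    matrix = cross.mean(axis=2)
    np.fill_diagonal(matrix, matrix.diagonal().real)
    return CrossSpectra(
        matrix=matrix,
        band=(lo, hi),
        n_trials=n_trials,
        n_bins=int(bins.size),
        window_tag=window_tag,
        condition=condition,
    )


def lagged_phase_synchronization(
    cross_spectra: CrossSpectra,
    roi_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """LPS matrix from pairwise phase coherencies.

    ``LPS = Im(rho)^2 / (1 - Re(rho)^2)``, in [0, 1]; the degenerate
    ``Re(rho)^2 = 1`` case (identical signals, pure zero-lag) maps to 0.
    """
    rho = cross_spectra.matrix
    mod = np.abs(rho)
    if np.any(mod > 1 + 1e-9):
        raise ValueError("coherency modulus exceeds 1: numerical integrity violated")
    denom = 1.0 - np.minimum(rho.real**2, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lps = np.where(denom > 1e-12, rho.imag**2 / np.where(denom > 1e-12, denom, 1.0), 0.0)
    lps = 0.5 * (lps + lps.T)
    np.fill_diagonal(lps, 0.0)
    lps = np.clip(lps, 0.0, 1.0)
    return ConnectivityMatrix(
        values=lps,
        band=cross_spectra.band,
        normalization="absolute",
        condition=cross_spectra.condition,
        window_tag=cross_spectra.window_tag,
        roi_labels=roi_labels,
    )


def event_related_index(
    event_conn: ConnectivityMatrix,
    baseline_conn: ConnectivityMatrix,
    eps: float = 1e-6,
    mode: str = "relative_change",
) -> ConnectivityMatrix:
    """Baseline-normalized connectivity (the c1 index).

    ``relative_change`` (default): ``(event - baseline) / max(baseline, eps)``
    — the percent-change reading of event-related modulation.  ``ratio``
    gives ``event / max(baseline, eps)`` instead.  Entries whose baseline
    fell below ``eps`` are floored and flagged in the output metadata.
    The untouched event matrix is the absolute (c2) index.
    """
    if event_conn.values.shape != baseline_conn.values.shape:
        raise ValueError("event and baseline matrices must have the same shape")
    if event_conn.band != baseline_conn.band:
        raise ValueError("event and baseline matrices must share the band")
    if event_conn.normalization != "absolute" or baseline_conn.normalization != "absolute":
        raise ValueError("event-related index requires absolute inputs")
    if mode not in ("relative_change", "ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    base = baseline_conn.values
    floored = base < eps
    denom = np.maximum(base, eps)
    if mode == "relative_change":
        vals = (event_conn.values - base) / denom
    else:
        vals = event_conn.values / denom
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(
        values=vals,
        band=event_conn.band,
        normalization="event_related",
        condition=event_conn.condition,
        window_tag=event_conn.window_tag,
        roi_labels=event_conn.roi_labels,
        flagged_entries=floored,
    )
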