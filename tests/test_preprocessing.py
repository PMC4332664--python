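"""Cleaning-chain contracts: filter response, referencing, SOBI and
BSS-CCA separation quality, epoching arithmetic."""
import numpy as np
import pandas as pd
import pytest

from lpsnet import (
    SimConfig,
    bandpass_filter,
    bsscca_remove_emg,
    extract_epochs,
    inject_artifacts,
    make_leadfield,
    project_to_channels,
    remove_eog_components,
    rereference_common_average,
    simulate_source_epochs,
    sobi_decompose,
)
from lpsnet.containers import EpochSet, RawRecording
from lpsnet.preprocessing import (
    _lagged_covariances,
    joint_diagonalize,
    offdiag_energy,
)

FS = 250.0


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant distance of P = unmixing @ mixing from identity."""
    P = np.abs(P)
    m = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return float((rows.sum() + cols.sum()) / (2 * m * (m - 1)))


class TestBandpass:
    def test_in_band_sinusoid_retained(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 11 * t)
        y = bandpass_filter(x, 1, 30, FS)
        mid = slice(500, 1500)
        rms_ratio = np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))
        assert rms_ratio == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_sinusoid_attenuated_20db(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 60 * t)
        y = bandpass_filter(x, 1, 30, FS)
        assert np.abs(y[500:1500]).max() < 0.1  # >= 20 dB down

    def test_zero_in_zero_out_and_length_preserved(self):
        y = bandpass_filter(np.zeros(300), 1, 30, FS)
        assert y.shape == (300,) and not y.any()

    def test_band_violating_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(300), 1, 130, FS)


class TestCommonAverage:
    def test_channel_mean_identically_zero(self, rng):
        x = rng.standard_normal((4, 16, 100))
        y = rereference_common_average(x)
        assert np.abs(y.mean(axis=1)).max() < 1e-10

    def test_idempotent_and_removes_common_offset(self, rng):
        x = rng.standard_normal((8, 100)) + 42.0
        once = rereference_common_average(x)
        twice = rereference_common_average(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_common_average(np.zeros((1, 50)))

    def test_commutes_with_filtering(self, rng):
        x = rng.standard_normal((6, 800))
        a = rereference_common_average(bandpass_filter(x, 1, 30, FS))
        b = bandpass_filter(np.asarray(rereference_common_average(x)), 1, 30, FS)
        np.testing.assert_allclose(a, b, atol=1e-8)


def _ar_sources(coefs, n, rng):
    out = np.zeros((len(coefs), n))
    for i, a in enumerate(coefs):
        e = rng.standard_normal(n)
        for t in range(1, n):
            out[i, t] = a * out[i, t - 1] + e[t]
    return out


class TestSobi:
    def test_identity_mixing_is_fixed_point(self, rng):
        s = _ar_sources([0.9, 0.5, -0.5, 0.1], 3000, rng)
        mixing, _ = sobi_decompose(s, lags=np.arange(1, 21))
        assert amari_index(np.linalg.pinv(mixing)) < 0.1

    def test_recovers_random_mixing_of_ar_sources(self, rng):
        s = _ar_sources([0.9, 0.5, -0.5, 0.1], 4000, rng)
        A = rng.standard_normal((4, 4))
        mixing, _ = sobi_decompose(A @ s, lags=np.arange(1, 21))
        assert amari_index(np.linalg.pinv(mixing) @ A) < 0.1

    def test_joint_diagonalization_reduces_offdiagonal_energy(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        mats = np.array([Q @ np.diag(rng.standard_normal(6)) @ Q.T for _ in range(10)])
        before = offdiag_energy(mats)
        _, rotated = joint_diagonalize(mats)
        assert offdiag_energy(rotated) < 1e-10 * before

    def test_empty_lag_set_rejected(self, rng):
        with pytest.raises(ValueError):
            sobi_decompose(rng.standard_normal((4, 100)), lags=np.array([], dtype=int))


def _contaminated_epochs(blink_rate, emg_rate, seed=2, n_trials=8):
    cfg = SimConfig(n_subjects=1, n_trials=n_trials, conditions=("IL",), seed=seed)
    lf = make_leadfield(64, 84, seed=seed)
    epochs, _ = simulate_source_epochs(cfg, subjects=[0], conditions=["IL"])
    chans = project_to_channels(epochs[(0, "IL", "sdp")], lf, seed=seed + 1)
    dirty, eog, emg = inject_artifacts(
        chans, FS, blink_rate=blink_rate, emg_rate=emg_rate, seed=seed + 2,
        electrode_positions=lf.electrode_positions,
    )
    return lf, chans, dirty, eog, emg


class TestEogRemoval:
    def test_clean_data_passes_through_nearly_unchanged(self):
        _, chans, dirty, eog, _ = _contaminated_epochs(0.0, 0.0)
        es = rereference_common_average(
            EpochSet(bandpass_filter(dirty, 1, 30, FS), FS, "sdp")
        )
        out = remove_eog_components(es, eog, threshold=0.7, per_trial=False)
        rel = np.linalg.norm(out.data - es.data) / np.linalg.norm(es.data)
        assert rel < 0.01

    def test_blink_contamination_reduced_at_least_80_percent(self):
        lf, chans, dirty, eog, _ = _contaminated_epochs(1.0, 0.0, n_trials=10)
        es = rereference_common_average(
            EpochSet(bandpass_filter(dirty, 1, 30, FS), FS, "sdp")
        )
        frontal = np.argsort(-lf.electrode_positions[:, 1])[:8]

        def mean_corr(data):
            return np.mean(
                [
                    abs(np.corrcoef(data[t, ch], eog[t])[0, 1])
                    for t in range(data.shape[0])
                    for ch in frontal
                ]
            )

        before = mean_corr(es.data)
        out = remove_eog_components(es, eog, threshold=0.7, per_trial=False)
        assert mean_corr(out.data) < 0.2 * before

    def test_unreachable_threshold_removes_nothing(self):
        _, _, dirty, eog, _ = _contaminated_epochs(1.0, 0.0, n_trials=4)
        es = EpochSet(bandpass_filter(dirty, 1, 30, FS), FS, "sdp")
        out = remove_eog_components(es, eog, threshold=1.01, per_trial=True)
        np.testing.assert_array_equal(out.data, es.data)


class TestBssCca:
    def test_narrowband_signals_survive_085_threshold(self):
        # lag-1 autocorrelation of a 10-12 Hz process at 250 Hz is
        # ~cos(2 pi * 11 / 250) = 0.96 > 0.85
        assert np.cos(2 * np.pi * 11 / FS) > 0.85
        cfg = SimConfig(n_subjects=1, n_trials=4, conditions=("IL",), seed=4, snr_db=30)
        epochs, _ = simulate_source_epochs(cfg, subjects=[0], conditions=["IL"])
        es = EpochSet(epochs[(0, "IL", "sdp")][:, :12, :], FS, "sdp")
        out = bsscca_remove_emg(es, autocorr_threshold=0.85, per_trial=True)
        rel = np.linalg.norm(out.data - es.data) / np.linalg.norm(es.data)
        assert rel < 0.25

    def test_white_noise_bursts_removed(self, rng):
        t = np.arange(500) / FS
        brain = np.array([np.sin(2 * np.pi * 11 * t + p) for p in rng.uniform(0, 6, 6)])
        data = brain.copy()
        data[3, 200:300] += 4 * rng.standard_normal(100)  # broadband burst
        es = EpochSet(data[None], FS, "sdp")
        out = bsscca_remove_emg(es, autocorr_threshold=0.85, per_trial=True)
        resid_burst = out.data[0, 3, 200:300] - brain[3, 200:300]
        assert np.abs(resid_burst).std() < 0.5 * 4

    def test_removal_cuts_high_band_keeps_alpha(self):
        from scipy.signal import welch

        _, chans, dirty, _, _ = _contaminated_epochs(0.0, 1.0, n_trials=10)
        es = EpochSet(dirty, FS, "sdp")
        out = bsscca_remove_emg(es, autocorr_threshold=0.85, per_trial=True)

        def bandpower(data, lo, hi):
            f, p = welch(data, fs=FS, nperseg=250, axis=-1)
            return p[..., (f >= lo) & (f <= hi)].mean()

        hi_before = bandpower(bandpass_filter(es.data, 1, 30, FS), 20, 30)
        hi_after = bandpower(bandpass_filter(out.data, 1, 30, FS), 20, 30)
        al_before = bandpower(bandpass_filter(es.data, 1, 30, FS), 10, 12)
        al_after = bandpower(bandpass_filter(out.data, 1, 30, FS), 10, 12)
        assert hi_after < hi_before
        assert abs(al_after / al_before - 1) < 0.1

    def test_threshold_outside_unit_interval_rejected(self, rng):
        es = EpochSet(rng.standard_normal((1, 4, 100)), FS, "sdp")
        with pytest.raises(ValueError):
            bsscca_remove_emg(es, autocorr_threshold=1.5)


class TestExtractEpochs:
    def _recording(self, onsets, duration=30.0):
        n = int(duration * FS)
        rng = np.random.default_rng(0)
        events = pd.DataFrame(
            {"time_s": onsets, "label": ["stimulus_on"] * len(onsets)}
        )
        return RawRecording(
            samples=rng.standard_normal((4, n)), sampling_rate=FS, events=events
        )

    def test_two_second_windows_have_500_samples(self):
        rec = self._recording([5.0, 12.0])
        base, sdp, dropped = extract_epochs(rec)
        assert base.data.shape == (2, 4, 500)
        assert sdp.data.shape == (2, 4, 500)
        assert dropped == []

    def test_window_arithmetic_matches_fixation_layout(self):
        # stimulus at t=3 s after a 3-s fixation: baseline covers [1, 3) s
        rec = self._recording([3.0], duration=10.0)
        base, sdp, _ = extract_epochs(rec)
        np.testing.assert_array_equal(base.data[0], rec.samples[:, 250:750])
        np.testing.assert_array_equal(sdp.data[0], rec.samples[:, 750:1250])

    def test_out_of_range_trial_dropped_and_logged(self):
        rec = self._recording([5.0, 29.5])
        base, sdp, dropped = extract_epochs(rec)
        assert base.n_trials == 1 and sdp.n_trials == 1
        assert len(dropped) == 1 and dropped[0]["trial"] == 1


class TestTrialRejection:
    def test_outlier_trials_dropped_clean_trials_kept(self, rng):
        from lpsnet.preprocessing import reject_noisy_trials

        data = rng.standard_normal((25, 8, 200))
        data[3] *= 40.0  # gross movement artifact
        es = EpochSet(data, FS, "sdp")
        kept, dropped = reject_noisy_trials(es)
        assert [d["trial"] for d in dropped] == [3]
        assert kept.n_trials == 24

    def test_default_study_keeps_at_least_22_of_25_trials(self):
        """On default generator output with artifacts and cleaning, the
        surviving trial count stays inside the study envelope."""
        from lpsnet.preprocessing import reject_noisy_trials

        lf, chans, dirty, eog, _ = _contaminated_epochs(0.25, 0.1, seed=6, n_trials=25)
        es = rereference_common_average(
            EpochSet(bandpass_filter(dirty, 1, 30, FS), FS, "sdp")
        )
        cleaned = remove_eog_components(es, eog, threshold=0.7, per_trial=False)
        kept, dropped = reject_noisy_trials(cleaned)
        assert kept.n_trials >= 22
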