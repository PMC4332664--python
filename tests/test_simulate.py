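"""Generator contracts: leadfield geometry, planted coupling, artifacts,
and the behavioral link."""
import numpy as np
import pytest
from scipy.stats import spearmanr

from lpsnet import (
    SimConfig,
    inject_artifacts,
    make_leadfield,
    simulate_behavior,
    simulate_source_epochs,
)
from lpsnet.connectivity import band_cross_spectra
from lpsnet.simulate import _emg_burst, _structural_truth, analytic_pair_coherency


class TestLeadfield:
    def test_columns_average_reference_centered(self):
        lf = make_leadfield(32, 20, spread=0.4, seed=3)
        assert np.abs(lf.gain.sum(axis=0)).max() < 1e-12

    def test_deterministic_given_seed(self):
        a = make_leadfield(32, 20, seed=5)
        b = make_leadfield(32, 20, seed=5)
        assert np.array_equal(a.gain, b.gain)

    def test_well_conditioned_no_degenerate_columns(self):
        lf = make_leadfield(64, 84, spread=0.5, seed=0)
        assert np.isfinite(np.linalg.cond(lf.gain))
        assert np.linalg.norm(lf.gain, axis=0).min() > 0

    @pytest.mark.parametrize("bad", [dict(n_channels=1), dict(n_sources=0), dict(spread=0.0)])
    def test_invalid_arguments_rejected(self, bad):
        kwargs = dict(n_channels=16, n_sources=8, spread=0.3)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            make_leadfield(**kwargs)


class TestSimConfig:
    def test_partition_must_cover_rois(self):
        with pytest.raises(ValueError, match="partition"):
            SimConfig(n_rois=8, partition=((0, 1), (2, 3)))

    def test_band_must_fit_sampling_rate(self):
        with pytest.raises(ValueError):
            SimConfig(band=(10.0, 130.0), sampling_rate=250.0)

    def test_lags_strictly_positive(self):
        with pytest.raises(ValueError):
            SimConfig(lag_range=(0.0, 0.04))


class TestSourceEpochs:
    def test_bit_identical_for_identical_config(self, tiny_config):
        a, _ = simulate_source_epochs(tiny_config, subjects=[0], conditions=["WE-IL"])
        b, _ = simulate_source_epochs(tiny_config, subjects=[0], conditions=["WE-IL"])
        key = (0, "WE-IL", "sdp")
        assert np.array_equal(a[key], b[key])

    def test_uncoupled_nodes_have_near_zero_coherency(self):
        cfg = SimConfig(
            n_subjects=1, n_trials=40, conditions=("IL",),
            coupling_within=1.0, coupling_between=0.0, seed=11,
        )
        epochs, gt = simulate_source_epochs(cfg, subjects=[0], conditions=["IL"])
        cs = band_cross_spectra(epochs[(0, "IL", "sdp")], cfg.band, sampling_rate=250)
        # nodes from different groups share no latent when B = 0
        i, j = cfg.partition[0][0], cfg.partition[1][0]
        assert abs(cs.matrix[i, j]) < 2 / np.sqrt(40 * cs.n_bins) + 0.15

    def test_lagged_shared_latent_has_imaginary_cross_spectrum(self, tiny_config):
        gt = _structural_truth(tiny_config)
        i, j = tiny_config.partition[0][:2]
        gamma = analytic_pair_coherency(tiny_config, gt, i, j, "WE-IL", "sdp")
        assert np.abs(gamma.imag).max() > 0

    def test_planted_sdp_gain_recorded_in_ground_truth(self):
        cfg = SimConfig(conditions=("WE-IL", "WE-IT"), planted_scale=2.0, seed=0)
        gt = _structural_truth(cfg)
        g, h = cfg.planted_pairs[0]
        base = gt.mean_between_coupling(g, h, "WE-IL", "baseline")
        sdp = gt.mean_between_coupling(g, h, "WE-IL", "sdp")
        assert sdp == pytest.approx(2.0 * base)
        # truth-telling condition is unmodulated
        assert gt.mean_between_coupling(g, h, "WE-IT", "sdp") == pytest.approx(base)

    def test_coupling_matrix_symmetric_zero_diagonal(self):
        cfg = SimConfig(seed=0)
        gt = _structural_truth(cfg)
        B = gt.group_coupling_matrix("WE-IL", "sdp")
        assert np.array_equal(B, B.T)
        assert np.all(np.diag(B) == 0)


class TestArtifacts:
    def test_zero_rates_returns_input_exactly(self, rng):
        clean = rng.standard_normal((3, 8, 100))
        dirty, eog, emg = inject_artifacts(clean, 250.0, blink_rate=0, emg_rate=0, seed=1)
        assert np.array_equal(dirty, clean)

    def test_eog_reference_tracks_frontal_contamination(self, leadfield64, rng):
        clean = 0.01 * rng.standard_normal((6, 64, 500))
        dirty, eog, _ = inject_artifacts(
            clean, 250.0, blink_rate=1.5, emg_rate=0.0, seed=2,
            electrode_positions=leadfield64.electrode_positions,
        )
        artifact = dirty - clean
        frontal = int(np.argmax(np.abs(artifact).sum(axis=(0, 2))))
        cors = [
            abs(np.corrcoef(artifact[t, frontal], eog[t])[0, 1])
            for t in range(6)
            if artifact[t, frontal].std() > 0
        ]
        assert np.mean(cors) > 0.9

    def test_emg_burst_broadband_vs_narrowband_autocorrelation(self, rng):
        burst = _emg_burst(250.0, rng)
        r1 = np.corrcoef(burst[:-1], burst[1:])[0, 1]
        assert r1 < 0.5
        t = np.arange(500) / 250.0
        alpha = np.sin(2 * np.pi * 11 * t)
        r1_alpha = np.corrcoef(alpha[:-1], alpha[1:])[0, 1]
        assert r1_alpha > 0.9


class TestBehavior:
    def test_zero_slope_decorrelates_rt_from_engagement(self):
        cfg = SimConfig(
            n_subjects=16, n_trials=2, conditions=("IL",),
            rt_link=(80, 0.0, 0.1), seed=21,
        )
        _, gt = simulate_source_epochs(cfg, subjects=[], conditions=[])
        table, _ = simulate_behavior(gt, cfg)
        mean_rt = table.groupby("subject")["response_time"].mean().to_numpy()
        rho = spearmanr(mean_rt, gt.engagement).statistic
        assert abs(rho) < 0.45  # null link; loose bound at n=16

    def test_noiseless_positive_slope_gives_perfect_rank_link(self):
        cfg = SimConfig(
            n_subjects=12, n_trials=1, conditions=("IL",),
            rt_link=(80, 1.0, 0.0), seed=3,
        )
        _, gt = simulate_source_epochs(cfg, subjects=[], conditions=[])
        table, _ = simulate_behavior(gt, cfg, trial_jitter_sd=0.0)
        mean_rt = table.groupby("subject")["response_time"].mean().to_numpy()
        assert spearmanr(mean_rt, gt.engagement).statistic == pytest.approx(1.0)

    def test_study_sized_table_has_16_rows_per_condition(self):
        cfg = SimConfig(n_subjects=16, n_trials=1, conditions=("WE-IL", "WE-IT"), seed=0)
        _, gt = simulate_source_epochs(cfg, subjects=[], conditions=[])
        table, traces = simulate_behavior(gt, cfg)
        per_cond = table.groupby("condition")["subject"].nunique()
        assert (per_cond == 16).all()
        assert set(traces) == {(s, c) for s in range(16) for c in cfg.conditions}

    def test_emg_trace_burst_starts_at_offset_plus_rt(self):
        cfg = SimConfig(n_subjects=1, n_trials=1, conditions=("IL",), seed=5)
        _, gt = simulate_source_epochs(cfg, subjects=[], conditions=[])
        _, traces = simulate_behavior(gt, cfg)
        info = traces[(0, "IL")]
        onset = int(round((info["stimulus_offset_s"] + info["true_rt"]) * 250))
        pre = info["trace"][: onset - 5]
        post = info["trace"][onset : onset + 50]
        assert post.std() > 5 * pre.std()
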