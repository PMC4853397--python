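"""Hierarchical Bayesian inverse stage: noise model, variances, filters, stitching."""

import numpy as np
import pytest
from scipy import linalg

import cortvowel as cv
from cortvowel import inverse, simulate
from cortvowel.exceptions import (
    InvalidConfigurationError,
    NoSourceError,
)


class TestEstimateNoise:
    def _epochs(self, data):
        return simulate.EpochedEEG(data=data, labels=np.array(["A"] * data.shape[0]))

    def test_white_baseline_small_off_diagonal(self):
        rng = np.random.default_rng(0)
        ep = self._epochs(rng.normal(size=(150, 8, 1024)))
        nm = inverse.estimate_noise(ep)
        d = np.sqrt(np.diag(nm.Sigma_s))
        rho = nm.Sigma_s / np.outer(d, d)
        off = rho[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_covariance_scales_quadratically(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(20, 4, 1024))
        s1 = inverse.estimate_noise(self._epochs(data)).sigma2
        s3 = inverse.estimate_noise(self._epochs(3.0 * data)).sigma2
        assert s3 == pytest.approx(9.0 * s1, rel=1e-9)

    def test_constant_baseline_stays_positive_definite(self):
        ep = self._epochs(np.ones((5, 4, 1024)))
        nm = inverse.estimate_noise(ep)
        linalg.cho_factor(nm.Sigma_s)  # must not raise

    def test_baseline_too_short(self):
        ep = self._epochs(np.zeros((3, 4, 1024)))
        with pytest.raises(InvalidConfigurationError):
            inverse.estimate_noise(ep, baseline=(-0.5005, -0.5))

    def test_baseline_must_be_preonset(self):
        ep = self._epochs(np.zeros((3, 4, 1024)))
        with pytest.raises(InvalidConfigurationError):
            inverse.estimate_noise(ep, baseline=(0.0, 0.5))


class TestReduceDipoles:
    def test_ratio_counts(self):
        src = cv.build_source_space(100, 30, seed=1)
        kept = inverse.reduce_dipoles(src, 0.2, seed=0)
        assert kept.size == 20

    def test_ratio_one_identity(self):
        src = cv.build_source_space(40, 10, seed=1)
        kept = inverse.reduce_dipoles(src, 1.0, seed=0)
        assert np.array_equal(kept, np.arange(40))

    def test_every_large_roi_retains_a_vertex(self):
        src = cv.build_source_space(173, 30, seed=2)
        kept = inverse.reduce_dipoles(src, 0.2, seed=5)
        kept_labels = set(src.roi_labels[kept])
        for roi in np.unique(src.roi_labels):
            if np.sum(src.roi_labels == roi) >= 5:
                assert roi in kept_labels

    def test_deterministic(self):
        src = cv.build_source_space(100, 30, seed=1)
        a = inverse.reduce_dipoles(src, 0.2, seed=9)
        b = inverse.reduce_dipoles(src, 0.2, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_ratio(self):
        src = cv.build_source_space(10, 5, seed=1)
        with pytest.raises(InvalidConfigurationError):
            inverse.reduce_dipoles(src, 0.0, seed=0)


class TestWindowSpec:
    def test_default_window_count(self):
        # -0.5..3 s at 0.5 s / 0.25 s shift -> 13 windows
        assert inverse.WindowSpec().n_windows == 13

    def test_non_tiling_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            inverse.WindowSpec((0.0, 1.1), 0.5, 0.25)

    def test_shift_greater_than_window_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            inverse.WindowSpec((0.0, 2.0), 0.25, 0.5)


class TestVBEstimate:
    def test_prior_dominated_limit(self, source20, focal_experiment, default_windows):
        truth, epochs, _ = focal_experiment
        noise = inverse.estimate_noise(epochs)
        act = np.zeros(20)
        act[truth.active_sets["A"][0]] = 1.0
        nu, nu0, _ = inverse.vb_estimate(
            epochs, source20.lead_field, act, noise,
            inverse.HyperParams(10, 1e12), default_windows,
        )
        assert np.max(np.abs(nu - nu0) / nu0) < 1e-6

    def test_single_source_localized_noise_free(self, source20, default_windows):
        # flat activity prior, no background, no sensor noise: the vertex
        # with the largest converged variance is the true source
        truth = simulate.GroundTruth(
            active_sets={"A": [7], "I": [13]},
            fmri_betas={t: np.zeros(20) for t in simulate.TASKS},
            snr=np.inf,
        )
        design = simulate.ExperimentDesign(n_trials_per_task=5, background_std=0.0)
        epochs, _ = cv.simulate_experiment(source20, truth, design, seed=6)
        noise = inverse.NoiseModel.isotropic(1e-8, 32)
        nu, _, _ = inverse.vb_estimate(
            epochs, source20.lead_field, np.zeros(20), noise,
            inverse.HyperParams(10, 1.0), default_windows,
            trial_idx=np.flatnonzero(epochs.labels == "A"),
        )
        assert int(np.argmax(nu.max(axis=0))) == 7

    def test_no_trials_rejected(self, source20, focal_experiment, default_windows):
        truth, epochs, _ = focal_experiment
        noise = inverse.estimate_noise(epochs)
        with pytest.raises(NoSourceError):
            inverse.vb_estimate(
                epochs, source20.lead_field, np.zeros(20), noise,
                inverse.HyperParams(), default_windows, trial_idx=np.array([], int),
            )

    def test_empty_lead_field_rejected(self, focal_experiment, default_windows):
        truth, epochs, _ = focal_experiment
        noise = inverse.estimate_noise(epochs)
        with pytest.raises(NoSourceError):
            inverse.vb_estimate(
                epochs, np.zeros((32, 0)), np.zeros(0), noise,
                inverse.HyperParams(), default_windows,
            )

    def test_m0_monotone_at_prior_peak(self, source20, focal_experiment,
                                       default_windows):
        truth, epochs, _ = focal_experiment
        noise = inverse.estimate_noise(epochs)
        tv = truth.active_sets["A"][0]
        act = np.zeros(20)
        act[tv] = 1.0
        peaks = []
        for m0 in (10, 100, 1000):
            nu, _, _ = inverse.vb_estimate(
                epochs, source20.lead_field, act, noise,
                inverse.HyperParams(m0, 10), default_windows,
            )
            peaks.append(nu[:, tv].max())
        assert peaks[0] <= peaks[1] <= peaks[2]


class TestInverseFilter:
    def test_noiseless_square_identity(self):
        rng = np.random.default_rng(0)
        G = rng.normal(size=(32, 32)) + 5 * np.eye(32)
        W = inverse.build_inverse_filter(
            np.ones(32), G, inverse.NoiseModel.isotropic(1e-12, 32)
        )
        assert np.abs(W @ G - np.eye(32)).max() < 1e-6

    def test_zero_variance_gives_zero_row(self):
        rng = np.random.default_rng(1)
        G = rng.normal(size=(8, 5))
        nu = np.array([1.0, 0.0, 1.0, 1.0, 1.0])
        W = inverse.build_inverse_filter(nu, G, inverse.NoiseModel.isotropic(0.1, 8))
        assert np.all(W[1] == 0)

    def test_reconstruction_on_high_variance_support(self):
        # data generated on high-variance vertices are recovered to < 5%
        rng = np.random.default_rng(2)
        G = rng.normal(size=(32, 20))
        nu = np.full(20, 1e-8)
        support = [3, 11, 17]
        nu[support] = 1.0
        W = inverse.build_inverse_filter(nu, G, inverse.NoiseModel.isotropic(1e-8, 32))
        j = np.zeros(20)
        j[support] = rng.normal(size=3)
        b = G @ j
        rel = np.linalg.norm(W @ b - j) / np.linalg.norm(j)
        assert rel < 0.05


class TestReconstruction:
    def _epochs(self, data):
        return simulate.EpochedEEG(data=data, labels=np.array(["A"] * data.shape[0]))

    def test_single_window_plain_product(self):
        rng = np.random.default_rng(3)
        ep = self._epochs(rng.normal(size=(2, 4, 1024)))
        W = rng.normal(size=(1, 3, 4))
        out = inverse.reconstruct_currents(W, [(384, 1024)], ep, (0.5, 3.0))
        expected = np.einsum("vs,tsn->tvn", W[0], ep.data[:, :, 384:1024])
        assert np.allclose(out, expected)

    def test_equal_filters_cross_fade_identity(self):
        rng = np.random.default_rng(4)
        ep = self._epochs(rng.normal(size=(2, 4, 1024)))
        Wone = rng.normal(size=(3, 4))
        W = np.stack([Wone, Wone, Wone])
        slices = [(384, 704), (544, 864), (704, 1024)]
        out = inverse.reconstruct_currents(W, slices, ep, (0.5, 3.0))
        expected = np.einsum("vs,tsn->tvn", Wone, ep.data[:, :, 384:1024])
        assert np.allclose(out, expected)

    def test_uncovered_range_rejected(self):
        ep = self._epochs(np.zeros((1, 4, 1024)))
        W = np.zeros((1, 3, 4))
        with pytest.raises(InvalidConfigurationError):
            inverse.reconstruct_currents(W, [(384, 640)], ep, (0.5, 3.0))


class TestModelResults:
    def test_model_restricts_to_prior_area(self, source20, focal_experiment,
                                           default_windows):
        truth, epochs, _ = focal_experiment
        prior = cv.PriorSet("Unc001", np.array([5, 7, 13]),
                            np.array([0.5, 1.0, 0.8]), 0.01, 0.01, 20)
        model = cv.HierarchicalCurrentModel(
            epochs, source20, prior, windows=default_windows
        )
        res = model.fit()
        assert np.array_equal(res.vertices, [5, 7, 13])
        assert res.nu.shape == (default_windows.n_windows, 3)
        assert "m0" in res.summary()

    def test_empty_prior_area_rejected(self, source20, focal_experiment,
                                       default_windows):
        truth, epochs, _ = focal_experiment
        prior = cv.PriorSet("Unc001", np.array([], int), np.array([]),
                            0.01, 0.01, 20)
        with pytest.raises(NoSourceError):
            cv.HierarchicalCurrentModel(epochs, source20, prior,
                                        windows=default_windows)

    def test_reconstruction_error_decreases_with_snr(self):
        # focal sources, low background: recovery improves with sensor SNR
        win = inverse.WindowSpec((0.5, 2.5))
        errs = []
        for snr in (1, 5, 25):
            es = []
            for s in range(3):
                src = cv.build_source_space(30, 15, seed=s)
                cv.compute_lead_field(src)
                tr = simulate.default_ground_truth(src, n_active=2, snr=snr,
                                                   seed=10 + s)
                des = simulate.ExperimentDesign(n_trials_per_task=10,
                                                background_std=0.1)
                ep, curr = cv.simulate_experiment(src, tr, des, seed=20 + s)
                nz = inverse.estimate_noise(ep)
                ids = np.concatenate([tr.active_sets["A"], tr.active_sets["I"]])
                act = np.zeros(30)
                act[ids] = 1.0
                nu, _, _ = inverse.vb_estimate(
                    ep, src.lead_field, act, nz, inverse.HyperParams(100, 1), win
                )
                W = inverse.build_inverse_filter(nu, src.lead_field, nz)
                sl = win.sample_slices(ep.fs, ep.onset_index, ep.n_samples)
                rec = inverse.reconstruct_currents(W, sl, ep, (1.0, 2.0))
                o0 = ep.onset_index + 256
                true_seg = curr[:, ids, o0:o0 + 256]
                es.append(np.linalg.norm(rec[:, ids, :] - true_seg)
                          / np.linalg.norm(true_seg))
            errs.append(np.mean(es))
        assert errs[0] > errs[1] > errs[2]
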