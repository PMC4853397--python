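"""Cross-validation, permutation significance, confusion ratios, ANOVA."""

import numpy as np
import pytest

import cortvowel as cv
from cortvowel import evaluation, features, inverse, simulate
from cortvowel.exceptions import InvalidConfigurationError, InvalidInputError


class TestConfusionRatios:
    def test_perfect_predictions_identity(self):
        y = np.array(["A", "I", "CTRL"] * 5)
        assert np.array_equal(
            evaluation.confusion_ratios(y, y, ("A", "I", "CTRL")), np.eye(3)
        )

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        y = np.repeat(["A", "I", "CTRL"], 20)
        pred = rng.choice(["A", "I", "CTRL"], 60)
        mat = evaluation.confusion_ratios(y, pred)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_uniform_predictions_near_third(self):
        rng = np.random.default_rng(1)
        y = np.repeat(["A", "I", "CTRL"], 10000)
        pred = rng.choice(["A", "I", "CTRL"], 30000)
        mat = evaluation.confusion_ratios(y, pred)
        assert np.abs(mat - 1 / 3).max() < 0.02

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidInputError):
            evaluation.confusion_ratios(["A"], ["X"])


class TestAnova:
    def test_df_structure_nine_groups_of_ten(self):
        rng = np.random.default_rng(2)
        F, df1, df2, p = evaluation.anova_oneway(
            [rng.normal(size=10) for _ in range(9)]
        )
        assert (df1, df2) == (8, 81)

    def test_identical_groups_f_zero(self):
        F, _, _, p = evaluation.anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert F == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # SSB = 6, SSW = 6 -> F = (6/2)/(6/6) = 3
        F, df1, df2, p = evaluation.anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert F == pytest.approx(3.0)
        assert (df1, df2) == (2, 6)

    def test_zero_within_variance_infinite_f(self):
        F, _, _, p = evaluation.anova_oneway([[1, 1], [2, 2]])
        assert np.isinf(F) and p == 0.0


class TestPermutationPvalue:
    def test_floor_when_observed_exceeds_all(self):
        res = evaluation.permutation_pvalue(
            10.0, lambda rng: rng.uniform(0, 1), n_perm=10000, seed=0
        )
        assert res.p_value == pytest.approx(1.0e-4)
        assert res.count_ge == 0

    def test_clamped_at_one(self):
        res = evaluation.permutation_pvalue(
            -10.0, lambda rng: rng.uniform(0, 1), n_perm=50, seed=0
        )
        assert res.p_value == 1.0

    def test_null_calibration_uniform(self):
        # statistic drawn from its own null: p ~ Uniform(0, 1]
        rng_master = np.random.default_rng(3)
        hits = 0
        for rep in range(200):
            obs = rng_master.normal()
            res = evaluation.permutation_pvalue(
                obs, lambda rng: rng.normal(), n_perm=99,
                seed=int(rng_master.integers(2**31)),
            )
            hits += res.p_value <= 0.05
        assert 0.01 <= hits / 200 <= 0.10


def _feature_matrix(n_per_class=50, d=8, sep=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(["A", "I", "CTRL"], n_per_class)
    X = rng.normal(size=(y.size, d))
    for i, mu in enumerate(("A", "I", "CTRL")):
        X[y == mu, i] += sep
    sh = rng.permutation(y.size)
    return features.FeatureMatrix(X=X[sh], names=[f"f{i}" for i in range(d)],
                                  labels=y[sh])


class TestRepeatedKfold:
    def test_partition_property(self):
        fm = _feature_matrix(sep=2.0)
        rep = evaluation.repeated_kfold(fm, k=10, repeats=2, seed=0,
                                        smlr_config={"max_iter": 10})
        assert len(rep.accuracies) == 20
        assert rep.confusion.shape == (3, 3)

    def test_null_data_near_chance(self):
        fm = _feature_matrix(sep=0.0, seed=5)
        rep = evaluation.repeated_kfold(fm, k=10, repeats=3, seed=1,
                                        smlr_config={"max_iter": 15})
        assert abs(rep.mean - 100 / 3) <= max(3 * rep.se, 3.0)

    def test_seeded_determinism(self):
        fm = _feature_matrix(sep=1.0, seed=6)
        r1 = evaluation.repeated_kfold(fm, k=5, repeats=1, seed=7,
                                       smlr_config={"max_iter": 10})
        r2 = evaluation.repeated_kfold(fm, k=5, repeats=1, seed=7,
                                       smlr_config={"max_iter": 10})
        assert np.array_equal(r1.accuracies, r2.accuracies)

    def test_k_exceeding_trials_rejected(self):
        fm = _feature_matrix(n_per_class=2)
        with pytest.raises(InvalidConfigurationError):
            evaluation.repeated_kfold(fm, k=10)

    def test_shuffled_training_labels_drop_to_chance(self):
        fm = _feature_matrix(sep=3.0, seed=8)
        rep = evaluation.repeated_kfold(fm, k=10, repeats=3, seed=2,
                                        smlr_config={"max_iter": 15},
                                        shuffle_labels=True)
        assert abs(rep.mean - 100 / 3) <= max(3 * rep.se, 4.0)


@pytest.fixture(scope="module")
def tiny_pipeline(source20):
    """Separable tiny decoding problem: strong focal sources, low noise."""
    truth = simulate.default_ground_truth(source20, n_active=1, snr=20, seed=4)
    design = simulate.ExperimentDesign(n_trials_per_task=10, background_std=0.1)
    epochs, _ = cv.simulate_experiment(source20, truth, design, seed=5)
    ids = np.concatenate([truth.active_sets["A"], truth.active_sets["I"]])
    act = np.ones(ids.size)
    prior = cv.PriorSet("Unc001", np.sort(ids), act[np.argsort(ids)], 0.01, 0.01, 20)
    pipe = evaluation.DecodingPipeline(
        epochs, source20, prior, windows=inverse.WindowSpec((0.5, 2.5)),
        vb_tol=1e-3, vb_max_iter=50,
    )
    return pipe


class TestNestedCV:
    def test_grid_geometry_and_selection(self, tiny_pipeline):
        rep = evaluation.nested_cv(
            tiny_pipeline, n_groups=10, n_repeats=1, seed=0,
            filter_scope="outer", smlr_config={"max_iter": 10},
        )
        assert len(rep.accuracies) == 10
        # 9 hyper-parameter pairs x 9 inner rotations per outer fold
        for rec in rep.inner_records:
            assert rec["inner_accuracy"].shape == (9, 9)
        assert all(h in inverse.HYPER_GRID for h in rep.selected)

    def test_separable_data_perfect_accuracy(self, tiny_pipeline):
        rep = evaluation.nested_cv(
            tiny_pipeline, grid=[inverse.HyperParams(10, 1)],
            n_groups=10, n_repeats=1, seed=1,
            filter_scope="outer", smlr_config={"max_iter": 30},
        )
        assert rep.mean == pytest.approx(100.0)

    def test_unbalanced_classes_rejected(self, source20, tiny_pipeline):
        pipe = tiny_pipeline
        bad = simulate.EpochedEEG(
            data=pipe.epochs.data[:29], labels=pipe.epochs.labels[:29],
            fs=pipe.epochs.fs, onset_index=pipe.epochs.onset_index,
        )
        bad_pipe = evaluation.DecodingPipeline(
            bad, pipe.source, pipe.prior, windows=pipe.windows
        )
        with pytest.raises(InvalidInputError):
            evaluation.nested_cv(bad_pipe, n_groups=10, n_repeats=1, seed=0)

    def test_empty_grid_rejected(self, tiny_pipeline):
        with pytest.raises(InvalidConfigurationError):
            evaluation.nested_cv(tiny_pipeline, grid=[])

    def test_no_leakage_from_test_trials(self, source20, tiny_pipeline):
        """Corrupting held-out test trials leaves inner accuracies and the
        selected hyper-parameters of that fold unchanged."""
        pipe = tiny_pipeline
        grid = [inverse.HyperParams(10, 1), inverse.HyperParams(10, 10)]
        rep1 = evaluation.nested_cv(
            pipe, grid=grid, n_groups=10, n_repeats=1, seed=3,
            filter_scope="inner", smlr_config={"max_iter": 10},
        )
        # corrupt the trials of test group 0 (never used by its inner loop)
        groups = rep1.groups[0]
        test_idx = np.flatnonzero(groups == 0)
        rng = np.random.default_rng(99)
        data = pipe.epochs.data.copy()
        data[test_idx] = rng.normal(scale=10.0, size=data[test_idx].shape)
        corrupted = simulate.EpochedEEG(
            data=data, labels=pipe.epochs.labels.copy(),
            fs=pipe.epochs.fs, onset_index=pipe.epochs.onset_index,
        )
        pipe2 = evaluation.DecodingPipeline(
            corrupted, pipe.source, pipe.prior, windows=pipe.windows,
            noise=pipe.noise, vb_tol=pipe.vb_tol, vb_max_iter=pipe.vb_max_iter,
        )
        rep2 = evaluation.nested_cv(
            pipe2, grid=grid, n_groups=10, n_repeats=1, seed=3,
            filter_scope="inner", smlr_config={"max_iter": 10},
        )
        assert np.array_equal(rep2.groups[0], groups)
        assert np.allclose(
            rep1.inner_records[0]["inner_accuracy"],
            rep2.inner_records[0]["inner_accuracy"],
        )
        assert rep1.selected[0] == rep2.selected[0]

    def test_shuffled_train_labels_near_chance(self, tiny_pipeline):
        rep = evaluation.nested_cv(
            tiny_pipeline, grid=[inverse.HyperParams(10, 1)],
            n_groups=10, n_repeats=2, seed=4, filter_scope="outer",
            smlr_config={"max_iter": 15}, shuffle_train_labels=True,
        )
        assert abs(rep.mean - 100 / 3) <= max(3 * rep.se, 12.0)


class TestDecodingPermutation:
    def test_strong_signal_beats_all_permutations(self):
        fm = _feature_matrix(n_per_class=20, d=6, sep=4.0, seed=9)
        res = evaluation.decoding_permutation_test(fm, n_perm=99, seed=0)
        assert res.observed == pytest.approx(100.0)
        assert res.p_value == pytest.approx(1 / 99)
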