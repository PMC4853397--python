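"""Model selection and significance machinery for the three-task decoding.

Implements the nested cross-validation over the (m0, gamma0) grid used for
cortical-current decoding (10 outer test groups, 9 inner train/validate
rotations per grid pair, 5 repetitions with reshuffled groups), the 5 x 10-fold
repeated CV used for sensor baselines, label-permutation significance with
p = (count_ge + 1) / n_perm, classification output ratios per task, and a
one-way ANOVA for comparing ratio groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .exceptions import InvalidConfigurationError, InvalidInputError
from .features import FeatureMatrix, FeatureScaler, extract_features
from .inverse import (
    HYPER_GRID,
    HierarchicalCurrentModel,
    HyperParams,
    NoiseModel,
    WindowSpec,
    estimate_noise,
)
from .priors import PriorSet
from .simulate import TASKS, EpochedEEG, SourceModel
from .smlr import SMLRResults, fit_smlr


@dataclass
class CVReport:
    """Pooled cross-validation outcome."""

    accuracies: np.ndarray                 # per test fold, in percent
    selected: list = field(default_factory=list)   # HyperParams per outer fold
    confusion: np.ndarray | None = None    # 3 x 3 output-ratio matrix
    classes: tuple = TASKS
    n_repetitions: int = 1
    seed: int | None = None
    inner_records: list = field(default_factory=list)  # per-fold inner-loop tables
    models: list = field(default_factory=list)         # final SMLRResults per fold
    groups: list = field(default_factory=list)         # per-repetition group assignment

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def se(self) -> float:
        a = np.asarray(self.accuracies, dtype=float)
        return float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0

    def summary(self) -> str:
        lines = [
            "Cross-validation report",
            "=" * 40,
            f"folds                {len(self.accuracies)} "
            f"({self.n_repetitions} repetition(s))",
            f"mean accuracy        {self.mean:.1f}% +/- {self.se:.1f}% (SE)",
        ]
        if self.selected:
            pairs = [(h.m0, h.gamma0) for h in self.selected if h is not None]
            if pairs:
                lines.append(f"selected (m0,g0)     {pairs}")
        if self.confusion is not None:
            lines.append("output ratios (rows=true task):")
            for t, row in zip(self.classes, self.confusion):
                lines.append(
                    f"  {t:>4}: " + "  ".join(f"{v:.3f}" for v in row)
                )
        return "\n".join(lines)


@dataclass
class PermutationResult:
    """Label-permutation significance for an observed statistic."""

    observed: float
    n_permutations: int
    count_ge: int
    p_value: float
    null_values: np.ndarray | None = None


def confusion_ratios(y_true, y_pred, classes=TASKS) -> np.ndarray:
    """Row t, column c: fraction of task-t trials classified as c."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("label vectors must have equal length")
    classes = list(classes)
    for arr in (y_true, y_pred):
        bad = set(arr.tolist()) - set(classes)
        if bad:
            raise InvalidInputError(f"labels outside class set: {bad}")
    mat = np.zeros((len(classes), len(classes)))
    for i, t in enumerate(classes):
        sel = y_true == t
        if sel.any():
            for j, c in enumerate(classes):
                mat[i, j] = np.mean(y_pred[sel] == c)
    return mat


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise InvalidInputError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    N = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df1, df2 = k - 1, N - k
    msb, msw = ssb / df1, ssw / df2
    if msw == 0:
        if msb == 0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    F = msb / msw
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def permutation_pvalue(observed: float, null_fn, n_perm: int,
                       seed: int = 0, keep_null: bool = False) -> PermutationResult:
    """p = (count_ge + 1) / n_perm, clamped to <= 1.

    ``null_fn(rng)`` recomputes the statistic under one label permutation; the
    smallest attainable p is 1/n_perm (an observed value exceeding every
    permuted value).
    """
    if n_perm < 1:
        raise InvalidConfigurationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        nulls[i] = null_fn(rng)
    count_ge = int(np.sum(nulls >= observed))
    p = min((count_ge + 1) / n_perm, 1.0)
    return PermutationResult(
        observed=float(observed), n_permutations=n_perm, count_ge=count_ge,
        p_value=p, null_values=nulls if keep_null else None,
    )


def _accuracy(model: SMLRResults, X, y) -> float:
    _, pred = model.predict(X)
    return 100.0 * float(np.mean(pred == y))


def _fit_predict(X_train, y_train, X_test, smlr_config) -> tuple[SMLRResults, np.ndarray]:
    scaler = FeatureScaler().fit(X_train)
    model = fit_smlr(scaler.transform(X_train), y_train, **smlr_config)
    _, pred = model.predict(scaler.transform(X_test))
    return model, pred


def repeated_kfold(
    features: FeatureMatrix,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    smlr_config: dict | None = None,
    shuffle_labels: bool = False,
) -> CVReport:
    """Stratified k-fold CV repeated with reshuffled folds; accuracies pooled.

    ``shuffle_labels=True`` permutes the *training* labels within each fold
    (the RandLOOgroup-style null) while test labels stay intact.
    """
    smlr_config = smlr_config or {}
    X, y = features.X, np.asarray(features.labels)
    if k > X.shape[0]:
        raise InvalidConfigurationError(f"k={k} exceeds {X.shape[0]} trials")
    rng = np.random.default_rng(seed)
    accs, true_all, pred_all, models = [], [], [], []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for train_idx, test_idx in skf.split(X, y):
            y_train = y[train_idx]
            if shuffle_labels:
                y_train = y_train[rng.permutation(y_train.size)]
            model, pred = _fit_predict(X[train_idx], y_train, X[test_idx], smlr_config)
            accs.append(100.0 * float(np.mean(pred == y[test_idx])))
            true_all.append(y[test_idx])
            pred_all.append(pred)
            models.append(model)
    classes = tuple(np.unique(y))
    conf = confusion_ratios(np.concatenate(true_all), np.concatenate(pred_all), classes)
    return CVReport(
        accuracies=np.array(accs), confusion=conf, classes=classes,
        n_repetitions=repeats, seed=seed, models=models,
    )


class DecodingPipeline:
    """Bundles the source-space decoding stages behind one feature factory.

    Given a hyper-parameter pair and the trials allowed to inform the inverse
    filter, it fits the hierarchical Bayesian variance model on those trials
    only, reconstructs current time courses for *all* trials with the
    resulting filters, and returns the binned time-point features. Inverse
    fits are cached on (hyper, fit trials) because filters depend on trials,
    not labels.
    """

    def __init__(
        self,
        epochs: EpochedEEG,
        source: SourceModel,
        prior: PriorSet,
        reduced_ids=None,
        windows: WindowSpec | None = None,
        noise: NoiseModel | None = None,
        feature_window=(1.0, 2.0),
        bin_size: int = 8,
        reconstruct_range=None,
        vb_tol: float = 1e-4,
        vb_max_iter: int = 100,
    ):
        self.epochs = epochs
        self.source = source
        self.prior = prior
        self.reduced_ids = reduced_ids
        self.windows = windows or WindowSpec()
        # None -> each inverse fit estimates noise from its own training
        # trials (leakage-free); a shared NoiseModel may be supplied instead
        self.noise = noise
        self.feature_window = feature_window
        self.bin_size = bin_size
        if reconstruct_range is None:
            lo, hi = self.windows.t_range
            reconstruct_range = (max(0.5, lo), hi)
        self.reconstruct_range = reconstruct_range
        self.vb_tol = vb_tol
        self.vb_max_iter = vb_max_iter
        self._cache: dict = {}
        self.labels = np.asarray(epochs.labels)

    def current_features(self, hyper: HyperParams, fit_idx) -> FeatureMatrix:
        """Features for all trials from filters fitted on ``fit_idx`` trials."""
        key = (hyper.m0, hyper.gamma0, tuple(np.sort(np.asarray(fit_idx))))
        if key not in self._cache:
            model = HierarchicalCurrentModel(
                self.epochs, self.source, self.prior, hyper,
                windows=self.windows, noise=self.noise,
                reduced_ids=self.reduced_ids,
                tol=self.vb_tol, max_iter=self.vb_max_iter,
            )
            res = model.fit(trial_idx=np.asarray(fit_idx))
            currents = res.reconstruct(t_range=self.reconstruct_range)
            onset_in_range = self.epochs.onset_index - (
                self.epochs.onset_index
                + int(round(self.reconstruct_range[0] * self.epochs.fs))
            )
            feats = extract_features(
                currents, labels=self.labels, fs=self.epochs.fs,
                onset_index=onset_in_range, window=self.feature_window,
                bin_size=self.bin_size,
                channel_names=[f"v{v}" for v in res.vertices],
                channel_kind="vertex",
            )
            self._cache[key] = feats
        return self._cache[key]


def _make_groups(labels: np.ndarray, n_groups: int, rng) -> np.ndarray:
    """Assign each trial a group id; groups are balanced across tasks."""
    group = np.empty(labels.size, dtype=int)
    for task in np.unique(labels):
        idx = np.flatnonzero(labels == task)
        if idx.size % n_groups:
            raise InvalidInputError(
                f"{idx.size} trials of task {task} not divisible into {n_groups} groups"
            )
        perm = rng.permutation(idx)
        group[perm] = np.repeat(np.arange(n_groups), idx.size // n_groups)
    return group


def nested_cv(
    pipeline: DecodingPipeline,
    grid: list[HyperParams] | None = None,
    n_groups: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
    filter_scope: str = "inner",
    smlr_config: dict | None = None,
    shuffle_train_labels: bool = False,
) -> CVReport:
    """Nested cross-validation over the hyper-parameter grid.

    Per outer fold (one held-out test group): for every grid pair, rotate a
    validation group through the remaining 9 groups (train on 8, validate on
    1), select the pair with the highest mean validation accuracy (ties break
    toward smaller m0, then gamma0), retrain on all 9 non-test groups and
    score the test group. The whole procedure repeats ``n_repeats`` times with
    reshuffled groups and pools the test accuracies.

    ``filter_scope`` controls where inverse filters are fitted: ``"inner"``
    (conforming) refits on each rotation's 8 training groups; ``"outer"``
    (fast, non-conforming approximation) fits once per grid pair on all 9
    non-test groups. Neither uses held-out test trials.
    ``shuffle_train_labels`` permutes training labels everywhere (the
    RandLOOgroup condition) while test labels stay intact.
    """
    if grid is None:
        grid = HYPER_GRID
    if not grid:
        raise InvalidConfigurationError("empty hyper-parameter grid")
    if filter_scope not in ("inner", "outer"):
        raise InvalidConfigurationError(f"unknown filter_scope {filter_scope!r}")
    smlr_config = smlr_config or {}
    labels = pipeline.labels
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() != counts.max():
        raise InvalidInputError("unbalanced classes")
    rng = np.random.default_rng(seed)
    accs, selected, inner_records = [], [], []
    true_all, pred_all, models, groups = [], [], [], []
    for rep in range(n_repeats):
        group = _make_groups(labels, n_groups, rng)
        groups.append(group)
        for test_g in range(n_groups):
            test_idx = np.flatnonzero(group == test_g)
            inner_groups = [g for g in range(n_groups) if g != test_g]
            inner_idx = np.flatnonzero(group != test_g)
            perm_labels = labels.copy()
            if shuffle_train_labels:
                perm_labels[inner_idx] = perm_labels[
                    inner_idx[rng.permutation(inner_idx.size)]
                ]
            inner_acc = np.zeros((len(grid), len(inner_groups)))
            for gi, hyper in enumerate(grid):
                if filter_scope == "outer":
                    feats = pipeline.current_features(hyper, inner_idx)
                for vi, val_g in enumerate(inner_groups):
                    train_idx = np.flatnonzero((group != test_g) & (group != val_g))
                    val_idx = np.flatnonzero(group == val_g)
                    if filter_scope == "inner":
                        feats = pipeline.current_features(hyper, train_idx)
                    _, pred = _fit_predict(
                        feats.X[train_idx], perm_labels[train_idx],
                        feats.X[val_idx], smlr_config,
                    )
                    inner_acc[gi, vi] = 100.0 * float(
                        np.mean(pred == perm_labels[val_idx])
                    )
            best = int(np.argmax(inner_acc.mean(axis=1)))  # grid sorted small->large
            hyper = grid[best]
            feats = pipeline.current_features(hyper, inner_idx)
            model, pred = _fit_predict(
                feats.X[inner_idx], perm_labels[inner_idx],
                feats.X[test_idx], smlr_config,
            )
            accs.append(100.0 * float(np.mean(pred == labels[test_idx])))
            selected.append(hyper)
            inner_records.append(
                {"repeat": rep, "test_group": test_g, "inner_accuracy": inner_acc}
            )
            true_all.append(labels[test_idx])
            pred_all.append(pred)
            models.append(model)
    conf = confusion_ratios(
        np.concatenate(true_all), np.concatenate(pred_all), tuple(classes)
    )
    return CVReport(
        accuracies=np.array(accs), selected=selected, confusion=conf,
        classes=tuple(classes), n_repetitions=n_repeats, seed=seed,
        inner_records=inner_records, models=models, groups=groups,
    )


def decoding_permutation_test(
    features: FeatureMatrix,
    n_perm: int = 10000,
    seed: int = 0,
    test_fraction: float = 0.3,
    smlr_config: dict | None = None,
    observed: float | None = None,
) -> PermutationResult:
    """Label-permutation significance of a decoding accuracy.

    The statistic is the held-out accuracy of a classifier trained on a fixed
    stratified split; each permutation shuffles the training labels and
    retrains. Feature extraction (and any inverse filtering that produced the
    features) is label-free, so it is computed once and shared across
    permutations. When ``observed`` is omitted it is computed from the
    unpermuted labels first.
    """
    smlr_config = dict(smlr_config or {})
    smlr_config.setdefault("max_iter", 12)
    X, y = features.X, np.asarray(features.labels)
    rng = np.random.default_rng(seed)
    # fixed stratified split
    test_idx = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        n_test = max(1, int(round(test_fraction * idx.size)))
        test_idx.append(rng.permutation(idx)[:n_test])
    test_idx = np.sort(np.concatenate(test_idx))
    train_idx = np.setdiff1d(np.arange(y.size), test_idx)
    scaler = FeatureScaler().fit(X[train_idx])
    Xtr, Xte = scaler.transform(X[train_idx]), scaler.transform(X[test_idx])

    def run(y_train) -> float:
        model = fit_smlr(Xtr, y_train, **smlr_config)
        _, pred = model.predict(Xte)
        return 100.0 * float(np.mean(pred == y[test_idx]))

    if observed is None:
        observed = run(y[train_idx])

    def null_fn(r):
        return run(y[train_idx][r.permutation(train_idx.size)])

    return permutation_pvalue(observed, null_fn, n_perm,
                              seed=int(rng.integers(2**31 - 1)))
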