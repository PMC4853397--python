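"""Hierarchical Bayesian estimation of cortical current variances and inverse filters.

Observation model per analysis window: B_t = G J_t + eps, eps ~ N(0, Sigma_noise),
J_t ~ N(0, diag(nu)). The per-vertex current variances nu carry a conjugate
prior whose mean nu0 is set from the fMRI activity prior,

    nu0_v = nu_base * (1 + (m0 - 1) * that_v),

where ``that_v`` is the normalized activity value (0 off the fMRI activation,
1 at its peak), ``m0`` magnifies prior variance at fMRI-active vertices, and
the reliability ``gamma0`` controls how strongly the variance estimate is
pinned to nu0. The variational fixed point alternates the Gaussian posterior
of the currents with the conjugate variance update

    nu_v <- [ sum_t Jhat_v,t^2 + T*K*S_vv + 2*gamma0*nu0_v ] / (T*K + 2*gamma0).

A large gamma0 therefore returns nu = nu0 (prior-dominated limit); gamma0 -> 0
gives the data-driven variance. The converged variances define the inverse
filter W = A G' (G A G' + Sigma_noise)^-1 used to reconstruct single-trial
current time courses, stitched across the sliding windows by linear
cross-fade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import (
    InvalidConfigurationError,
    InvalidInputError,
    NoSourceError,
    NumericalError,
)
from .priors import PriorSet
from .simulate import EpochedEEG, SourceModel


@dataclass(frozen=True)
class HyperParams:
    """Prior variance magnification m0 and prior reliability gamma0."""

    m0: float = 10.0
    gamma0: float = 1.0

    def __post_init__(self):
        if self.m0 <= 0 or self.gamma0 <= 0:
            raise InvalidConfigurationError("m0 and gamma0 must be positive")


#: The 3 x 3 hyper-parameter grid searched by the nested cross-validation,
#: ordered so that ties resolve toward smaller (m0, gamma0).
HYPER_GRID: list[HyperParams] = [
    HyperParams(m0, g0) for m0 in (10.0, 100.0, 1000.0) for g0 in (1.0, 10.0, 100.0)
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis windows: default -0.5..3 s, 0.5 s long, 0.25 s shift."""

    t_range: tuple = (-0.5, 3.0)
    window: float = 0.5
    shift: float = 0.25

    def __post_init__(self):
        lo, hi = self.t_range
        if self.shift > self.window or self.shift <= 0:
            raise InvalidConfigurationError("need 0 < shift <= window")
        span = hi - lo - self.window
        n = span / self.shift
        if span < -1e-9 or abs(n - round(n)) > 1e-9:
            raise InvalidConfigurationError("windows must tile the analysis range")

    @property
    def n_windows(self) -> int:
        lo, hi = self.t_range
        return int(round((hi - lo - self.window) / self.shift)) + 1

    def starts(self) -> np.ndarray:
        return self.t_range[0] + self.shift * np.arange(self.n_windows)

    def sample_slices(self, fs: float, onset_index: int, n_samples: int):
        """Per-window (start, stop) sample indices into an epoch array."""
        slices = []
        for a in self.starts():
            s0 = onset_index + int(round(a * fs))
            s1 = onset_index + int(round((a + self.window) * fs))
            if s0 < 0 or s1 > n_samples:
                raise InvalidConfigurationError(
                    f"window {a:.3g}..{a + self.window:.3g} s outside the epoch"
                )
            slices.append((s0, s1))
        return slices


@dataclass
class NoiseModel:
    """Sensor noise: scalar scale sigma2 and (loaded) covariance Sigma_s.

    ``Sigma_s`` is the pooled baseline covariance after diagonal loading and is
    used directly as the observation noise covariance; ``sigma2`` (its mean
    diagonal) is the scalar scale quoted in diagnostics.
    """

    sigma2: float
    Sigma_s: np.ndarray

    @classmethod
    def isotropic(cls, sigma2: float, n_sensors: int) -> "NoiseModel":
        return cls(sigma2=sigma2, Sigma_s=sigma2 * np.eye(n_sensors))


def estimate_noise(epochs: EpochedEEG, baseline=(-1.0, -0.5)) -> NoiseModel:
    """Pooled across-trial covariance of baseline samples, diagonally loaded.

    The default baseline (-1.0..-0.5 s) precedes the analysis range so noise
    statistics never overlap the estimated windows.
    """
    b0, b1 = baseline
    if b1 <= b0:
        raise InvalidConfigurationError("baseline end must exceed start")
    fs, onset = epochs.fs, epochs.onset_index
    i0 = onset + int(round(b0 * fs))
    i1 = onset + int(round(b1 * fs))
    if i0 < 0 or i1 > epochs.n_samples or i1 > onset:
        raise InvalidConfigurationError("baseline must lie inside the pre-onset interval")
    if i1 - i0 < 2:
        raise InvalidConfigurationError("baseline shorter than 2 samples")
    X = epochs.data[:, :, i0:i1]                       # (trials, sensors, samples)
    n_sensors = X.shape[1]
    pooled = np.swapaxes(X, 0, 1).reshape(n_sensors, -1)
    pooled = pooled - pooled.mean(axis=1, keepdims=True)
    n = pooled.shape[1]
    Sigma = pooled @ pooled.T / (n - 1)
    loading = max(1e-6 * np.trace(Sigma) / n_sensors, 1e-12)
    Sigma = Sigma + loading * np.eye(n_sensors)
    return NoiseModel(sigma2=float(np.mean(np.diag(Sigma))), Sigma_s=Sigma)


def reduce_dipoles(source: SourceModel, ratio: float = 0.2, seed: int = 0) -> np.ndarray:
    """Retain ceil(ratio * n_vertices) vertices, stratified uniformly within ROIs.

    Per-ROI quotas are floor(ratio * size) with the remainder assigned by
    largest fractional part (ties toward earlier ROIs); selection within a ROI
    is a seeded uniform draw without replacement. Deterministic under seed.
    """
    if not 0 < ratio <= 1:
        raise InvalidConfigurationError(f"ratio must be in (0, 1], got {ratio}")
    n = source.n_vertices
    target = math.ceil(ratio * n)
    rng = np.random.default_rng(seed)
    rois, first_pos = np.unique(source.roi_labels, return_index=True)
    rois = rois[np.argsort(first_pos)]  # stable ROI order
    members = {r: np.flatnonzero(source.roi_labels == r) for r in rois}
    quota = {r: int(ratio * members[r].size) for r in rois}
    frac = sorted(
        rois,
        key=lambda r: (-(ratio * members[r].size - quota[r]), list(rois).index(r)),
    )
    short = target - sum(quota.values())
    for r in frac:
        if short <= 0:
            break
        if quota[r] < members[r].size:
            quota[r] += 1
            short -= 1
    picked = []
    for r in rois:
        k = min(quota[r], members[r].size)
        if k:
            picked.append(np.sort(rng.choice(members[r], size=k, replace=False)))
    out = np.sort(np.concatenate(picked)) if picked else np.array([], dtype=int)
    # rounding guard: top up from unpicked vertices if quotas undershoot
    if out.size < target:
        rest = np.setdiff1d(np.arange(n), out)
        extra = np.sort(rng.choice(rest, size=target - out.size, replace=False))
        out = np.sort(np.concatenate([out, extra]))
    return out


def _nu_base(epochs: EpochedEEG, G: np.ndarray, noise: NoiseModel,
             windows: WindowSpec, trial_idx) -> float:
    """Baseline current variance: match expected to observed sensor power.

    nu_base = (mean sensor variance over the analysis range - noise power)
    divided by the mean squared column norm of G, floored at 1e-12.
    """
    slices = windows.sample_slices(epochs.fs, epochs.onset_index, epochs.n_samples)
    s0, s1 = slices[0][0], slices[-1][1]
    X = epochs.data[trial_idx][:, :, s0:s1]
    sensor_var = float(np.mean(X**2))
    noise_power = float(np.mean(np.diag(noise.Sigma_s)))
    colnorm2 = float(np.mean(np.sum(G**2, axis=0)))
    return max((sensor_var - noise_power) / colnorm2, 1e-12)


def _vb_window(B: np.ndarray, G: np.ndarray, Sigma_noise: np.ndarray,
               nu0: np.ndarray, gamma0: float, tol: float, max_iter: int):
    """Fixed-point variance update for one window's pooled samples."""
    n_samp = B.shape[1]
    nu = nu0.copy()
    n_iter = 0
    converged = False
    BB = B  # (sensors, T*K)
    for n_iter in range(1, max_iter + 1):
        GA = G * nu                     # (s, v) = G diag(nu)
        SigmaB = GA @ G.T + Sigma_noise
        try:
            cho = linalg.cho_factor(SigmaB, lower=True)
        except linalg.LinAlgError as exc:
            raise NumericalError(f"system matrix not positive definite: {exc}") from exc
        M = linalg.cho_solve(cho, GA)   # Sigma_B^-1 G A, (s, v)
        J = M.T @ BB                    # posterior means, (v, T*K)
        S_diag = nu - np.einsum("sv,sv->v", GA, M)
        nu_new = (np.sum(J**2, axis=1) + n_samp * S_diag + 2 * gamma0 * nu0) / (
            n_samp + 2 * gamma0
        )
        nu_new = np.maximum(nu_new, 0.0)
        denom = np.maximum(np.abs(nu), 1e-300)
        if np.max(np.abs(nu_new - nu) / denom) < tol:
            nu = nu_new
            converged = True
            break
        nu = nu_new
    return nu, n_iter, converged


def vb_estimate(
    epochs: EpochedEEG,
    G: np.ndarray,
    activity: np.ndarray,
    noise: NoiseModel,
    hyper: HyperParams,
    windows: WindowSpec | None = None,
    trial_idx=None,
    tol: float = 1e-4,
    max_iter: int = 100,
    nu_base: float | None = None,
):
    """Per-window current variances for a lead field restricted to the prior area.

    ``activity`` aligns with the columns of ``G`` (normalized t-values in
    [0, 1]). Returns (nu, nu0, info) with nu of shape (n_windows, n_vertices).
    """
    if windows is None:
        windows = WindowSpec()
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise NoSourceError("empty restricted lead field")
    activity = np.asarray(activity, dtype=float)
    if activity.shape != (G.shape[1],):
        raise InvalidInputError("activity must align with lead-field columns")
    trial_idx = np.arange(epochs.n_trials) if trial_idx is None else np.asarray(trial_idx)
    if trial_idx.size == 0:
        raise NoSourceError("no training trials")
    if nu_base is None:
        nu_base = _nu_base(epochs, G, noise, windows, trial_idx)
    nu0 = nu_base * (1.0 + (hyper.m0 - 1.0) * activity)
    slices = windows.sample_slices(epochs.fs, epochs.onset_index, epochs.n_samples)
    nu = np.empty((len(slices), G.shape[1]))
    info = {"n_iter": [], "converged": [], "nu_base": nu_base}
    for w, (s0, s1) in enumerate(slices):
        B = np.swapaxes(epochs.data[trial_idx][:, :, s0:s1], 0, 1).reshape(
            G.shape[0], -1
        )
        nu_w, it, conv = _vb_window(B, G, noise.Sigma_s, nu0, hyper.gamma0, tol, max_iter)
        nu[w] = nu_w
        info["n_iter"].append(it)
        info["converged"].append(conv)
    return nu, nu0, info


def build_inverse_filter(nu: np.ndarray, G: np.ndarray, noise: NoiseModel | None) -> np.ndarray:
    """W = A G' (G A G' + Sigma_noise)^-1 with A = diag(nu).

    ``nu`` may be one window's vector or a (n_windows, n_vertices) stack; the
    result has matching leading shape with filters (n_vertices, n_sensors).
    A vertex with nu = 0 gets an all-zero filter row.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.ndim == 2:
        return np.stack([build_inverse_filter(v, G, noise) for v in nu])
    Sigma_noise = 0.0 if noise is None else noise.Sigma_s
    GA = G * nu
    SigmaB = GA @ G.T + Sigma_noise
    try:
        W = linalg.solve(SigmaB, GA, assume_a="pos").T
    except linalg.LinAlgError as exc:
        raise NumericalError(f"singular inverse-filter system: {exc}") from exc
    return W


def reconstruct_currents(
    filters: np.ndarray,
    window_slices,
    epochs: EpochedEEG,
    t_range=(0.5, 3.0),
) -> np.ndarray:
    """Stitch per-window reconstructions W_w B into trial current time courses.

    Each output sample is the linear cross-fade of the reconstructions of the
    windows covering it, with weights proportional to the distance from the
    window edges (a partition of unity). Returns (trials, vertices, samples)
    over ``t_range``.
    """
    fs, onset = epochs.fs, epochs.onset_index
    o0 = onset + int(round(t_range[0] * fs))
    o1 = onset + int(round(t_range[1] * fs))
    o1 = min(o1, epochs.n_samples)
    starts = np.array([s0 for s0, _ in window_slices])
    stops = np.array([s1 for _, s1 in window_slices])
    if o0 < starts.min() or o1 > stops.max():
        raise InvalidConfigurationError("output range not covered by the windows")
    n_out = o1 - o0
    n_trials = epochs.n_trials
    n_vert = filters.shape[1]
    out = np.zeros((n_trials, n_vert, n_out))
    wsum = np.zeros(n_out)
    samples = np.arange(o0, o1)
    for w, (s0, s1) in enumerate(window_slices):
        lo, hi = max(s0, o0), min(s1, o1)
        if lo >= hi:
            continue
        rec = np.einsum("vs,tsn->tvn", filters[w], epochs.data[:, :, lo:hi])
        sw = samples[(samples >= lo) & (samples < hi)]
        weight = np.minimum(sw - s0 + 1, s1 - sw).astype(float)
        out[:, :, lo - o0:hi - o0] += rec * weight
        wsum[lo - o0:hi - o0] += weight
    if np.any(wsum == 0):
        raise InvalidConfigurationError("output range has uncovered samples")
    out /= wsum
    return out


class HierarchicalCurrentModel:
    """fMRI-prior-informed hierarchical Bayesian source model for epoched EEG.

    Parameters
    ----------
    epochs : EpochedEEG
        Sensor data (all trials; `fit` may restrict to a training subset).
    source : SourceModel
        Source space with lead field.
    prior : PriorSet
        Area/activity prior; only area vertices are modelled.
    hyper : HyperParams
        (m0, gamma0) pair.
    reduced_ids : array, optional
        Vertex ids surviving dipole reduction; the model is restricted to
        ``prior.area`` intersected with these.
    reduction_ratio : float, optional
        Alternative to ``reduced_ids``: run `reduce_dipoles` at this ratio.
    """

    def __init__(
        self,
        epochs: EpochedEEG,
        source: SourceModel,
        prior: PriorSet,
        hyper: HyperParams = HyperParams(),
        windows: WindowSpec | None = None,
        noise: NoiseModel | None = None,
        reduced_ids=None,
        reduction_ratio: float | None = None,
        seed: int = 0,
        tol: float = 1e-4,
        max_iter: int = 100,
    ):
        if source.lead_field is None:
            raise InvalidInputError("source model has no lead field")
        self.epochs = epochs
        self.source = source
        self.prior = prior
        self.hyper = hyper
        self.windows = windows or WindowSpec()
        self.tol = tol
        self.max_iter = max_iter
        if reduced_ids is None and reduction_ratio is not None:
            reduced_ids = reduce_dipoles(source, reduction_ratio, seed)
        if reduced_ids is None:
            reduced_ids = np.arange(source.n_vertices)
        self.vertices = np.intersect1d(prior.area, reduced_ids)
        if self.vertices.size == 0:
            raise NoSourceError(
                f"prior {prior.condition!r} leaves no vertices to estimate"
            )
        self.G = source.lead_field[:, self.vertices]
        self.activity = prior.activity_full()[self.vertices]
        # noise left unset is estimated in fit() from the training trials
        # only, so held-out trials never inform the noise covariance
        self.noise = noise

    def fit(self, trial_idx=None) -> "HierarchicalCurrentResults":
        """Estimate per-window variances on the given trials and build filters."""
        noise = self.noise
        if noise is None:
            sub = self.epochs if trial_idx is None else EpochedEEG(
                data=self.epochs.data[np.asarray(trial_idx)],
                labels=np.asarray(self.epochs.labels)[np.asarray(trial_idx)],
                fs=self.epochs.fs, onset_index=self.epochs.onset_index,
                sensor_names=self.epochs.sensor_names,
            )
            noise = estimate_noise(sub)
        nu, nu0, info = vb_estimate(
            self.epochs, self.G, self.activity, noise, self.hyper,
            self.windows, trial_idx, self.tol, self.max_iter,
        )
        info["sigma2"] = noise.sigma2
        filters = build_inverse_filter(nu, self.G, noise)
        slices = self.windows.sample_slices(
            self.epochs.fs, self.epochs.onset_index, self.epochs.n_samples
        )
        return HierarchicalCurrentResults(self, nu, nu0, filters, slices, info)


@dataclass
class HierarchicalCurrentResults:
    """Fitted variances, filters and reconstruction for a hyper-parameter pair."""

    model: HierarchicalCurrentModel
    nu: np.ndarray            # (n_windows, n_vertices)
    nu0: np.ndarray           # prior variance means
    filters: np.ndarray       # (n_windows, n_vertices, n_sensors)
    window_slices: list = field(default_factory=list)
    info: dict = field(default_factory=dict)

    @property
    def vertices(self) -> np.ndarray:
        """Global vertex ids of the estimated dipoles."""
        return self.model.vertices

    def reconstruct(self, epochs: EpochedEEG | None = None, t_range=(0.5, 3.0)) -> np.ndarray:
        """Current time courses (trials x vertices x samples) over ``t_range``."""
        epochs = epochs or self.model.epochs
        return reconstruct_currents(self.filters, self.window_slices, epochs, t_range)

    def summary(self) -> str:
        h = self.model.hyper
        w = self.model.windows
        lines = [
            "Hierarchical Bayesian cortical current estimate",
            "=" * 48,
            f"hyper-parameters     m0={h.m0:g}  gamma0={h.gamma0:g}",
            f"windows              {w.n_windows} x {w.window:g}s (shift {w.shift:g}s) "
            f"over {w.t_range[0]:g}..{w.t_range[1]:g}s",
            f"vertices estimated   {self.vertices.size}",
            f"noise scale sigma2   {self.info.get('sigma2', float('nan')):.4g}",
            f"nu_base              {self.info.get('nu_base', float('nan')):.4g}",
            f"VB iterations        {self.info.get('n_iter', [])}",
            f"mean nu per window   {np.array2string(self.nu.mean(axis=1), precision=3)}",
        ]
        top = self.vertices[np.argsort(self.nu.max(axis=0))[::-1][:5]]
        lines.append(f"top-variance vertices {top.tolist()}")
        return "\n".join(lines)
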