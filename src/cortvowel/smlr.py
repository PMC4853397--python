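"""Sparse multinomial logistic regression with automatic relevance determination.

The classifier is a softmax model with one weight vector per class and a
per-weight Gaussian prior w_ck ~ N(0, 1/alpha_ck). Training alternates

  (i)  a simultaneous per-class block-Newton step on the penalized multinomial
       log-likelihood (all class steps computed from the current weights, then
       applied with a shared backtracking factor, which keeps the update exactly
       symmetric under class relabelling and the penalized likelihood monotone);
  (ii) the MacKay evidence fixed point alpha_ck <- (1 - alpha_ck * S_ck) / w_ck^2
       with S_ck the corresponding diagonal of the inverse block Hessian.

Weights whose precision exceeds ``prune_threshold`` are clamped to exactly zero
and removed permanently, which is what makes the classifier sparse. The bias of
each class carries a tiny fixed ridge instead of an ARD precision and is never
pruned. When there are more active features than trials, the Newton step and
the inverse-Hessian diagonal are computed through the Woodbury identity so the
cost stays O(n^2 d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import InvalidInputError

_BIAS_RIDGE = 1e-6
_ALPHA_INIT = 1.0
_ALPHA_MAX = 1e12


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


@dataclass
class SMLRResults:
    """Fitted sparse multinomial logistic model.

    ``weights`` is (n_classes, n_features + 1) with the bias last;
    ``ard_precisions`` has the same shape; ``active_mask`` marks weights that
    survived pruning (pruned weights are exactly zero).
    """

    weights: np.ndarray
    ard_precisions: np.ndarray
    active_mask: np.ndarray
    classes: np.ndarray
    n_iter: int = 0
    converged: bool = False
    ll_trace: list = field(default_factory=list)   # penalized LL after each sweep
    ll_sweeps: list = field(default_factory=list)  # (before, after) at fixed alpha

    @property
    def n_features(self) -> int:
        return self.weights.shape[1] - 1

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise InvalidInputError(
                f"expected {self.n_features} features, got {X.shape}"
            )
        Z = X @ self.weights[:, :-1].T + self.weights[:, -1]
        return _softmax(Z)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, labels); argmax ties resolve to the earlier class."""
        proba = self.predict_proba(X)
        return proba, self.classes[np.argmax(proba, axis=1)]

    def feature_sparsity(self) -> float:
        """Fraction of feature weights pruned (bias excluded)."""
        return 1.0 - self.active_mask[:, :-1].mean()

    def summary(self) -> str:
        kept = int(self.active_mask[:, :-1].sum())
        total = self.active_mask[:, :-1].size
        lines = [
            "Sparse multinomial logistic regression (ARD)",
            "=" * 46,
            f"classes              {list(self.classes)}",
            f"features             {self.n_features}",
            f"iterations           {self.n_iter} (converged={self.converged})",
            f"active weights       {kept}/{total} "
            f"({100 * (1 - self.feature_sparsity()):.1f}% kept)",
            f"final penalized LL   {self.ll_trace[-1]:.4f}" if self.ll_trace else "",
        ]
        per_class = self.active_mask[:, :-1].sum(axis=1)
        for c, k in zip(self.classes, per_class):
            lines.append(f"  class {c}: {int(k)} active features")
        return "\n".join(line for line in lines if line)


class SparseMultinomialLogit:
    """Softmax classifier with per-weight ARD pruning.

    Parameters
    ----------
    X : (n_trials, n_features) array
    y : (n_trials,) labels; at least two classes, two trials per class.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, classes=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InvalidInputError("X must be trials x features aligned with y")
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("non-finite feature values")
        self.classes = np.unique(y) if classes is None else np.asarray(classes)
        if self.classes.size < 2:
            raise InvalidInputError("need at least two classes")
        counts = np.array([(y == c).sum() for c in self.classes])
        if (counts < 2).any():
            raise InvalidInputError("need >= 2 trials per class")
        self.X = X
        self.y = y
        self.Y = (y[:, None] == self.classes[None, :]).astype(float)

    def _penalized_ll(self, Xa, W, alpha) -> float:
        P = _softmax(Xa @ W.T)
        ll = float(np.sum(self.Y * np.log(np.maximum(P, 1e-300))))
        return ll - 0.5 * float(np.sum(alpha * W**2))

    def fit(self, max_iter: int = 200, tol: float = 1e-5,
            prune_threshold: float = 1e8) -> SMLRResults:
        n, d = self.X.shape
        C = self.classes.size
        Xa = np.column_stack([self.X, np.ones(n)])
        W = np.zeros((C, d + 1))
        alpha = np.full((C, d + 1), _ALPHA_INIT)
        alpha[:, -1] = _BIAS_RIDGE
        active = np.ones((C, d + 1), dtype=bool)
        ll_trace = []
        ll_sweeps = []
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            P = _softmax(Xa @ W.T)
            steps = np.zeros_like(W)
            sigma_diag = np.zeros_like(W)
            for c in range(C):
                idx = np.flatnonzero(active[c])
                Xc = Xa[:, idx]
                lam = P[:, c] * (1 - P[:, c])
                g = Xc.T @ (self.Y[:, c] - P[:, c]) - alpha[c, idx] * W[c, idx]
                a = np.maximum(alpha[c, idx], 1e-12)
                if idx.size <= n:
                    H = (Xc.T * lam) @ Xc + np.diag(a)
                    try:
                        cho = linalg.cho_factor(H)
                        steps[c, idx] = linalg.cho_solve(cho, g)
                        sigma_diag[c, idx] = np.diag(
                            linalg.cho_solve(cho, np.eye(idx.size))
                        )
                    except linalg.LinAlgError:
                        steps[c, idx] = np.linalg.lstsq(H, g, rcond=None)[0]
                        sigma_diag[c, idx] = np.diag(np.linalg.pinv(H))
                else:
                    # Woodbury: (D + X' L X)^-1 with D = diag(a), L = diag(lam)
                    sl = np.sqrt(lam)
                    U = Xc * sl[:, None]               # (n, m)
                    V = U / a[None, :]                 # X D^-1 scaled
                    K = np.eye(n) + V @ U.T
                    cho = linalg.cho_factor(K)
                    ginv = g / a
                    steps[c, idx] = ginv - (V.T @ linalg.cho_solve(cho, V @ g))
                    KV = linalg.cho_solve(cho, V)
                    sigma_diag[c, idx] = 1.0 / a - np.einsum("nm,nm->m", V, KV)
            # shared backtracking keeps the update class-symmetric and monotone
            ll_old = self._penalized_ll(Xa, W, alpha)
            step_size = 1.0
            for _ in range(30):
                W_new = W + step_size * steps
                if self._penalized_ll(Xa, W_new, alpha) >= ll_old - 1e-10:
                    break
                step_size *= 0.5
            else:
                W_new = W
            max_change = float(np.max(np.abs(W_new - W))) if active.any() else 0.0
            W = W_new
            ll_new = self._penalized_ll(Xa, W, alpha)
            ll_sweeps.append((ll_old, ll_new))
            ll_trace.append(ll_new)
            # MacKay ARD update on active feature weights (bias ridge fixed)
            feat = active.copy()
            feat[:, -1] = False
            gamma = 1.0 - alpha * sigma_diag
            with np.errstate(divide="ignore", invalid="ignore"):
                new_alpha = np.where(
                    W**2 > 0, np.maximum(gamma, 1e-12) / np.maximum(W**2, 1e-300),
                    _ALPHA_MAX,
                )
            alpha[feat] = np.minimum(new_alpha[feat], _ALPHA_MAX)
            prune = feat & (alpha > prune_threshold)
            if prune.any():
                W[prune] = 0.0
                active[prune] = False
            if max_change < tol:
                converged = True
                break
        mask = active.copy()
        W = np.where(mask, W, 0.0)
        return SMLRResults(
            weights=W, ard_precisions=alpha, active_mask=mask,
            classes=self.classes, n_iter=n_iter, converged=converged,
            ll_trace=ll_trace, ll_sweeps=ll_sweeps,
        )


def fit_smlr(X, y, max_iter: int = 200, tol: float = 1e-5,
             prune_threshold: float = 1e8, classes=None) -> SMLRResults:
    """Functional wrapper around `SparseMultinomialLogit(...).fit(...)`."""
    return SparseMultinomialLogit(X, y, classes=classes).fit(
        max_iter=max_iter, tol=tol, prune_threshold=prune_threshold
    )


def predict(model: SMLRResults, X) -> tuple[np.ndarray, np.ndarray]:
    """(softmax probabilities, argmax labels) for a fitted model."""
    return model.predict(X)
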