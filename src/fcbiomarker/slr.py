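"""Sparse Bayesian logistic regression with automatic relevance determination.

The diagnostic label is modeled as P(y=1 | ẑ; w) = 1 / (1 + exp(−wᵀẑ)) with
ẑ = [zᵀ, 1]ᵀ the feature vector augmented by a constant bias input.  Each
weight carries an independent zero-mean Gaussian prior with its own
precision α_i; evidence maximization drives the precisions of irrelevant
features to infinity, pruning them from the model (automatic relevance
determination).  Estimation alternates a Laplace approximation of the
posterior at fixed α (Newton/IRLS with step halving) with the MacKay
fixed-point update α_i ← γ_i / μ_i², γ_i = 1 − α_i Σ_ii.

The weighted linear summation (WLS) wᵀẑ is the linear discriminant score:
positive → patient (label 1), negative → control (label 0); an exact zero
is resolved to control and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["SlrModel", "WlsScore", "fit_slr", "predict_proba", "wls"]

#: α above this prunes the corresponding feature weight to exactly zero.
PRUNE_THRESHOLD = 1e8
#: |w| cap guarding against separation-driven divergence.
WEIGHT_CAP = 1e3
#: fixed precision of the bias prior — effectively unpenalized; the bias is
#: exempt from relevance determination and can never be pruned.
BIAS_ALPHA = 1e-6


@dataclass
class SlrModel:
    """Fitted ARD logistic model over m features plus a bias.

    ``weights`` has length m+1 (bias last); pruned feature weights are
    exactly zero.  ``active_set`` lists the surviving feature indices
    (bias excluded — it is exempt from pruning).
    """

    weights: np.ndarray
    alpha: np.ndarray
    active_set: np.ndarray
    fit_log: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.weights.size - 1

    @property
    def bias(self) -> float:
        return float(self.weights[-1])

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.weights, dtype=np.float64).tobytes())
        h.update(np.ascontiguousarray(self.alpha, dtype=np.float64).tobytes())
        return h.hexdigest()

    def to_dict(self) -> dict:
        return {
            "schema": "slr-model/1",
            "weights": self.weights.tolist(),
            "alpha": self.alpha.tolist(),
            "active_set": self.active_set.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SlrModel":
        if d.get("schema") != "slr-model/1":
            raise ValueError(f"unsupported SLR model schema: {d.get('schema')!r}")
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            active_set=np.asarray(d["active_set"], dtype=int),
        )


@dataclass
class WlsScore:
    value: float
    label: int
    at_boundary: bool = False


def _penalized_newton(
    X: np.ndarray, y: np.ndarray, alpha: np.ndarray, w0: np.ndarray,
    max_iter: int = 50, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """MAP weights, posterior covariance and its log-determinant at fixed α.

    Maximizes the Bernoulli log-likelihood minus ½ Σ α_i w_i² by damped
    Newton iterations; returns (w_MAP, Σ = H⁻¹, log det Σ) with everything
    derived from one Cholesky factorization of the Hessian at the mode.
    """
    from scipy.linalg import cho_factor, cho_solve

    w = w0.copy()

    def objective(wv: np.ndarray) -> float:
        eta = X @ wv
        # log σ(η) y + log σ(−η) (1−y), numerically stable
        ll = -np.logaddexp(0.0, -eta) @ y - np.logaddexp(0.0, eta) @ (1.0 - y)
        return float(ll - 0.5 * np.sum(alpha * wv**2))

    def hessian_chol(wv: np.ndarray):
        mu = expit(X @ wv)
        r = np.maximum(mu * (1.0 - mu), 1e-10)
        H = (X.T * r) @ X
        H[np.diag_indices_from(H)] += alpha
        return mu, cho_factor(H, lower=True)

    obj = objective(w)
    mu, chol = hessian_chol(w)
    for _ in range(max_iter):
        grad = X.T @ (y - mu) - alpha * w
        step = cho_solve(chol, grad)
        t = 1.0
        for _ in range(30):
            w_new = w + t * step
            obj_new = objective(w_new)
            if obj_new >= obj - 1e-12:
                break
            t *= 0.5
        done = np.max(np.abs(w_new - w)) < tol
        w, obj = w_new, obj_new
        mu, chol = hessian_chol(w)
        if done:
            break
    sigma = cho_solve(chol, np.eye(w.size))
    logdet_sigma = -2.0 * float(np.sum(np.log(np.diag(chol[0]))))
    return w, sigma, logdet_sigma


def fit_slr(
    Z_sel: np.ndarray,
    y: np.ndarray,
    max_iter: int = 500,
    alpha_tol: float = 1e-4,
    prune_threshold: float = PRUNE_THRESHOLD,
) -> SlrModel:
    """Fit the ARD logistic model by evidence maximization.

    Deterministic from the fixed initialization α = 1, w = 0 (the bias
    precision stays fixed at ``BIAS_ALPHA``).  Feature i is pruned when
    α_i exceeds ``prune_threshold``; the bias is exempt.
    Convergence: max relative α change below ``alpha_tol`` over the active
    weights, or ``max_iter`` evidence updates.  Perfectly separable designs
    are caught by a weight cap with a warning rather than divergence.
    """
    Z_sel = np.asarray(Z_sel, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if Z_sel.ndim == 1:
        Z_sel = Z_sel[:, None]
    n, m = Z_sel.shape if Z_sel.size else (y.size, 0)
    if Z_sel.size == 0:
        Z_sel = np.empty((y.size, 0))
        n, m = y.size, 0
    if y.size != n:
        raise ValueError("row mismatch between features and labels")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size < 2:
        raise ValueError("labels must contain both classes 0 and 1")
    X_full = np.column_stack([Z_sel, np.ones(n)])
    active = np.arange(m + 1)  # bias = index m, always kept
    alpha = np.ones(m + 1)
    alpha[m] = BIAS_ALPHA
    w_active = np.zeros(m + 1)
    evidence_trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        X = X_full[:, active]
        a = alpha[active]
        w_active, sigma, logdet_sigma = _penalized_newton(X, y, a, w_active)
        if np.max(np.abs(w_active)) > WEIGHT_CAP:
            warnings.warn(
                "separation-driven divergence: weights capped", stacklevel=2
            )
            w_active = np.clip(w_active, -WEIGHT_CAP, WEIGHT_CAP)
        diag_sigma = np.diag(sigma)
        gamma = 1.0 - a * diag_sigma
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_new = np.where(
                w_active**2 > 1e-300, gamma / w_active**2, 10.0 * prune_threshold
            )
        alpha_new = np.clip(alpha_new, 1e-10, 1e12)
        is_feature = active < m
        alpha_new[~is_feature] = BIAS_ALPHA  # bias exempt from ARD
        # evidence (Laplace approximation of the log marginal likelihood)
        eta = X @ w_active
        ll = float(-np.logaddexp(0.0, -eta) @ y - np.logaddexp(0.0, eta) @ (1.0 - y))
        ev = (
            ll
            - 0.5 * float(np.sum(a * w_active**2))
            + 0.5 * float(np.sum(np.log(a)))
            + 0.5 * logdet_sigma
        )
        evidence_trace.append(ev)
        surviving = is_feature & (alpha_new <= prune_threshold)
        rel_change = (
            float(
                np.max(
                    np.abs(alpha_new[surviving] - a[surviving])
                    / np.maximum(a[surviving], 1e-300)
                )
            )
            if np.any(surviving)
            else 0.0
        )
        alpha[active] = alpha_new
        keep_local = surviving | ~is_feature
        if not np.all(keep_local):
            active = active[keep_local]
            w_active = w_active[keep_local]
        if rel_change < alpha_tol:
            break
    weights = np.zeros(m + 1)
    weights[active] = w_active
    active_features = active[active < m]
    return SlrModel(
        weights=weights,
        alpha=alpha,
        active_set=active_features,
        fit_log={"n_iter": n_iter, "evidence_trace": evidence_trace},
    )


def predict_proba(model: SlrModel, z: np.ndarray) -> float | np.ndarray:
    """P(y=1 | ẑ; w) = 1 / (1 + exp(−wᵀẑ)) with the augmented bias input.

    Numerically stable for arbitrarily large |WLS| (expit saturates to 0/1
    without overflow).
    """
    score = wls(model, z)
    if isinstance(score, WlsScore):
        return float(expit(score.value))
    return expit(np.array([s.value for s in score]))


def wls(model: SlrModel, z: np.ndarray) -> WlsScore | list[WlsScore]:
    """Weighted linear summation wᵀẑ and the sign-rule label.

    Positive WLS → label 1 (patient); negative → label 0 (control); an
    exact zero is classified as control and flagged ``at_boundary``.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    if z.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {z.shape[1]} != model feature count {model.n_features}"
        )
    values = z @ model.weights[:-1] + model.bias
    scores = [
        WlsScore(value=float(v), label=int(v > 0), at_boundary=bool(v == 0))
        for v in values
    ]
    return scores[0] if single else scores
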