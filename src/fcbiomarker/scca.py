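"""L1-sparse canonical correlation analysis for nuisance-robust PC selection.

Links the PC scores of a cohort to its attribute matrix (diagnosis plus
nuisance variables: age, sex, handedness and three medication flags) by the
penalized matrix decomposition form of sparse CCA: maximize uᵀ Zᵀ A v under
‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1 and L1 budgets on both weight vectors, solved by
alternating soft-thresholded power iterations with rank-1 deflation between
successive canonical pairs.

A canonical pair whose attribute-side weights load on the diagnosis column
and (up to a tolerance, default exactly zero) on no nuisance column marks
its PC-side support as diagnosis-specific; the selection is the union of
such supports across a grid of L1 budgets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AttributeMatrix",
    "CanonicalPair",
    "SccaResult",
    "PcSelection",
    "attribute_matrix",
    "fit_l1_scca",
    "fit_scca_grid",
    "select_diagnosis_pcs",
]

ATTRIBUTE_COLUMNS = [
    "diagnosis",
    "age",
    "sex",
    "handedness",
    "med_anxiolytic",
    "med_antidepressant",
    "med_antipsychotic",
]


@dataclass
class AttributeMatrix:
    """Participants × attributes design, each column standardized to mean 0 / sd 1.

    Standardization puts binary and continuous attributes on one scale so a
    single L1 budget treats them symmetrically.  Constant columns (e.g. no
    medicated participant in a training fold) standardize to all-zero and
    can never enter a canonical pair.
    """

    data: np.ndarray
    columns: list[str]
    diagnosis_index: int

    @property
    def n_attributes(self) -> int:
        return self.data.shape[1]

    @property
    def nuisance_indices(self) -> list[int]:
        return [j for j in range(self.n_attributes) if j != self.diagnosis_index]


def attribute_matrix(
    attributes: pd.DataFrame, columns: list[str] | None = None
) -> AttributeMatrix:
    """Build a standardized attribute matrix from a participant table.

    ``columns`` defaults to diagnosis plus the six nuisance variables; the
    diagnosis column must be present.
    """
    cols = list(columns) if columns is not None else list(ATTRIBUTE_COLUMNS)
    if "diagnosis" not in cols:
        raise ValueError("attribute matrix requires a 'diagnosis' column")
    missing = [c for c in cols if c not in attributes.columns]
    if missing:
        raise ValueError(f"attribute table lacks columns: {missing}")
    raw = attributes[cols].to_numpy(dtype=float)
    sd = raw.std(axis=0, ddof=0)
    centered = raw - raw.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        standardized = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return AttributeMatrix(
        data=standardized, columns=cols, diagnosis_index=cols.index("diagnosis")
    )


@dataclass
class CanonicalPair:
    u: np.ndarray  # PC-side weights, ‖u‖₂ ≤ 1
    v: np.ndarray  # attribute-side weights, ‖v‖₂ ≤ 1
    correlation: float
    objective: float
    converged: bool
    n_iter: int


@dataclass
class SccaResult:
    pairs: list[CanonicalPair]
    c_u: float
    c_v: float
    fraction_u: float | None = None
    fraction_v: float | None = None

    @property
    def u_supports(self) -> list[np.ndarray]:
        return [np.flatnonzero(p.u) for p in self.pairs]


@dataclass
class PcSelection:
    """Diagnosis-specific PC indices with grid provenance.

    ``provenance`` records, per contributing (grid cell, pair) combination,
    the hyperparameters and the PCs it added.  An empty selection is a valid
    result and is reported, not raised.
    """

    indices: np.ndarray
    provenance: list[dict] = field(default_factory=list)
    n_grid_cells: int = 0

    @property
    def is_empty(self) -> bool:
        return self.indices.size == 0


def _soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _snap_unit(x: np.ndarray) -> np.ndarray:
    """Zero numerically negligible entries and renormalize to unit L2.

    Support sets feed exact-zero sparsity rules downstream, so entries that
    are pure floating-point residue (≤ 1e-10 of the largest) are snapped.
    """
    top = np.abs(x).max()
    if top == 0:
        return x
    x = np.where(np.abs(x) < 1e-10 * top, 0.0, x)
    return x / np.linalg.norm(x)


def _l1_projected_unit(a: np.ndarray, c: float) -> np.ndarray:
    """Unit-L2 vector maximizing aᵀx subject to ‖x‖₁ ≤ c.

    Standard penalized-matrix-decomposition update: soft-threshold ``a`` at
    the smallest Δ whose L2-normalized result meets the L1 budget.  The
    ratio ‖S(a,Δ)‖₁/‖S(a,Δ)‖₂ is piecewise smooth and non-increasing in Δ,
    so the exact Δ* is found by solving a quadratic on the segment (between
    consecutive sorted |a| values) that brackets ``c``.
    """
    norm = np.linalg.norm(a)
    if norm == 0:
        return np.zeros_like(a)
    x = a / norm
    if np.abs(x).sum() <= c + 1e-12:
        return _snap_unit(x)
    mag = np.sort(np.abs(a))[::-1]
    s1 = np.cumsum(mag)
    s2 = np.cumsum(mag**2)
    n = mag.size
    for k in range(1, n + 1):
        # support = top-k entries while Δ lies in [mag_{k+1}, mag_k)
        if np.sqrt(k) < c - 1e-12:
            continue  # a k-support vector cannot reach an L1/L2 ratio of c
        A = k * (k - c**2)
        B = 2.0 * s1[k - 1] * (c**2 - k)
        C = s1[k - 1] ** 2 - c**2 * s2[k - 1]
        if abs(A) < 1e-30:
            if abs(B) < 1e-30:
                continue
            roots = [-C / B]
        else:
            disc = B**2 - 4 * A * C
            if disc < 0:
                continue
            sq = np.sqrt(disc)
            roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
        seg_lo = mag[k] if k < n else 0.0
        seg_hi = mag[k - 1]
        for delta in roots:
            if seg_lo - 1e-12 <= delta < seg_hi + 1e-12 and delta >= 0:
                xt = _soft_threshold(a, float(min(max(delta, seg_lo), seg_hi)))
                nt = np.linalg.norm(xt)
                if nt > 0 and np.abs(xt).sum() / nt <= c + 1e-9:
                    return _snap_unit(xt / nt)
    # numerical fallback: bisection on the same monotone ratio
    lo, hi = 0.0, float(np.abs(a).max())
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        xt = _soft_threshold(a, mid)
        nt = np.linalg.norm(xt)
        if nt == 0 or np.abs(xt).sum() / nt > c:
            lo = mid
        else:
            hi = mid
    xt = _soft_threshold(a, hi)
    nt = np.linalg.norm(xt)
    if nt == 0:  # c → 1 limit: all mass on the largest coefficient
        xt = np.zeros_like(a)
        k = int(np.argmax(np.abs(a)))
        xt[k] = np.sign(a[k])
        return xt
    return _snap_unit(xt / nt)


def _c_from_fraction(fraction: float, dim: int) -> float:
    """Map an L1 budget fraction in [0, 1] to c in the feasible [1, √dim].

    c = fraction · √dim, clipped below at the minimum feasible budget 1 —
    the usual sum-absolute-value parameterization of the penalized matrix
    decomposition.  Small fractions therefore reach the fully sparse
    single-nonzero regime exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"penalty fraction must lie in [0, 1], got {fraction}")
    return float(np.clip(fraction * np.sqrt(dim), 1.0, np.sqrt(dim)))


def fit_l1_scca(
    Z: np.ndarray,
    A: AttributeMatrix | np.ndarray,
    c_u: float,
    c_v: float,
    n_pairs: int = 1,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> SccaResult:
    """Sparse CCA by penalized matrix decomposition of M = Zᵀ A.

    Each canonical pair maximizes uᵀ M v subject to unit L2 balls and L1
    budgets c_u, c_v (feasible ranges [1, √p] and [1, √q]); pairs after the
    first operate on the projection-deflated M ← (I − uuᵀ) M (I − vvᵀ),
    which removes the found component from both sides — in particular, an
    attribute sharing variance with an already-extracted pair (medication
    mediated by diagnosis, say) cannot re-load the same PCs.
    Initialization is the leading singular pair of the (deflated) M, so the
    fit is deterministic.  Non-convergence emits a warning and keeps the
    best iterate.
    """
    Z = np.asarray(Z, dtype=float)
    Adata = A.data if isinstance(A, AttributeMatrix) else np.asarray(A, dtype=float)
    if Z.shape[0] != Adata.shape[0]:
        raise ValueError(
            f"row mismatch: Z has {Z.shape[0]} rows, A has {Adata.shape[0]}"
        )
    p, q = Z.shape[1], Adata.shape[1]
    if not 1.0 <= c_u <= np.sqrt(p) + 1e-9:
        raise ValueError(f"c_u={c_u:.4g} outside feasible [1, sqrt({p})]")
    if not 1.0 <= c_v <= np.sqrt(q) + 1e-9:
        raise ValueError(f"c_v={c_v:.4g} outside feasible [1, sqrt({q})]")
    M = Z.T @ Adata
    pairs: list[CanonicalPair] = []
    for _ in range(n_pairs):
        U0, _, V0t = np.linalg.svd(M, full_matrices=False)
        u, v = U0[:, 0], V0t[0]
        obj_prev = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            u = _l1_projected_unit(M @ v, c_u)
            v = _l1_projected_unit(M.T @ u, c_v)
            obj = float(u @ M @ v)
            if abs(obj - obj_prev) < tol:
                converged = True
                break
            obj_prev = obj
        if not converged:
            warnings.warn(
                f"L1-SCCA pair did not converge in {max_iter} iterations; "
                "keeping best iterate",
                stacklevel=2,
            )
        obj = float(u @ M @ v)
        zu, av = Z @ u, Adata @ v
        denom = np.linalg.norm(zu) * np.linalg.norm(av)
        corr = float(zu @ av / denom) if denom > 0 else 0.0
        pairs.append(
            CanonicalPair(
                u=u, v=v, correlation=corr, objective=obj,
                converged=converged, n_iter=n_iter,
            )
        )
        if np.linalg.norm(u) > 0:
            M = M - np.outer(u, u @ M)
        if np.linalg.norm(v) > 0:
            M = M - np.outer(M @ v, v)
    return SccaResult(pairs=pairs, c_u=c_u, c_v=c_v)


def fit_scca_grid(
    Z: np.ndarray,
    A: AttributeMatrix,
    fractions_u: list[float] | None = None,
    fractions_v: list[float] | None = None,
    n_pairs: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[SccaResult]:
    """Fit the sparse CCA over a grid of L1-budget fractions on both sides.

    Fractions in [0, 1] map linearly onto the feasible budget range
    [1, √dim]; the default grid is 0.1 … 0.9 in steps of 0.1 on both sides,
    with one canonical pair per attribute column.
    """
    if fractions_u is None:
        fractions_u = [round(0.1 * k, 1) for k in range(1, 10)]
    if fractions_v is None:
        fractions_v = [round(0.1 * k, 1) for k in range(1, 10)]
    if n_pairs is None:
        n_pairs = A.n_attributes
    results = []
    p = np.asarray(Z).shape[1]
    for fu in fractions_u:
        for fv in fractions_v:
            res = fit_l1_scca(
                Z,
                A,
                c_u=_c_from_fraction(fu, p),
                c_v=_c_from_fraction(fv, A.n_attributes),
                n_pairs=n_pairs,
                max_iter=max_iter,
                tol=tol,
            )
            res.fraction_u, res.fraction_v = fu, fv
            results.append(res)
    return results


def select_diagnosis_pcs(
    grid_results: list[SccaResult],
    diagnosis_index: int,
    nv_tolerance: float = 0.0,
    min_corr_fraction: float = 0.5,
) -> PcSelection:
    """Union over the grid of per-cell diagnosis-specific PC sets.

    Within one grid cell, a canonical pair is *diagnosis-only* when its
    attribute-side weights are nonzero at the diagnosis column and within
    ``nv_tolerance`` of zero at every nuisance column (default: exactly
    zero), and *NV-related* when any nuisance weight exceeds the tolerance.
    The cell contributes the PCs supported by its diagnosis-only pairs
    minus the PCs supported by any of its NV-related pairs — a PC attached
    to a nuisance-related canonical variable is not specific to diagnosis,
    even if another pair links it to the label.  The selection is the union
    of these per-cell sets.  An empty union is returned as an explicit
    empty selection with diagnostics, never an exception.

    Successive deflation leaves residual low-correlation pairs that carry
    no structure; only pairs whose |canonical correlation| reaches
    ``min_corr_fraction`` of the cell's strongest pair participate in the
    rule.
    """
    if not grid_results:
        raise ValueError("empty grid")
    selected: set[int] = set()
    provenance: list[dict] = []
    for res in grid_results:
        diag_pcs: set[int] = set()
        nv_pcs: set[int] = set()
        diag_pairs: list[int] = []
        corr_floor = min_corr_fraction * max(
            (abs(p.correlation) for p in res.pairs), default=0.0
        )
        for pair_idx, pair in enumerate(res.pairs):
            if abs(pair.correlation) < corr_floor:
                continue
            v = pair.v
            support = {int(k) for k in np.flatnonzero(pair.u)}
            nv = np.delete(np.abs(v), diagnosis_index)
            nv_loaded = bool(nv.size and nv.max() > nv_tolerance)
            if nv_loaded:
                nv_pcs |= support
            elif v[diagnosis_index] != 0 and support:
                diag_pcs |= support
                diag_pairs.append(pair_idx)
        cell = diag_pcs - nv_pcs
        if cell:
            selected |= cell
            provenance.append(
                {
                    "fraction_u": res.fraction_u,
                    "fraction_v": res.fraction_v,
                    "c_u": res.c_u,
                    "c_v": res.c_v,
                    "pairs": diag_pairs,
                    "pcs": sorted(cell),
                }
            )
    return PcSelection(
        indices=np.array(sorted(selected), dtype=int),
        provenance=provenance,
        n_grid_cells=len(grid_results),
    )
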