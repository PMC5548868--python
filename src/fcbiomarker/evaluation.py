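"""Classifier training, nested LOOCV, permutation and external validation.

The pipeline cascade is: PCA of the cohort FC matrix → L1-sparse CCA
selection of diagnosis-specific PCs (robust to nuisance variables) → ARD
sparse logistic regression → weighted linear summation (WLS) scores for
held-out or external participants.  Leave-one-out cross-validation assesses
internal accuracy/AUC, a label-shuffling permutation test its significance,
and frozen artifacts are applied unchanged to an external cohort.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reduction, scca, slr
from .config import PipelineConfig

__all__ = [
    "EvaluationReport",
    "TrainedArtifacts",
    "PermutationResult",
    "auc",
    "train_classifier",
    "loocv",
    "permutation_test",
    "external_validate",
    "chi_squared_2x2",
    "two_sample_t",
    "wls_histogram",
    "subgroup_tables",
]


@dataclass
class EvaluationReport:
    """Per-participant WLS scores and summary metrics for one evaluation."""

    per_participant: pd.DataFrame  # columns: wls, predicted, true
    accuracy: float
    auc: float
    permutation_p: float | None = None
    fold_provenance: list[dict] = field(default_factory=list)
    subgroups: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "permutation_p": self.permutation_p,
            "per_participant": self.per_participant.reset_index().to_dict(
                orient="list"
            ),
        }


@dataclass
class TrainedArtifacts:
    """Frozen training products applied unchanged to external data."""

    pca: reduction.PcaModel
    selection: scca.PcSelection
    model: slr.SlrModel
    edge_columns: list[str]
    attribute_columns: list[str]
    config_hash: str

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.pca.content_hash().encode())
        h.update(np.ascontiguousarray(self.selection.indices, dtype=np.int64).tobytes())
        h.update(self.model.content_hash().encode())
        h.update("\x1f".join(self.edge_columns).encode())
        return h.hexdigest()


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    null_distribution: np.ndarray
    statistic: str


def auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve, ties half-credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _fit_fold(
    Z_train: np.ndarray,
    attrs_train: pd.DataFrame,
    y_train: np.ndarray,
    config: PipelineConfig,
    selection: scca.PcSelection | None = None,
) -> tuple[scca.PcSelection, slr.SlrModel]:
    """SCCA selection (unless given) + ARD-SLR fit on one training set."""
    if selection is None:
        A = scca.attribute_matrix(attrs_train)
        grid = scca.fit_scca_grid(
            Z_train,
            A,
            fractions_u=config.scca_fractions_u,
            fractions_v=config.scca_fractions_v,
            n_pairs=config.scca_n_pairs,
        )
        selection = scca.select_diagnosis_pcs(
            grid,
            A.diagnosis_index,
            nv_tolerance=config.nv_tolerance,
            min_corr_fraction=config.scca_min_corr_fraction,
        )
    if selection.is_empty:
        warnings.warn(
            "empty diagnosis-specific PC selection; falling back to a "
            "bias-only classifier",
            stacklevel=2,
        )
        Z_sel = np.empty((len(y_train), 0))
    else:
        Z_sel = Z_train[:, selection.indices]
    model = slr.fit_slr(
        Z_sel,
        y_train,
        max_iter=config.slr_max_iter,
        alpha_tol=config.slr_alpha_tol,
        prune_threshold=config.slr_prune_threshold,
    )
    return selection, model


def train_classifier(
    X: pd.DataFrame, attributes: pd.DataFrame, config: PipelineConfig | None = None
) -> TrainedArtifacts:
    """Train the full cascade on a cohort FC matrix (no cross-validation).

    PCA on all rows, pooled SCCA selection, ARD-SLR on the selected scores.
    The returned artifacts are what external validation consumes.
    """
    config = config or PipelineConfig()
    Xv = X.to_numpy(dtype=float)
    y = attributes["diagnosis"].to_numpy(dtype=float)
    pca = reduction.fit_pca(Xv)
    Z = reduction.transform(pca, Xv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        selection, model = _fit_fold(Z, attributes, y, config)
    return TrainedArtifacts(
        pca=pca,
        selection=selection,
        model=model,
        edge_columns=list(X.columns),
        attribute_columns=list(scca.ATTRIBUTE_COLUMNS),
        config_hash=config.content_hash(),
    )


def loocv(
    X: pd.DataFrame,
    attributes: pd.DataFrame,
    config: PipelineConfig | None = None,
    _pca: reduction.PcaModel | None = None,
    _selection: scca.PcSelection | None = None,
) -> EvaluationReport:
    """Leave-one-out cross-validation of the selection + classification cascade.

    Per fold, all-but-one participants train the classifier and the held-out
    participant receives a WLS score.  PCA scope follows
    ``config.pca_scope`` (default: fitted once on the whole cohort, the
    published convention; ``per_fold`` refits inside each fold).  SCCA
    selection follows ``config.selection_scope`` (default per_fold).
    ``_pca`` / ``_selection`` allow callers that loop over label
    permutations to reuse label-independent (or deliberately frozen)
    artifacts.
    """
    config = config or PipelineConfig()
    Xv = X.to_numpy(dtype=float)
    y = attributes["diagnosis"].to_numpy(dtype=float)
    n = Xv.shape[0]
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("LOOCV requires at least 2 participants per class")
    ids = list(X.index)
    pooled_pca = None
    Z_all = None
    if config.pca_scope == "pooled":
        pooled_pca = _pca if _pca is not None else reduction.fit_pca(Xv)
        Z_all = reduction.transform(pooled_pca, Xv)
    pooled_selection = _selection
    if pooled_selection is None and config.selection_scope == "pooled":
        if Z_all is None:
            raise ValueError("pooled selection requires pooled PCA scope")
        A = scca.attribute_matrix(attributes)
        grid = scca.fit_scca_grid(
            Z_all,
            A,
            fractions_u=config.scca_fractions_u,
            fractions_v=config.scca_fractions_v,
            n_pairs=config.scca_n_pairs,
        )
        pooled_selection = scca.select_diagnosis_pcs(
            grid,
            A.diagnosis_index,
            nv_tolerance=config.nv_tolerance,
            min_corr_fraction=config.scca_min_corr_fraction,
        )
    wls_values = np.empty(n)
    provenance = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n):
            train = np.arange(n) != k
            y_train = y[train]
            if np.unique(y_train).size < 2:
                raise ValueError(f"fold {k} has a single-class training set")
            if config.pca_scope == "per_fold":
                fold_pca = reduction.fit_pca(Xv[train])
                Z_train = reduction.transform(fold_pca, Xv[train])
                z_test = reduction.transform(fold_pca, Xv[k])
            else:
                Z_train = Z_all[train]
                z_test = Z_all[k]
            selection, model = _fit_fold(
                Z_train,
                attributes.iloc[train],
                y_train,
                config,
                selection=pooled_selection,
            )
            z_sel = (
                np.empty(0) if selection.is_empty else z_test[selection.indices]
            )
            wls_values[k] = slr.wls(model, z_sel).value
            provenance.append(
                {
                    "fold": k,
                    "held_out": ids[k],
                    "train_hash": hashlib.sha256(
                        "\x1f".join(ids[j] for j in range(n) if j != k).encode()
                    ).hexdigest(),
                    "n_selected": int(selection.indices.size),
                    "n_active": int(model.active_set.size),
                }
            )
    predicted = (wls_values > 0).astype(int)
    per_participant = pd.DataFrame(
        {"wls": wls_values, "predicted": predicted, "true": y.astype(int)},
        index=pd.Index(ids, name="participant_id"),
    )
    return EvaluationReport(
        per_participant=per_participant,
        accuracy=float(np.mean(predicted == y)),
        auc=auc(wls_values, y),
        fold_provenance=provenance,
    )


def permutation_test(
    X: pd.DataFrame,
    attributes: pd.DataFrame,
    config: PipelineConfig | None = None,
    n_perm: int | None = None,
    seed: int | None = None,
    observed_report: EvaluationReport | None = None,
) -> PermutationResult:
    """Label-shuffling significance of the LOOCV statistic (default AUC).

    Diagnosis labels are permuted per replicate and the full selection +
    fit + scoring cascade is recomputed (unless
    ``config.permutation_freeze_selection``, which freezes the observed
    run's pooled selection).  p = (1 + #{null ≥ observed}) / (1 + n_perm),
    so p is never zero and lies in [1/(1+n_perm), 1].
    """
    config = config or PipelineConfig()
    n_perm = n_perm if n_perm is not None else config.n_perm
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    seed = seed if seed is not None else config.seed
    pooled_pca = (
        reduction.fit_pca(X.to_numpy(dtype=float))
        if config.pca_scope == "pooled"
        else None
    )
    if observed_report is None:
        observed_report = loocv(X, attributes, config, _pca=pooled_pca)
    frozen_selection = None
    if config.permutation_freeze_selection:
        artifacts = train_classifier(X, attributes, config)
        frozen_selection = artifacts.selection

    def statistic(report: EvaluationReport) -> float:
        return report.auc if config.permutation_statistic == "auc" else report.accuracy

    observed = statistic(observed_report)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    y = attributes["diagnosis"].to_numpy()
    for b in range(n_perm):
        shuffled = attributes.copy()
        shuffled["diagnosis"] = rng.permutation(y)
        report_b = loocv(
            X, shuffled, config, _pca=pooled_pca, _selection=frozen_selection
        )
        null[b] = statistic(report_b)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PermutationResult(
        p_value=p,
        observed=observed,
        null_distribution=null,
        statistic=config.permutation_statistic,
    )


def external_validate(
    artifacts: TrainedArtifacts,
    X_external: pd.DataFrame,
    attributes_external: pd.DataFrame,
) -> EvaluationReport:
    """Score an external cohort with frozen artifacts (no refitting).

    The external FC matrix must use exactly the training edge set (after
    zero-variance ROI exclusion).  Artifact hashes are verified unchanged
    after scoring.
    """
    if list(X_external.columns) != artifacts.edge_columns:
        missing = set(artifacts.edge_columns) - set(X_external.columns)
        extra = set(X_external.columns) - set(artifacts.edge_columns)
        raise ValueError(
            "external edge set differs from the training edge set "
            f"({len(missing)} missing, {len(extra)} extra); re-extract the "
            "external FC matrix over the training ROI list and edge order"
        )
    hash_before = artifacts.content_hash()
    Z = reduction.transform(artifacts.pca, X_external.to_numpy(dtype=float))
    if artifacts.selection.is_empty:
        Z_sel = np.empty((Z.shape[0], 0))
    else:
        Z_sel = Z[:, artifacts.selection.indices]
    scores = slr.wls(artifacts.model, Z_sel)
    wls_values = np.array([s.value for s in scores])
    y = attributes_external["diagnosis"].to_numpy(dtype=float)
    predicted = (wls_values > 0).astype(int)
    if artifacts.content_hash() != hash_before:
        raise RuntimeError("training artifacts mutated during external validation")
    per_participant = pd.DataFrame(
        {"wls": wls_values, "predicted": predicted, "true": y.astype(int)},
        index=pd.Index(list(X_external.index), name="participant_id"),
    )
    return EvaluationReport(
        per_participant=per_participant,
        accuracy=float(np.mean(predicted == y)),
        auc=auc(wls_values, y),
    )


def chi_squared_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared on a 2×2 table, 1 df, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2×2 with nonnegative counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("chi-squared test requires positive margins")
    expected = np.outer(row, col) / t.sum()
    statistic = float(np.sum((t - expected) ** 2 / expected))
    return statistic, float(stats.chi2.sf(statistic, df=1))


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided Student's t-test with pooled variance.

    Each group is either an array of raw values or a ``(mean, sd, n)``
    summary triple; the two input forms give identical results.
    """

    def as_summary(g):
        if isinstance(g, tuple) and len(g) == 3:
            mean, sd, n = g
            return float(mean), float(sd), int(n)
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError("each group needs n ≥ 2")
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)

    m1, s1, n1 = as_summary(group_a)
    m2, s2, n2 = as_summary(group_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n ≥ 2")
    if s1 == 0 and s2 == 0 and m1 == m2:
        return 0.0, 1.0
    if (n1 == 2 and s1 == 0) or (n2 == 2 and s2 == 0):
        raise ValueError("degenerate variance with n = 2")
    t, p = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=True
    )
    return float(t), float(p)


def wls_histogram(
    report: EvaluationReport, bin_width: float = 5.0
) -> pd.DataFrame:
    """Per-group WLS histogram table with a configurable bin width.

    Bins are aligned to multiples of ``bin_width`` around zero; returns one
    row per bin with patient and control counts, suitable for plotting the
    score-separation figure with any renderer.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = report.per_participant["wls"].to_numpy()
    labels = report.per_participant["true"].to_numpy()
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    patient, _ = np.histogram(values[labels == 1], bins=edges)
    control, _ = np.histogram(values[labels == 0], bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "n_patient": patient,
            "n_control": control,
        }
    )


def subgroup_tables(
    report: EvaluationReport, attributes: pd.DataFrame
) -> dict:
    """Correct-vs-misclassified comparisons: age (t), sex (chi²), Y-BOCS (t).

    Mirrors the published subgroup checks; Y-BOCS is compared among
    patients only (controls carry no severity score).
    """
    merged = report.per_participant.join(attributes, how="inner")
    correct = merged["predicted"] == merged["true"]
    out: dict = {"n_correct": int(correct.sum()), "n_total": int(len(merged))}
    if 2 <= correct.sum() <= len(merged) - 2:
        out["age_t"] = two_sample_t(
            merged.loc[correct, "age"].to_numpy(),
            merged.loc[~correct, "age"].to_numpy(),
        )
        sex_table = np.array(
            [
                [
                    int(((merged["sex"] == s) & correct).sum()),
                    int(((merged["sex"] == s) & ~correct).sum()),
                ]
                for s in (0, 1)
            ]
        )
        try:
            out["sex_chi2"] = chi_squared_2x2(sex_table)
        except ValueError:
            out["sex_chi2"] = None
        if "ybocs" in merged:
            patients = merged[merged["true"] == 1].dropna(subset=["ybocs"])
            pc = patients["predicted"] == patients["true"]
            if 2 <= pc.sum() <= len(patients) - 2:
                out["ybocs_t"] = two_sample_t(
                    patients.loc[pc, "ybocs"].to_numpy(),
                    patients.loc[~pc, "ybocs"].to_numpy(),
                )
    return out
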