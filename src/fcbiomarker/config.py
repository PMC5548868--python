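"""Pipeline configuration: every tunable, schema-checked, hashable.

Defaults reproduce the published analysis constants: 0.008–0.1 Hz band,
0.5 mm frame-displacement threshold with a (−1, +2)-frame scrub window,
1,000 permutation repetitions, contribution thresholds 100/200/400/600.
Choices the published description leaves open (SCCA grid, ARD tolerances,
selection scope) are flagged as implementation choices by
``explain_config``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "explain_config"]

SCHEMA_VERSION = 1

#: provenance of each default: "published" constants vs implementation choices
_PROVENANCE = {
    "low_hz": ("published", "band-pass low edge 0.008 Hz"),
    "high_hz": ("published", "band-pass high edge 0.1 Hz"),
    "fd_threshold_mm": ("published", "scrub frames with FD above 0.5 mm"),
    "head_radius_mm": ("choice", "50 mm arc-length radius for angular rotations"),
    "scca_fractions_u": ("choice", "L1 budget grid, PC side (fractions of [1, sqrt(p)])"),
    "scca_fractions_v": ("choice", "L1 budget grid, attribute side"),
    "scca_n_pairs": ("choice", "canonical pairs per grid cell; None = n_attributes"),
    "nv_tolerance": ("published", "selected pairs must load on diagnosis only"),
    "scca_min_corr_fraction": ("choice", "ignore deflation-residue pairs below this fraction of a cell's top canonical correlation"),
    "selection_scope": ("choice", "per_fold (leakage-safe) or pooled SCCA selection"),
    "pca_scope": ("published", "PCA fitted on the whole training cohort"),
    "slr_max_iter": ("choice", "ARD evidence-update cap"),
    "slr_alpha_tol": ("choice", "relative alpha-change convergence tolerance"),
    "slr_prune_threshold": ("choice", "alpha above this prunes a weight"),
    "n_perm": ("published", "1,000-repetition permutation test"),
    "permutation_statistic": ("choice", "permutation statistic: auc (default) or accuracy"),
    "permutation_freeze_selection": ("choice", "re-run selection per permutation when False"),
    "top_k_list": ("published", "contribution thresholds 100/200/400/600"),
    "seed": ("choice", "global random seed"),
    "schema_version": ("choice", "config schema version"),
}


@dataclass
class PipelineConfig:
    # connectivity
    low_hz: float = 0.008
    high_hz: float = 0.1
    fd_threshold_mm: float = 0.5
    head_radius_mm: float = 50.0
    # SCCA selection
    scca_fractions_u: list[float] = field(
        default_factory=lambda: [round(0.1 * k, 1) for k in range(1, 10)]
    )
    scca_fractions_v: list[float] = field(
        default_factory=lambda: [round(0.1 * k, 1) for k in range(1, 10)]
    )
    scca_n_pairs: int | None = None
    nv_tolerance: float = 0.0
    scca_min_corr_fraction: float = 0.5
    selection_scope: str = "per_fold"  # per_fold | pooled
    pca_scope: str = "pooled"  # pooled | per_fold
    # ARD logistic regression
    slr_max_iter: int = 500
    slr_alpha_tol: float = 1e-4
    slr_prune_threshold: float = 1e8
    # evaluation
    n_perm: int = 1000
    permutation_statistic: str = "auc"  # auc | accuracy
    permutation_freeze_selection: bool = False
    # interpretation
    top_k_list: list[int] = field(default_factory=lambda: [100, 200, 400, 600])
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.selection_scope not in ("per_fold", "pooled"):
            raise ValueError(
                f"selection_scope must be per_fold or pooled, got {self.selection_scope!r}"
            )
        if self.pca_scope not in ("pooled", "per_fold"):
            raise ValueError(
                f"pca_scope must be pooled or per_fold, got {self.pca_scope!r}"
            )
        if self.permutation_statistic not in ("auc", "accuracy"):
            raise ValueError(
                "permutation_statistic must be auc or accuracy, "
                f"got {self.permutation_statistic!r}"
            )
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema_version {self.schema_version}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def explain_config(config: PipelineConfig) -> str:
    """Per-field provenance: published constant or implementation choice."""
    lines = []
    for f in dataclasses.fields(config):
        kind, note = _PROVENANCE[f.name]
        value = getattr(config, f.name)
        lines.append(f"{f.name} = {value!r}  [{kind}] {note}")
    return "\n".join(lines)
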