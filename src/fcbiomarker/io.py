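"""Plain-text file formats and reproducibility manifests.

Everything is TSV/CSV/JSON: per-participant ROI time-series TSV (header =
ROI names), motion TSV (tx,ty,tz,rx,ry,rz), nuisance TSV (wm,csf,global),
an attributes CSV, an ROI→network atlas TSV, cohort FC matrices as
participants × edges TSV, and JSON for models, reports, ground truth and
manifests.  A manifest ties every artifact to a SHA-256 content hash plus
the config hash and seed, so a rerun can be verified bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import (
    MOTION_COLUMNS,
    NUISANCE_COLUMNS,
    MotionTrace,
    NuisanceSignals,
    RoiTimeSeries,
)
from .reduction import PcaModel
from .scca import PcSelection
from .slr import SlrModel
from .synthetic import GroundTruth, Participant

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_fc_matrix",
    "read_fc_matrix",
    "write_attributes",
    "read_attributes",
    "save_artifacts",
    "load_artifacts",
    "file_sha256",
    "write_manifest",
    "verify_manifest",
]

_FLOAT_FORMAT = "%.10g"


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_cohort(
    directory, participants: list[Participant], truth: GroundTruth | None = None
) -> None:
    """One time-series / motion / nuisance TSV triple per participant,
    plus attributes.csv and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in participants:
        pid = p.participant_id
        pd.DataFrame(p.series.data, columns=p.series.roi_names).to_csv(
            directory / f"{pid}_timeseries.tsv",
            sep="\t", index=False, float_format=_FLOAT_FORMAT,
        )
        pd.DataFrame(p.motion.data, columns=list(MOTION_COLUMNS)).to_csv(
            directory / f"{pid}_motion.tsv",
            sep="\t", index=False, float_format=_FLOAT_FORMAT,
        )
        pd.DataFrame(p.nuisance.data, columns=list(NUISANCE_COLUMNS)).to_csv(
            directory / f"{pid}_nuisance.tsv",
            sep="\t", index=False, float_format=_FLOAT_FORMAT,
        )
        rows.append(
            {
                "participant_id": pid,
                "tr_seconds": p.series.tr_seconds,
                "rotation_units": p.motion.rotation_units,
                **p.attributes,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "attributes.csv", index=False)
    if truth is not None:
        with open(directory / "truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1, allow_nan=True)


def read_cohort(directory) -> list[Participant]:
    directory = Path(directory)
    attrs = pd.read_csv(directory / "attributes.csv")
    participants = []
    for _, row in attrs.iterrows():
        pid = row["participant_id"]
        ts = pd.read_csv(directory / f"{pid}_timeseries.tsv", sep="\t")
        motion = pd.read_csv(directory / f"{pid}_motion.tsv", sep="\t")
        nuis = pd.read_csv(directory / f"{pid}_nuisance.tsv", sep="\t")
        series = RoiTimeSeries(
            participant_id=pid,
            data=ts.to_numpy(dtype=float),
            tr_seconds=float(row["tr_seconds"]),
            roi_names=list(ts.columns),
        )
        attributes = row.drop(
            ["participant_id", "tr_seconds", "rotation_units"]
        ).to_dict()
        participants.append(
            Participant(
                participant_id=pid,
                series=series,
                motion=MotionTrace(
                    data=motion.to_numpy(dtype=float),
                    rotation_units=str(row["rotation_units"]),
                ),
                nuisance=NuisanceSignals(data=nuis.to_numpy(dtype=float)),
                attributes=attributes,
            )
        )
    return participants


def write_fc_matrix(path, fc: pd.DataFrame) -> None:
    fc.to_csv(path, sep="\t", index_label="participant_id",
              float_format=_FLOAT_FORMAT)


def read_fc_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="participant_id")


def write_attributes(path, attributes: pd.DataFrame) -> None:
    attributes.to_csv(path, index_label="participant_id")


def read_attributes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")


def save_artifacts(path, artifacts) -> None:
    """Serialize trained artifacts (PCA + selection + SLR) to one JSON file."""
    payload = {
        "schema": "trained-artifacts/1",
        "pca": artifacts.pca.to_dict(),
        "selection": {
            "indices": artifacts.selection.indices.tolist(),
            "provenance": artifacts.selection.provenance,
            "n_grid_cells": artifacts.selection.n_grid_cells,
        },
        "slr": artifacts.model.to_dict(),
        "edge_columns": artifacts.edge_columns,
        "attribute_columns": artifacts.attribute_columns,
        "config_hash": artifacts.config_hash,
        "content_hash": artifacts.content_hash(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_artifacts(path):
    from .evaluation import TrainedArtifacts

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema") != "trained-artifacts/1":
        raise ValueError(f"unsupported artifacts schema: {payload.get('schema')!r}")
    artifacts = TrainedArtifacts(
        pca=PcaModel.from_dict(payload["pca"]),
        selection=PcSelection(
            indices=np.asarray(payload["selection"]["indices"], dtype=int),
            provenance=payload["selection"]["provenance"],
            n_grid_cells=payload["selection"]["n_grid_cells"],
        ),
        model=SlrModel.from_dict(payload["slr"]),
        edge_columns=list(payload["edge_columns"]),
        attribute_columns=list(payload["attribute_columns"]),
        config_hash=payload["config_hash"],
    )
    if artifacts.content_hash() != payload["content_hash"]:
        raise ValueError(f"artifact content hash mismatch in {path}")
    return artifacts


def write_manifest(path, artifact_paths: list, config_hash: str, seed: int) -> None:
    """Record SHA-256 of every artifact plus the config hash and seed."""
    base = Path(path).parent
    entries = {
        str(Path(p).relative_to(base) if Path(p).is_relative_to(base) else Path(p)):
            file_sha256(p)
        for p in artifact_paths
    }
    with open(path, "w") as fh:
        json.dump(
            {
                "schema": "manifest/1",
                "config_hash": config_hash,
                "seed": seed,
                "artifacts": entries,
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def verify_manifest(path) -> dict:
    """Re-hash every artifact; returns {file: ok} and raises on mismatch."""
    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh)
    base = path.parent
    status = {}
    bad = []
    for rel, expected in manifest["artifacts"].items():
        target = base / rel
        actual = file_sha256(target)
        status[rel] = actual == expected
        if not status[rel]:
            bad.append(rel)
    if bad:
        raise ValueError(f"manifest hash mismatch for: {bad}")
    return status
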