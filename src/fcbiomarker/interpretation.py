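"""Per-connection interpretation of the trained linear cascade.

PCA and the logistic classifier are both linear, so the classifier weight
on each selected PC back-projects through the PCA transformation matrix to
an effective weight c_j on every FC edge:

    WLS(x) = bias + Σ_j c_j (x_j − mean_j),   c_j = Σ_{k∈selected} w_k V_{k,j}

Edges are ranked by |c_j| (ties broken by edge index), thresholded at
top-K, and aggregated into a symmetric count matrix over 18 macroscale
networks (within-network counts on the diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import edge_pairs
from .reduction import PcaModel
from .scca import PcSelection
from .slr import SlrModel

__all__ = [
    "NetworkAtlas",
    "DEFAULT_NETWORK_LABELS",
    "round_robin_atlas",
    "fc_contributions",
    "top_k",
    "network_matrix",
    "pair_count_sweep",
]

#: 18 macroscale functional networks in the style of the BrainMap-ICA
#: decomposition used to aggregate edge contributions.
DEFAULT_NETWORK_LABELS = [
    "orbitofrontal",
    "striatum",
    "basal_ganglia_thalamus",
    "default_mode",
    "left_frontoparietal",
    "right_frontoparietal",
    "dorsal_attention",
    "ventral_attention",
    "salience",
    "medial_visual",
    "lateral_visual",
    "occipital_visual",
    "auditory",
    "sensorimotor",
    "cerebellum",
    "temporal",
    "limbic",
    "precuneus",
]


@dataclass
class NetworkAtlas:
    """ROI → macroscale-network mapping with a fixed label set."""

    roi_to_network: dict[str, str]
    labels: list[str]

    def __post_init__(self) -> None:
        unknown = sorted(set(self.roi_to_network.values()) - set(self.labels))
        if unknown:
            raise ValueError(f"atlas uses labels outside the label set: {unknown}")

    def network_of(self, roi: str) -> str:
        try:
            return self.roi_to_network[roi]
        except KeyError:
            raise ValueError(f"ROI {roi!r} is not mapped to a network") from None

    @classmethod
    def from_tsv(cls, path, labels: list[str] | None = None) -> "NetworkAtlas":
        table = pd.read_csv(path, sep="\t")
        if not {"roi", "network"} <= set(table.columns):
            raise ValueError("atlas TSV needs 'roi' and 'network' columns")
        mapping = dict(zip(table["roi"], table["network"]))
        if labels is None:
            labels = sorted(set(mapping.values()))
        return cls(roi_to_network=mapping, labels=labels)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"roi": list(self.roi_to_network), "network": list(self.roi_to_network.values())}
        ).to_csv(path, sep="\t", index=False)


def round_robin_atlas(
    roi_names: list[str], labels: list[str] | None = None
) -> NetworkAtlas:
    """Synthetic atlas assigning ROIs to the label cycle in order."""
    labels = list(labels) if labels is not None else list(DEFAULT_NETWORK_LABELS)
    mapping = {roi: labels[k % len(labels)] for k, roi in enumerate(roi_names)}
    return NetworkAtlas(roi_to_network=mapping, labels=labels)


def fc_contributions(
    pca: PcaModel,
    selection: PcSelection,
    model: SlrModel,
    roi_names: list[str],
    atlas: NetworkAtlas | None = None,
) -> pd.DataFrame:
    """Effective per-edge weights of the trained cascade.

    Returns a DataFrame (one row per edge, in edge-index order) with the
    ROI pair, the contribution c_j, the absolute-value rank (1 = largest,
    ties broken by edge index) and, when an atlas is given, the network
    pair.  The classifier's feature weights must correspond one-to-one to
    the selected PCs.
    """
    if model.n_features != selection.indices.size:
        raise ValueError(
            f"classifier has {model.n_features} feature weights but the "
            f"selection holds {selection.indices.size} PCs"
        )
    n_rois = len(roi_names)
    pairs = edge_pairs(n_rois)
    if pairs.shape[0] != pca.n_edges:
        raise ValueError(
            f"{n_rois} ROIs imply {pairs.shape[0]} edges but the PCA model "
            f"has {pca.n_edges}"
        )
    if selection.indices.size:
        c = model.weights[:-1] @ pca.components_[selection.indices]
    else:
        c = np.zeros(pca.n_edges)
    order = np.lexsort((np.arange(c.size), -np.abs(c)))
    rank = np.empty(c.size, dtype=int)
    rank[order] = np.arange(1, c.size + 1)
    table = pd.DataFrame(
        {
            "edge": np.arange(c.size),
            "roi_i": [roi_names[i] for i, _ in pairs],
            "roi_j": [roi_names[j] for _, j in pairs],
            "contribution": c,
            "rank": rank,
        }
    )
    if atlas is not None:
        table["network_i"] = [atlas.network_of(r) for r in table["roi_i"]]
        table["network_j"] = [atlas.network_of(r) for r in table["roi_j"]]
    return table


def top_k(table: pd.DataFrame, k: int = 200) -> pd.DataFrame:
    """The k edges of largest |contribution| (deterministic tie-break)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} available edges")
    return table[table["rank"] <= k]


def network_matrix(edges: pd.DataFrame, atlas: NetworkAtlas) -> pd.DataFrame:
    """Symmetric network-pair count matrix of an edge subset.

    Entry (a, b) counts edges joining networks a and b; within-network
    counts sit on the diagonal.  The matrix total (upper triangle plus
    diagonal) equals the number of edges supplied.
    """
    labels = atlas.labels
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for _, row in edges.iterrows():
        a = atlas.network_of(row["roi_i"])
        b = atlas.network_of(row["roi_j"])
        counts.loc[a, b] += 1
        if a != b:
            counts.loc[b, a] += 1
    return counts


def pair_count_sweep(
    table: pd.DataFrame,
    atlas: NetworkAtlas,
    pair: tuple[str, str],
    thresholds: list[int] = (100, 200, 400, 600),
) -> dict[int, int]:
    """Count of top-K edges joining two networks, for each threshold K.

    The counts are non-decreasing in K because top-K sets are nested.
    """
    a, b = pair
    for label in (a, b):
        if label not in atlas.labels:
            raise ValueError(f"unknown network label {label!r}")
    out: dict[int, int] = {}
    for k in thresholds:
        sub = top_k(table, k)
        nets_i = sub["roi_i"].map(atlas.network_of)
        nets_j = sub["roi_j"].map(atlas.network_of)
        hit = ((nets_i == a) & (nets_j == b)) | ((nets_i == b) & (nets_j == a))
        out[int(k)] = int(hit.sum())
    return out
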