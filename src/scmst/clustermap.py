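"""Normalization, subpopulation clustering, and co-expression gating.

Counts are z-scored gene-wise within normalization groups: ``per_stage``
pools all fields of view of one developmental stage into one group (so
"high"/"low" calls are consistent across a cross-section), while
``cross_stage`` pools every cell into a single group for between-stage
comparisons; a second "through genes" standardization across the panel is
available for the pooled mode.  Cells are then hierarchically clustered on
their z profiles into transcriptionally distinct subpopulations, and named
gene modules (pluripotency, pan-ectoderm, neural crest, neural) are gated
by strict co-expression: a cell passes a module iff z > 0 — above the gene
mean — for *every* gene in the module.

The z-score uses the population standard deviation (divide by n), so a
two-cell group with counts [1, 3] gives exactly z = [-1, +1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .quantify import CountMatrix

__all__ = [
    "ZScoreMatrix",
    "ClusterAssignment",
    "GeneModule",
    "GateResult",
    "GENE_MODULES",
    "zscore",
    "zscore_through_genes",
    "hierarchical_cluster",
    "plot_heatmap",
    "gate_coexpression",
    "annotate_clusters",
]

#: Named gene modules used for co-expression gating.
GENE_MODULES: dict[str, list[str]] = {
    "pluripotency": ["PouV", "Nanog", "Klf4"],
    "pan_ecto": ["PouV", "Nanog", "Klf4", "Tfap2A", "Sox2"],
    "nc": ["Foxd3", "cMyc", "Pax7", "Snai2", "Sox10", "Sox9"],
    "neural": ["Nestin", "MycN", "Msi1"],
}


@dataclass
class GeneModule:
    name: str
    genes: list[str]

    @classmethod
    def named(cls, name: str) -> "GeneModule":
        if name not in GENE_MODULES:
            raise ValidationError(
                f"unknown module {name!r}; known: {sorted(GENE_MODULES)}"
            )
        return cls(name, list(GENE_MODULES[name]))


@dataclass
class ZScoreMatrix:
    """Gene x cell z-scores with their normalization grouping.

    ``zero_variance[(gene, group)]`` flags gene/group pairs whose counts
    were constant; their z entries are set to 0.
    """

    z: np.ndarray
    genes: list[str]
    cells: pd.DataFrame
    mode: str
    grouping: np.ndarray                       # per-cell group key
    zero_variance: set = field(default_factory=set)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise ValidationError(f"gene {gene!r} not in z-score matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.z, index=self.genes, columns=self.cells["cell_id"].to_numpy()
        )


@dataclass
class ClusterAssignment:
    """Flat subpopulation labels plus the dendrogram they were cut from."""

    assignment: pd.Series                      # cell_id -> cluster id
    linkage_matrix: np.ndarray
    leaf_order: np.ndarray                     # cell ids in dendrogram order
    annotations: dict[int, str] = field(default_factory=dict)
    colors: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignment))


@dataclass
class GateResult:
    """Cells passing a strict z>0 intersection over a module's genes."""

    module: GeneModule
    cell_ids: set
    per_stage: pd.DataFrame                    # stage, n_pass, n_total, fraction


def _resolve_grouping(counts: CountMatrix, mode: str, grouping) -> np.ndarray:
    if grouping is not None:
        g = np.asarray(grouping)
        if g.shape[0] != counts.n_cells:
            raise ValidationError("grouping must cover all cells")
        return g
    if mode == "per_stage":
        return counts.cells["stage"].to_numpy()
    if mode == "cross_stage":
        return np.zeros(counts.n_cells, dtype=int)
    raise ValidationError(f"unknown z-score mode {mode!r}")


def zscore(
    counts: CountMatrix,
    mode: str = "per_stage",
    grouping=None,
    log1p: bool = False,
) -> ZScoreMatrix:
    """Gene-wise z-scores within normalization groups.

    ``per_stage``: each stage (its FOVs pooled) is one group.
    ``cross_stage``: all cells pooled into a single group.
    ``grouping`` overrides the mode-derived group per cell.  ``log1p``
    optionally transforms counts first (off by default: raw counts).
    """
    groups = _resolve_grouping(counts, mode, grouping)
    x = counts.counts.astype(float)
    if log1p:
        x = np.log1p(x)
    if x.shape[1] == 0:
        raise ValidationError("cannot z-score an empty matrix")
    z = np.zeros_like(x)
    zero_var: set = set()
    for gval in pd.unique(groups):
        sel = groups == gval
        if not sel.any():
            raise ValidationError(f"empty normalization group {gval!r}")
        sub = x[:, sel]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)          # population convention
        flat = sd[:, 0] == 0
        sd[flat] = 1.0
        z[:, sel] = (sub - mu) / sd
        z[np.ix_(flat, sel)] = 0.0
        for gi in np.flatnonzero(flat):
            zero_var.add((counts.genes[gi], gval))
    return ZScoreMatrix(
        z, list(counts.genes), counts.cells.copy(), mode, groups, zero_var
    )


def zscore_through_genes(zmat: ZScoreMatrix) -> ZScoreMatrix:
    """Second-pass standardization of each cell's profile across genes.

    Used after pooled (cross-stage) per-gene z-scoring to compare a gene's
    standing within each cell's overall profile between stages.
    """
    z = zmat.z
    mu = z.mean(axis=0, keepdims=True)
    sd = z.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return ZScoreMatrix(
        (z - mu) / sd, list(zmat.genes), zmat.cells.copy(),
        zmat.mode + "+through_genes", zmat.grouping, set(zmat.zero_variance),
    )


def hierarchical_cluster(
    zmat: ZScoreMatrix,
    n_clusters: int,
    metric: str = "correlation",
    linkage: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering of cells on their z profiles.

    Flat clusters come from cutting the dendrogram at ``n_clusters``;
    display order is the dendrogram leaf order.  Ward linkage requires the
    euclidean metric.
    """
    if n_clusters < 1:
        raise ValidationError("n_clusters must be >= 1")
    if metric not in ("euclidean", "correlation"):
        raise ValidationError(f"unsupported metric {metric!r}")
    if linkage not in ("ward", "average", "complete"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ValidationError("ward linkage requires the euclidean metric")
    profiles = zmat.z.T                        # cells x genes
    n = profiles.shape[0]
    if n == 0:
        raise ValidationError("no cells to cluster")
    cell_ids = zmat.cells["cell_id"].to_numpy()
    if n == 1:
        return ClusterAssignment(
            pd.Series([1], index=cell_ids), np.empty((0, 4)), cell_ids.copy()
        )
    dists = pdist(profiles, metric=metric)
    if np.isnan(dists).any():
        warnings.warn(
            "NaN distances (constant cell profiles); treating them as maximal"
        )
        dists = np.nan_to_num(dists, nan=1.0 if metric == "correlation" else np.nanmax(dists))
    Z = scipy_linkage(dists, method=linkage)
    flat = fcluster(Z, t=min(n_clusters, n), criterion="maxclust")
    leaf_order = cell_ids[leaves_list(Z)]
    return ClusterAssignment(pd.Series(flat, index=cell_ids), Z, leaf_order)


def gate_coexpression(zmat: ZScoreMatrix, module: GeneModule) -> GateResult:
    """Strict co-expression gate: z > 0 for every module gene.

    Matches the "above the mean" selection rule: for each module gene the
    cell set with z > 0 (strict) is formed, and the sets are intersected.
    """
    if not module.genes:
        raise ValidationError(f"module {module.name!r} is empty")
    rows = [zmat.gene_index(g) for g in module.genes]
    mask = np.all(zmat.z[rows, :] > 0, axis=0)
    cell_ids = zmat.cells["cell_id"].to_numpy()
    passing = set(cell_ids[mask])
    stages = zmat.cells["stage"].to_numpy()
    recs = []
    for st in pd.unique(stages):
        sel = stages == st
        n_tot = int(sel.sum())
        n_pass = int(mask[sel].sum())
        recs.append(
            {
                "stage": st, "n_pass": n_pass, "n_total": n_tot,
                "fraction": n_pass / n_tot if n_tot else 0.0,
            }
        )
    return GateResult(module, passing, pd.DataFrame(recs))


def annotate_clusters(
    assignment: ClusterAssignment,
    labels: dict[int, str],
    colors: dict[int, tuple[float, float, float]] | None = None,
) -> ClusterAssignment:
    """Attach free-text annotations (and display colors) to clusters.

    Purely metadata: cluster membership and display order are unchanged.
    Labels must cover every cluster present.
    """
    present = set(assignment.cluster_ids)
    unknown = set(labels) - present
    if unknown:
        raise ValidationError(f"labels for unknown cluster ids: {sorted(unknown)}")
    missing = present - set(labels)
    if missing:
        raise ValidationError(f"missing labels for clusters: {sorted(missing)}")
    out = ClusterAssignment(
        assignment.assignment.copy(),
        assignment.linkage_matrix,
        assignment.leaf_order.copy(),
        annotations=dict(labels),
        colors=dict(colors or assignment.colors),
    )
    return out


def plot_heatmap(
    zmat: ZScoreMatrix,
    assignment: ClusterAssignment,
    path=None,
    cmap: str = "RdBu_r",
    vlim: float = 2.5,
):
    """Gene x cell heatmap in dendrogram leaf order with a cluster strip.

    Returns the matplotlib figure; writes PNG/SVG when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cell_ids = zmat.cells["cell_id"].to_numpy()
    order = [int(np.flatnonzero(cell_ids == c)[0]) for c in assignment.leaf_order]
    z = zmat.z[:, order]
    clusters = assignment.assignment.loc[assignment.leaf_order].to_numpy()
    palette = plt.get_cmap("tab20")
    strip = np.array([palette((c - 1) % 20) for c in clusters])[None, :, :3]

    fig, (ax_strip, ax_hm) = plt.subplots(
        2, 1, figsize=(10, 6), height_ratios=[1, 24], sharex=True
    )
    ax_strip.imshow(strip, aspect="auto", interpolation="nearest")
    ax_strip.set_yticks([])
    ax_strip.set_title("subpopulations (dendrogram leaf order)", fontsize=9)
    im = ax_hm.imshow(
        z, aspect="auto", cmap=cmap, vmin=-vlim, vmax=vlim,
        interpolation="nearest",
    )
    ax_hm.set_yticks(range(len(zmat.genes)))
    ax_hm.set_yticklabels(zmat.genes, fontsize=6)
    ax_hm.set_xlabel("cells")
    fig.colorbar(im, ax=ax_hm, label="z-score", shrink=0.6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def annotations_to_json(assignment: ClusterAssignment) -> str:
    payload = {
        "annotations": {str(k): v for k, v in assignment.annotations.items()},
        "colors": {str(k): list(v) for k, v in assignment.colors.items()},
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def annotations_from_json(
    assignment: ClusterAssignment, text: str
) -> ClusterAssignment:
    payload = json.loads(text)
    labels = {int(k): v for k, v in payload["annotations"].items()}
    colors = {int(k): tuple(v) for k, v in payload.get("colors", {}).items()}
    return annotate_clusters(assignment, labels, colors or None)
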