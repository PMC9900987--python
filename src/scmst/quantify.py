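"""Spot-to-cell assignment and gene x cell count-matrix construction.

Counting is volumetric: a spot belongs to the cell whose 3D label region
contains its voxel.  Only spots gated as ``signal`` contribute to counts;
spots falling on background (label 0) or outside the volume are recorded as
unassigned and excluded.  Fields of view are combined into one matrix with
globally unique cell ids derived deterministically from (fov, local label).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ValidationError
from .segment import LabelVolume
from .spots import Codebook

__all__ = ["CountMatrix", "assign_spots_to_cells", "build_count_matrix", "concat_count_matrices"]

CELL_COLUMNS = ["cell_id", "fov", "section", "stage", "z", "y", "x", "volume_voxels"]


@dataclass
class CountMatrix:
    """Genes x cells integer count matrix with per-cell metadata.

    ``counts[i, j]`` is the number of signal spots of ``genes[i]`` assigned
    to cell ``cells.cell_id[j]``.  Gene order follows the codebook; every
    panel gene is present even when all-zero.
    """

    counts: np.ndarray
    genes: list[str]
    cells: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CELL_COLUMNS))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2D (genes x cells)")
        if self.counts.shape[0] != len(self.genes):
            raise ValidationError("row count must equal number of genes")
        if self.counts.shape[1] != len(self.cells):
            raise ValidationError("column count must equal number of cells")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise ValidationError(f"gene {gene!r} not in panel") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.genes, columns=self.cells["cell_id"].to_numpy()
        )


def global_cell_id(fov: int, local_id: int, stride: int = 100_000) -> int:
    """Flatten (fov, local label) into one deterministic global id."""
    return int(fov) * stride + int(local_id)


def assign_spots_to_cells(
    spots: pd.DataFrame, labels: LabelVolume, fov: int | None = None
) -> pd.DataFrame:
    """Set ``cell_id`` to the label value at each spot's (rounded) voxel.

    Spots outside the volume bounds get cell_id 0 with a warning giving the
    out-of-bounds count; background spots get 0.  Coordinates must already
    be in the registered frame of the label volume.
    """
    out = spots.copy()
    if out.empty:
        return out
    if fov is not None:
        sel = out["fov"].to_numpy() == fov
    else:
        sel = np.ones(len(out), dtype=bool)
    zyx = out.loc[sel, ["z", "y", "x"]].to_numpy(dtype=float)
    idx = np.round(zyx).astype(int)
    shape = np.array(labels.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    cell = np.zeros(len(idx), dtype=int)
    if inside.any():
        ii = idx[inside]
        cell[inside] = labels.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    n_oob = int((~inside).sum())
    if n_oob:
        warnings.warn(f"{n_oob} spots outside volume bounds left unassigned")
    col = out["cell_id"].to_numpy(dtype=int, copy=True)
    col[np.flatnonzero(sel)] = cell
    out["cell_id"] = col
    return out


def build_count_matrix(
    assigned_spots: pd.DataFrame,
    codebook: Codebook,
    labels: dict[int, LabelVolume] | LabelVolume,
    min_spots_per_cell: int = 0,
    min_cell_volume: float = 0.0,
    section: int = 0,
    stage: str = "",
    fov_trim: int = 0,
) -> CountMatrix:
    """Tally signal spots per gene per cell across fields of view.

    Parameters
    ----------
    assigned_spots
        Decoded, gated SpotTable with cell ids set per FOV (local labels).
    labels
        One LabelVolume, or a mapping fov -> LabelVolume.
    min_spots_per_cell, min_cell_volume
        QC filters; both default off (the reference pipeline applies no
        count-level filters).
    fov_trim
        Width (voxels, x-axis) of the overlap strip trimmed from every FOV
        after the first: cells whose centroid falls within the first
        ``fov_trim`` x-columns of FOV f>min are dropped to avoid double
        counting across tiles.
    """
    if isinstance(labels, LabelVolume):
        labels = {0: labels}
    panel = codebook.genes
    gene_to_row = {g: i for i, g in enumerate(panel)}

    spot_genes = set(assigned_spots["gene"].unique()) - {""}
    unknown = spot_genes - set(panel)
    if unknown:
        raise ConsistencyError(f"spot genes absent from codebook: {sorted(unknown)}")

    cell_rows: list[dict] = []
    col_of: dict[int, int] = {}
    first_fov = min(labels) if labels else 0
    for fov in sorted(labels):
        cents = labels[fov].centroids()
        voxel_vol = float(np.prod(labels[fov].voxel_size))
        for rec in cents.itertuples(index=False):
            if fov != first_fov and fov_trim > 0 and rec.x < fov_trim:
                continue
            if min_cell_volume > 0 and rec.volume_voxels * voxel_vol < min_cell_volume:
                continue
            gid = global_cell_id(fov, rec.cell_id)
            col_of[gid] = len(cell_rows)
            cell_rows.append(
                {
                    "cell_id": gid,
                    "fov": fov,
                    "section": section,
                    "stage": stage,
                    "z": rec.z,
                    "y": rec.y,
                    "x": rec.x,
                    "volume_voxels": rec.volume_voxels,
                }
            )
    cells = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)

    counts = np.zeros((len(panel), len(cells)), dtype=int)
    sig = assigned_spots[
        (assigned_spots["class"] == "signal") & (assigned_spots["cell_id"] > 0)
    ]
    for rec in sig.itertuples(index=False):
        gid = global_cell_id(rec.fov, rec.cell_id)
        col = col_of.get(gid)
        if col is not None:
            counts[gene_to_row[rec.gene], col] += 1

    if min_spots_per_cell > 0:
        keep = counts.sum(axis=0) >= min_spots_per_cell
        counts = counts[:, keep]
        cells = cells.loc[keep].reset_index(drop=True)
    return CountMatrix(counts, list(panel), cells)


def concat_count_matrices(matrices: list[CountMatrix]) -> CountMatrix:
    """Pool matrices (e.g. stages) sharing one gene panel, column-wise."""
    if not matrices:
        raise ValidationError("nothing to concatenate")
    panel = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != panel:
            raise ConsistencyError("count matrices have different gene panels")
    counts = np.concatenate([m.counts for m in matrices], axis=1)
    cells = pd.concat([m.cells for m in matrices], ignore_index=True)
    if cells["cell_id"].duplicated().any():
        # disambiguate pooled stages by section-major renumbering
        cells = cells.copy()
        cells["cell_id"] = (
            cells["cell_id"].to_numpy()
            + np.repeat(np.arange(len(matrices)), [m.n_cells for m in matrices])
            * 10_000_000
        )
    return CountMatrix(counts, list(panel), cells)
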