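"""3D cell segmentation and label-volume handling.

Cells are delineated with a classical seeded watershed: nuclei (DAPI) provide
seeds, the membrane stain provides the elevation map, and the flooded basins
become cell territories.  Precomputed label masks (e.g. from an external
segmenter) are accepted as first-class input through :func:`load_labels`.

Conventions: voxel coordinates are 0-based ``(z, y, x)``; label 0 is
background; positive labels are cells, relabeled ``1..K`` in lexicographic
order of their centroids so that output labeling is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .errors import FormatError, ValidationError

__all__ = ["LabelVolume", "segment_cells", "load_labels", "save_labels"]


@dataclass
class LabelVolume:
    """A 3D integer volume partitioning tissue into cells.

    Parameters
    ----------
    labels
        ``(Z, Y, X)`` non-negative integer array; 0 is background.
    voxel_size
        Physical voxel spacing in µm per axis ``(z, y, x)``.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (0.5, 0.2, 0.2)
    border_flags: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D (z, y, x) volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must be an integer volume")
        if self.labels.size and self.labels.min() < 0:
            raise FormatError("labels must be non-negative (0 = background)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    def centroids(self) -> pd.DataFrame:
        """Per-cell centroid (voxel units) and volume table."""
        ids = self.cell_ids
        if ids.size == 0:
            return pd.DataFrame(
                columns=["cell_id", "z", "y", "x", "volume_voxels", "border_flag"]
            )
        coords = ndi.center_of_mass(np.ones_like(self.labels), self.labels, ids)
        volumes = ndi.sum_labels(np.ones_like(self.labels), self.labels, ids)
        df = pd.DataFrame(coords, columns=["z", "y", "x"])
        df.insert(0, "cell_id", ids)
        df["volume_voxels"] = volumes.astype(int)
        df["border_flag"] = [self.border_flags.get(int(i), False) for i in ids]
        return df

    def validate_connectivity(self, strict: bool = False) -> list[int]:
        """Return labels that split into >1 connected component (26-conn).

        With ``strict=True`` a non-empty result raises ``ValidationError``.
        """
        bad: list[int] = []
        structure = np.ones((3, 3, 3), bool)
        objects = ndi.find_objects(self.labels)
        for i, sl in enumerate(objects, start=1):
            if sl is None:
                continue
            mask = self.labels[sl] == i
            _, n = ndi.label(mask, structure=structure)
            if n > 1:
                bad.append(i)
        if strict and bad:
            raise ValidationError(
                f"labels with disconnected components: {bad}"
            )
        return bad


def _relabel_by_centroid(labels: np.ndarray) -> np.ndarray:
    """Relabel 1..K ordered by (z, y, x) centroid — deterministic output."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels
    cents = ndi.center_of_mass(np.ones_like(labels), labels, ids)
    order = np.lexsort(tuple(np.asarray([c[ax] for c in cents]) for ax in (2, 1, 0)))
    lut = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    for new, idx in enumerate(order, start=1):
        lut[ids[idx]] = new
    return lut[labels]


def _border_flags(labels: np.ndarray) -> dict[int, bool]:
    """Flag cells touching the XY image border (handled at FOV stitching)."""
    edge = np.zeros(labels.shape, bool)
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    touching = set(np.unique(labels[edge])) - {0}
    return {int(i): (i in touching) for i in np.unique(labels) if i > 0}


def segment_cells(
    membrane: np.ndarray,
    nuclei: np.ndarray,
    min_cell_volume: float = 15.0,
    voxel_size: tuple[float, float, float] = (0.5, 0.2, 0.2),
    seed_sigma: tuple[float, float, float] = (1.0, 2.0, 2.0),
    seed_min_distance_um: float = 3.0,
) -> LabelVolume:
    """Seeded 3D watershed segmentation.

    Seeds are local maxima of the Gaussian-smoothed nuclei channel above the
    Otsu threshold, separated by at least ``seed_min_distance_um`` (local
    maxima rather than threshold components, so adjacent nuclei whose tails
    touch still seed separate cells); the membrane channel is the elevation
    map.  Basins are restricted to a tissue foreground mask (union of
    membrane and nuclei support) so that empty background stays label 0.
    Cells smaller than ``min_cell_volume`` (µm³) are discarded.

    An empty nuclei channel yields an empty :class:`LabelVolume` with a
    warning rather than an exception.
    """
    membrane = np.asarray(membrane, dtype=float)
    nuclei = np.asarray(nuclei, dtype=float)
    if membrane.shape != nuclei.shape:
        raise ValidationError("membrane and nuclei volumes must share a shape")

    smoothed = ndi.gaussian_filter(nuclei, seed_sigma)
    if smoothed.max() <= 0:
        warnings.warn("nuclei channel empty: no seeds, returning empty labels")
        return LabelVolume(np.zeros(membrane.shape, np.int32), voxel_size)
    thr = threshold_otsu(smoothed)
    half = np.maximum(
        (seed_min_distance_um / np.asarray(voxel_size) / 2).astype(int), 1
    )
    footprint = np.ones(2 * half + 1, dtype=bool)
    peaks = peak_local_max(
        smoothed, footprint=footprint, threshold_abs=float(thr),
        exclude_border=False,
    )
    if len(peaks) == 0:
        warnings.warn("no nuclei above threshold: returning empty labels")
        return LabelVolume(np.zeros(membrane.shape, np.int32), voxel_size)
    seeds = np.zeros(membrane.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        seeds[tuple(p)] = i

    # Tissue cannot be told from cell interiors by intensity (both are
    # dark); enclosure by the membrane ring is the cue.  A generous mask is
    # built by filling the ring plane-wise (a cell clipped by the stack
    # border is open in 3D but still ringed in each xy section); its
    # complement seeds a background basin, and flooding the membrane
    # elevation from nuclei + background markers puts each cell/background
    # boundary on the ridge crest — the true cell surface.
    elevation = ndi.gaussian_filter(membrane, (0.5, 1.0, 1.0))
    signal = elevation + smoothed
    fg = signal > threshold_otsu(signal)
    fg = ndi.binary_closing(fg, np.ones((1, 3, 3), bool))
    for z in range(fg.shape[0]):
        fg[z] = ndi.binary_fill_holes(fg[z])
    bg_label = len(peaks) + 1
    markers = seeds.copy()
    markers[~ndi.binary_dilation(fg, np.ones((1, 3, 3), bool))] = bg_label
    labels = watershed(elevation, markers=markers).astype(np.int32)
    labels[labels == bg_label] = 0

    voxel_vol = float(np.prod(voxel_size))
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    too_small = ids[counts * voxel_vol < min_cell_volume]
    if too_small.size:
        labels[np.isin(labels, too_small)] = 0
    labels = _relabel_by_centroid(labels)
    return LabelVolume(labels, voxel_size, border_flags=_border_flags(labels))


def save_labels(path, volume: LabelVolume) -> None:
    """Write labels as TIFF, promoting to 32-bit when 16-bit would overflow."""
    labels = volume.labels
    dtype = np.uint16 if (labels.size == 0 or labels.max() < 2**16) else np.uint32
    tifffile.imwrite(str(path), labels.astype(dtype))


def load_labels(
    path,
    voxel_size: tuple[float, float, float] = (0.5, 0.2, 0.2),
    min_cell_volume: float = 0.0,
    strict_connectivity: bool = False,
) -> LabelVolume:
    """Load a precomputed label mask from TIFF and validate it."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"{path}: label volume has non-integer values")
        arr = np.round(arr).astype(np.int64)
    if arr.size and arr.min() < 0:
        raise FormatError(f"{path}: label volume has negative values")
    arr = arr.astype(np.int32 if arr.max(initial=0) < 2**31 else np.int64)
    if min_cell_volume > 0:
        voxel_vol = float(np.prod(voxel_size))
        ids, counts = np.unique(arr[arr > 0], return_counts=True)
        small = ids[counts * voxel_vol < min_cell_volume]
        if small.size:
            arr[np.isin(arr, small)] = 0
    vol = LabelVolume(arr, voxel_size, border_flags=_border_flags(arr))
    vol.validate_connectivity(strict=strict_connectivity)
    return vol
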