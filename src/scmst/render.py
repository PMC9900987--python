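"""Spatial back-mapping: pseudo-coloring cells in the original section.

Each segmented cell is painted with the color of its transcriptional
subpopulation (or of a co-expression gate it passes) on a 2D projection of
the label volume, reproducing the heatmap-to-tissue visualization that ties
expression profiles back to their anatomical position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

from .errors import ValidationError
from .segment import LabelVolume

__all__ = ["BackmapImage", "backmap", "save_backmap"]

NEUTRAL_CELL = (0.55, 0.55, 0.55)
BACKGROUND = (0.0, 0.0, 0.0)


@dataclass
class BackmapImage:
    """RGB rendering of a label projection plus its color legend."""

    rgb: np.ndarray                                 # (Y, X, 3) float in [0, 1]
    legend: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    provenance: str = ""


def _project_labels(labels: np.ndarray, projection: str, plane: int | None) -> np.ndarray:
    if projection == "max_z":
        return labels.max(axis=0)
    if projection == "plane":
        if plane is None or not (0 <= plane < labels.shape[0]):
            raise ValidationError(
                f"plane index {plane} out of range for {labels.shape[0]} planes"
            )
        return labels[plane]
    raise ValidationError(f"unknown projection {projection!r}")


def backmap(
    labels: LabelVolume,
    coloring: dict[int, tuple[float, float, float]],
    projection: str = "max_z",
    plane: int | None = None,
    neutral: tuple[float, float, float] = NEUTRAL_CELL,
    background: tuple[float, float, float] = BACKGROUND,
    underlay: np.ndarray | None = None,
    underlay_opacity: float = 0.5,
    legend: dict[str, tuple[float, float, float]] | None = None,
    provenance: str = "",
) -> BackmapImage:
    """Paint cells by group color on a z projection of the label volume.

    Cells absent from ``coloring`` are painted ``neutral``; label 0 gets
    ``background``.  ``projection="max_z"`` takes the maximum label along z
    (how 2D figures summarize a 20 µm section); ``projection="plane"`` with
    ``plane=k`` shows a single optical plane.  An optional grayscale
    ``underlay`` (e.g. the membrane channel, same projection applied) is
    alpha-blended under the colors.
    """
    proj = _project_labels(labels.labels, projection, plane)
    max_label = int(proj.max(initial=0))
    lut = np.empty((max_label + 1, 3), dtype=float)
    lut[:] = neutral
    lut[0] = background
    for cell, color in coloring.items():
        if 0 < cell <= max_label:
            lut[cell] = color
    rgb = lut[proj]
    if underlay is not None:
        under = np.asarray(underlay, dtype=float)
        if under.ndim == 3:
            under = under.max(axis=0) if projection == "max_z" else under[plane]
        if under.shape != proj.shape:
            raise ValidationError("underlay shape does not match projection")
        rng = np.ptp(under)
        under = (under - under.min()) / rng if rng else np.zeros_like(under)
        a = float(underlay_opacity)
        rgb = np.clip((1 - a) * rgb + a * under[..., None], 0, 1)
    return BackmapImage(rgb, dict(legend or {}), provenance)


def save_backmap(path, image: BackmapImage) -> None:
    """Write the rendering as 8-bit PNG."""
    arr = np.clip(np.round(image.rgb * 255), 0, 255).astype(np.uint8)
    iio.imwrite(str(path), arr, extension=".png")
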