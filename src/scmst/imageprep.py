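"""Pre-filtering and inter-round alignment of raw image stacks.

The documented preprocessing order is: retrospective flat-field correction
(per channel), 3x3x3 median filtering to suppress shot noise ahead of spot
detection, then integer-voxel translational registration of each
hybridization round to the reference round.  Rotation, scaling and nonrigid
motion are out of scope: rounds are acquired on the same mounted coverslip,
so residual motion is translational drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "FlatField",
    "RoundShift",
    "estimate_flatfield",
    "correct_illumination",
    "median_filter_3d",
    "register_rounds",
    "translate",
]


@dataclass
class FlatField:
    """Multiplicative shading field (mean 1) with optional additive offset."""

    flatfield: np.ndarray
    darkfield: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.flatfield = np.asarray(self.flatfield, dtype=float)
        if self.flatfield.min() <= 0:
            raise ValidationError("flatfield must be strictly positive everywhere")
        if abs(self.flatfield.mean() - 1.0) > 1e-6:
            raise ValidationError("flatfield must be normalized to spatial mean 1")
        if np.any(np.asarray(self.darkfield) < 0):
            raise ValidationError("darkfield must be non-negative")

    @classmethod
    def from_unnormalized(cls, field: np.ndarray, darkfield=0.0) -> "FlatField":
        field = np.asarray(field, dtype=float)
        field = np.maximum(field, 1e-6)
        return cls(field / field.mean(), darkfield)


@dataclass
class RoundShift:
    """Integer translation aligning one round to the reference round."""

    round: int
    shift: tuple[int, int, int]
    score: float
    low_confidence: bool = False


def _polyfit_surface(img: np.ndarray, order: int) -> np.ndarray:
    """Least-squares polynomial surface fit of a 2D image."""
    ny, nx = img.shape
    y, x = np.mgrid[0:ny, 0:nx]
    y = (y / max(ny - 1, 1)) * 2 - 1
    x = (x / max(nx - 1, 1)) * 2 - 1
    cols = [
        (y**i * x**j).ravel()
        for i in range(order + 1)
        for j in range(order + 1 - i)
    ]
    A = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(A, img.ravel(), rcond=None)
    return (A @ coef).reshape(img.shape)


def estimate_flatfield(
    planes: np.ndarray | list[np.ndarray],
    method: str = "median-poly",
    poly_order: int = 2,
    smooth_sigma: float | None = None,
    estimate_darkfield: bool = False,
) -> FlatField:
    """Retrospective flat-field estimate from a collection of planes.

    Stacks the planes of one channel (3D volumes are unrolled into their z
    planes), takes the per-pixel median — robust against the sparse spot
    content — and regularizes it into a smooth field.

    Parameters
    ----------
    planes
        Array ``(n, Y, X)``, or a list of 2D planes / 3D volumes with a
        common in-plane shape.  At least 2 planes required, >= 8 recommended.
    method
        ``"median-poly"`` (default): fit a low-order polynomial surface to
        the median image — matches a smooth shading model exactly.
        ``"median-smooth"``: heavy Gaussian smoothing of the median image.
    estimate_darkfield
        If True, use the 1st percentile across planes as an additive offset
        estimate (default off).
    """
    if isinstance(planes, (list, tuple)):
        arrs = []
        for p in planes:
            p = np.asarray(p, dtype=float)
            arrs.extend(p if p.ndim == 3 else [p])
        if not arrs:
            raise InsufficientDataError("no planes provided")
        stack = np.stack(arrs)
    else:
        stack = np.asarray(planes, dtype=float)
        if stack.ndim == 2:
            stack = stack[None]
    if stack.shape[0] < 2:
        raise InsufficientDataError(
            f"flat-field estimation needs >= 2 planes, got {stack.shape[0]}"
        )
    if stack.shape[0] < 8:
        warnings.warn("fewer than 8 planes: flat-field estimate may be noisy")

    dark: np.ndarray | float = 0.0
    if estimate_darkfield:
        dark = np.percentile(stack, 1, axis=0)
        dark = ndi.gaussian_filter(dark, min(stack.shape[1:]) / 8)
    med = np.median(stack - dark, axis=0)
    if method == "median-poly":
        field = _polyfit_surface(med, poly_order)
    elif method == "median-smooth":
        sigma = smooth_sigma if smooth_sigma is not None else min(med.shape) / 8
        field = ndi.gaussian_filter(med, sigma)
    else:
        raise ValidationError(f"unknown flat-field method {method!r}")
    return FlatField.from_unnormalized(field, dark)


def correct_illumination(volume: np.ndarray, flatfield: FlatField) -> np.ndarray:
    """Apply ``(volume - darkfield) / flatfield``, clipped at 0.

    A 2D flat field broadcasts over the z axis of a 3D volume.
    """
    volume = np.asarray(volume, dtype=float)
    field = flatfield.flatfield
    if np.any(field <= 0):
        raise ValidationError("flatfield contains nonpositive values")
    if volume.ndim == 3 and field.ndim == 2:
        field = field[None]
    out = (volume - flatfield.darkfield) / field
    return np.clip(out, 0, None)


def median_filter_3d(volume: np.ndarray, kernel: int = 3) -> np.ndarray:
    """3D median filter with a ``kernel**3`` neighborhood, reflected borders.

    The 3x3x3 default mirrors the standard despeckling step applied before
    spot detection.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValidationError(f"kernel must be odd and >= 1, got {kernel}")
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValidationError("median_filter_3d expects a 3D volume")
    return ndi.median_filter(volume, size=kernel, mode="reflect")


def register_rounds(
    reference: np.ndarray,
    moving: np.ndarray,
    max_shift: int = 10,
    round_: int = 0,
    score_floor: float = 0.2,
) -> RoundShift:
    """Find the integer translation of ``moving`` best matching ``reference``.

    The translation maximizing the cross-correlation (computed via FFT on
    mean-subtracted volumes, restricted to the ``±max_shift`` search window)
    is returned together with the normalized cross-correlation score of the
    overlapping region at that shift.  Applying ``-shift`` to ``moving``
    aligns it to ``reference``.  A score below ``score_floor`` marks the
    result low-confidence.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValidationError("reference and moving volumes must share a shape")
    if any(2 * max_shift >= s for s in reference.shape):
        raise ValidationError(
            f"max_shift {max_shift} too large for shape {reference.shape}"
        )
    ref = reference - reference.mean()
    mov = moving - moving.mean()
    cc = np.real(np.fft.ifftn(np.fft.fftn(mov) * np.conj(np.fft.fftn(ref))))
    # circular lags: index t corresponds to shift t (or t - N for t > N/2)
    window = np.ix_(*[
        np.concatenate([np.arange(0, max_shift + 1), np.arange(-max_shift, 0)]) % s
        for s in cc.shape
    ])
    sub = cc[window]
    flat = int(np.argmax(sub))
    idx = np.unravel_index(flat, sub.shape)
    shift = tuple(
        int(i) if i <= max_shift else int(i) - (2 * max_shift + 1)
        for i in idx
    )
    score = _overlap_ncc(reference, moving, shift)
    result = RoundShift(round_, shift, float(score), bool(score < score_floor))
    if result.low_confidence:
        warnings.warn(
            f"round {round_}: registration score {score:.3f} below floor "
            f"{score_floor}; shift {shift} is low-confidence"
        )
    return result


def _overlap_ncc(reference: np.ndarray, moving: np.ndarray, shift) -> float:
    """Pearson correlation of reference vs moving shifted back by ``shift``."""
    ref_sl, mov_sl = [], []
    for s, n in zip(shift, reference.shape):
        if s >= 0:
            ref_sl.append(slice(0, n - s))
            mov_sl.append(slice(s, n))
        else:
            ref_sl.append(slice(-s, n))
            mov_sl.append(slice(0, n + s))
    a = reference[tuple(ref_sl)].ravel()
    b = moving[tuple(mov_sl)].ravel()
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def translate(volume: np.ndarray, shift, fill: float = 0.0) -> np.ndarray:
    """Integer translation with constant fill (lossless within bounds).

    ``translate(v, s)`` moves content so that the voxel at position p ends
    up at p + s; out-of-canvas voxels are filled with ``fill``.
    """
    volume = np.asarray(volume)
    out = np.full_like(volume, fill)
    src, dst = [], []
    for s, n in zip(shift, volume.shape):
        s = int(s)
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = volume[tuple(src)]
    return out
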