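"""Stack preparation: slice alignment, intensity normalization, seeding blur.

FIB/SEM block-face images are nearly aligned by construction; the residual
per-slice drift is a small rigid translation, so registration here is
translation-only by design: each slice is matched against its predecessor by
exhaustive normalized cross-correlation over an integer shift window
(default ±20 px) and the stack is cropped to the always-valid common field.  No
rotation, scaling, or sub-pixel interpolation is applied.

Normalization compensates the slow detector/charging drift of the signal by
affinely rescaling each slice to a stack-wide reference (median of slice means
and SDs), and the "blurred" companion stack used for seed-based segmentation
is a per-slice 2D Gaussian with a 10-pixel radius (interpreted as
sigma = radius / 2, a common imaging-GUI convention; the kernel is
configurable).  Blur boundaries are reflective; measurements are never taken
on the blurred stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .stack import ImageStack

__all__ = [
    "AlignmentResult",
    "NormalizationResult",
    "align_translation",
    "normalize_slices",
    "blur_stack",
]


@dataclass
class AlignmentResult:
    """Per-slice translation estimates from pairwise registration.

    ``shifts`` are (dy, dx) of each slice relative to its predecessor (the
    first slice is the (0, 0) anchor); ``cumulative`` accumulates them
    relative to slice 0.  ``correction`` (= -cumulative) is what was applied
    to bring every slice into the slice-0 frame.  ``crop`` is the (y0, y1,
    x0, x1) window of the common always-valid field after correction.
    """

    shifts: np.ndarray
    cumulative: np.ndarray
    crop: tuple[int, int, int, int]
    flat_slices: list[int] = field(default_factory=list)
    boundary_limited: list[int] = field(default_factory=list)

    @property
    def correction(self) -> np.ndarray:
        return -self.cumulative


def _pairwise_shift(prev: np.ndarray, curr: np.ndarray, max_shift: int):
    """NCC argmax shift of ``curr`` relative to ``prev`` over ±max_shift.

    Returns ((dy, dx), boundary_limited).  The interior of ``prev`` (margin
    ``max_shift``) is used as the template and matched at every position in
    ``curr`` (skimage's normalized cross-correlation), which is exactly the
    exhaustive integer-shift search over the (2m+1)^2 window.  Ties go to
    the smaller shift magnitude, which makes the identity case exact.
    """
    m = max_shift
    template = prev[m:-m, m:-m].astype(np.float64)
    ncc = match_template(curr.astype(np.float64), template)
    best = float(ncc.max())
    cands = np.argwhere(ncc >= best - 1e-12)
    dy, dx = min(((int(i) - m, int(j) - m) for i, j in cands),
                 key=lambda s: (s[0] ** 2 + s[1] ** 2, s))
    boundary = abs(dy) == m or abs(dx) == m
    return (dy, dx), boundary


def align_translation(stack: ImageStack, max_shift_px: int = 20) -> tuple[ImageStack, AlignmentResult]:
    """Rigid registration without rotation: translation-only slice alignment.

    Each slice is registered to the previous slice by exhaustive integer-shift
    normalized cross-correlation; the returned stack has every slice moved
    into the frame of slice 0 and is cropped to the window that is valid in
    all slices.  Zero-variance (flat) slices have an undefined shift and are
    assigned (0, 0) with a warning flag; an NCC maximum on the window border
    is flagged boundary-limited.
    """
    grid = stack.grid
    nz, ny, nx = grid.shape
    if nz < 2:
        raise ValueError("alignment needs at least 2 slices")
    if max_shift_px < 1 or max_shift_px >= min(ny, nx) // 2:
        raise ValueError(f"max_shift_px={max_shift_px} must be in [1, slice extent/2)")

    shifts = np.zeros((nz, 2), dtype=int)
    flat: list[int] = []
    boundary: list[int] = []
    for z in range(1, nz):
        prev, curr = grid[z - 1], grid[z]
        if float(prev.std()) == 0.0 or float(curr.std()) == 0.0:
            flat.append(z)
            continue
        (dy, dx), at_border = _pairwise_shift(prev, curr, max_shift_px)
        shifts[z] = (dy, dx)
        if at_border:
            boundary.append(z)

    cumulative = np.cumsum(shifts, axis=0)
    aligned = np.empty_like(grid)
    aligned[0] = grid[0]
    for z in range(1, nz):
        dy, dx = -cumulative[z]
        aligned[z] = np.roll(grid[z], (dy, dx), axis=(0, 1))

    # Common always-valid window: rolling by (dy,dx) invalidates a border of
    # |dy| rows / |dx| cols on one side of each slice.
    corr = -cumulative
    y0 = int(max(0, corr[:, 0].max()))
    y1 = int(ny + min(0, corr[:, 0].min()))
    x0 = int(max(0, corr[:, 1].max()))
    x1 = int(nx + min(0, corr[:, 1].min()))
    if y1 <= y0 or x1 <= x0:
        raise ValueError("cumulative shifts leave no common field of view")
    out = stack.with_grid(aligned[:, y0:y1, x0:x1], note=f"align_translation(max_shift={max_shift_px})")
    return out, AlignmentResult(shifts=shifts, cumulative=cumulative, crop=(y0, y1, x0, x1),
                                flat_slices=flat, boundary_limited=boundary)


@dataclass
class NormalizationResult:
    """Applied per-slice affine corrections: out = gain * slice + offset."""

    gains: np.ndarray
    offsets: np.ndarray
    ref_mean: float
    ref_sd: float


def normalize_slices(stack: ImageStack) -> tuple[ImageStack, NormalizationResult]:
    """Match every slice's mean and SD to the stack-wide reference.

    The reference is the median of slice means and the median of slice SDs —
    robust to a few outlier slices.  Zero-SD slices are shifted in mean only.
    The operation is idempotent up to floating-point rounding.
    """
    grid = np.asarray(stack.grid, dtype=np.float64)
    means = grid.mean(axis=(1, 2))
    sds = grid.std(axis=(1, 2))
    ref_mean = float(np.median(means))
    ref_sd = float(np.median(sds))

    gains = np.where(sds > 0, ref_sd / np.where(sds > 0, sds, 1.0), 1.0)
    offsets = ref_mean - gains * means
    out = grid * gains[:, None, None] + offsets[:, None, None]
    res = NormalizationResult(gains=gains, offsets=offsets, ref_mean=ref_mean, ref_sd=ref_sd)
    return stack.with_grid(out.astype(np.float32), note="normalize_slices"), res


def blur_stack(stack: ImageStack, radius_px: float = 10.0) -> ImageStack:
    """Per-slice 2D Gaussian blur used only for seed-based segmentation.

    ``radius_px`` follows the GUI convention sigma = radius / 2; radius 0 is
    the identity.  Boundaries are reflective, which conserves total intensity
    for the symmetric kernel.
    """
    if radius_px < 0:
        raise ValueError("blur radius must be >= 0")
    if radius_px == 0:
        return stack.with_grid(stack.grid.copy(), note="blur_stack(radius=0)")
    sigma = radius_px / 2.0
    out = np.empty(stack.grid.shape, dtype=np.float32)
    for z in range(stack.grid.shape[0]):
        out[z] = ndimage.gaussian_filter(stack.grid[z].astype(np.float32), sigma=sigma, mode="reflect")
    return stack.with_grid(out, note=f"blur_stack(radius={radius_px})")
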