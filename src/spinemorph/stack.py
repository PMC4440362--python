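"""Image-stack container and multi-page TIFF I/O.

A FIB/SEM acquisition is a stack of serial block-face images: the milling
direction is Z (one TIFF page per slice) and the imaging plane is XY.  Voxels
are strongly anisotropic — the default geometry is 3.7 nm/pixel in XY and
25 nm slice thickness in Z — so every physical measurement downstream must go
through the spacing stored here, never through raw voxel counts.

Conventions (used package-wide):

* arrays are stored in ``(z, y, x)`` order;
* ``spacing`` is expressed in nm per axis in ``(x, y, z)`` order, matching how
  acquisition geometry is usually quoted (XY pixel size first);
* world coordinates are voxel centers at ``index * spacing``, 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]

DEFAULT_SPACING = (3.7, 3.7, 25.0)


@dataclass
class ImageStack:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    grid
        Intensity array, ``(z, y, x)`` order.
    spacing
        Voxel spacing in nm, ``(x, y, z)`` order.
    provenance
        Free-form processing log (source path, operations applied).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"stack grid must be 3D (z,y,x), got ndim={self.grid.ndim}")
        if self.grid.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive nm values, got {self.spacing}")
        if np.issubdtype(self.grid.dtype, np.floating) and not np.all(np.isfinite(self.grid)):
            raise ValueError("stack intensities must be finite")

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        sx, sy, sz = self.spacing
        return (sz, sy, sx)

    @property
    def n_slices(self) -> int:
        return self.grid.shape[0]

    @property
    def voxel_volume_nm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_grid(self, grid: np.ndarray, note: str | None = None) -> "ImageStack":
        """Return a copy holding ``grid``, appending ``note`` to the log."""
        log = list(self.provenance) + ([note] if note else [])
        return replace(self, grid=grid, provenance=log)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF, one page per Z slice.

    The spacing (nm) is embedded losslessly as JSON in the image description
    tag so a round trip through :func:`read_stack` preserves it.
    """
    meta = json.dumps({"spacing_nm_xyz": list(stack.spacing)})
    tifffile.imwrite(str(path), stack.grid, description=meta,
                     photometric="minisblack")


def read_stack(path, spacing: tuple[float, float, float] | None = None) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    ``spacing`` overrides any spacing embedded in the file; if neither is
    available the default acquisition geometry (3.7, 3.7, 25) nm is assumed.
    Raises ``ValueError`` for files whose pages disagree in shape.
    """
    with tifffile.TiffFile(str(path)) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page sizes in {path}: {sorted(shapes)}")
        grid = tf.asarray()
        desc = tf.pages[0].description
    if grid.ndim == 2:  # single-page stack
        grid = grid[None]
    if spacing is None:
        spacing = DEFAULT_SPACING
        if desc:
            try:
                spacing = tuple(json.loads(desc)["spacing_nm_xyz"])
            except (json.JSONDecodeError, KeyError, TypeError):
                pass
    return ImageStack(grid=grid, spacing=spacing, provenance=[f"read:{path}"])
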