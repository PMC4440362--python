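"""Volume, surface area, sphericity and branched-spine splitting.

Measurements are taken directly on the unsmoothed voxel masks — no mask
morphology and no mesh smoothing — mirroring the reproducible "absolute
intensity, maximal thresholding, no smoothing" object-generation convention.
Two surface estimators are provided:

``voxel_face`` (default)
    Sum of exposed voxel-face areas using the anisotropic face areas.  It
    systematically overestimates the area of smooth objects (a digitized ball
    converges to ~1.5x the analytic 4*pi*r^2, the classic staircase factor),
    but the bias is shared by all objects measured at the same voxel size, so
    within-study comparisons remain valid.

``mesh``
    Area of the marching-cubes iso-surface, without smoothing; converges to
    the true area within a few percent.  For the mesh method the sphericity
    uses the mesh-enclosed volume (divergence theorem) so that the
    isoperimetric bound (sphericity <= 1) holds exactly for every closed
    triangulated surface.

Wadell sphericity = (surface area of the equal-volume sphere) / (surface area
of the object) = pi^(1/3) * (6 V)^(2/3) / A.  A ball scores 1; elongated or
complex shapes score progressively lower.  Sphericities are only comparable
within one surface method — records carry the method tag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import marching_cubes, mesh_surface_area
from skimage.segmentation import watershed

from ._centerline import edt_nm, spine_anatomy

__all__ = [
    "MorphometryRecord",
    "measure_volume",
    "measure_surface_area",
    "mesh_area_volume",
    "sphericity",
    "eq_diameter",
    "measure_object",
    "measure_synapse",
    "split_branched",
]


@dataclass
class MorphometryRecord:
    """Per-object 3D measurements, all in nm-based units."""

    object_id: int
    volume_nm3: float
    surface_area_nm2: float
    sphericity: float
    eq_diameter_nm: float
    method: str  # "voxel_face" | "mesh"


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (z,y,x)")
    if not mask.any():
        raise ValueError("empty mask")
    return mask


def measure_volume(mask: np.ndarray, spacing) -> float:
    """Voxel-count volume: n_voxels * sx * sy * sz, in nm^3."""
    mask = _check_mask(mask)
    sx, sy, sz = (float(s) for s in spacing)
    if min(sx, sy, sz) <= 0:
        raise ValueError("spacing must be positive")
    return float(mask.sum()) * sx * sy * sz


def measure_surface_area(mask: np.ndarray, spacing, method: str = "voxel_face") -> float:
    """Surface area (nm^2) of a mask by exposed voxel faces or a mesh.

    ``spacing`` is (sx, sy, sz) nm.  Face areas are anisotropic: faces
    perpendicular to x have area sy*sz, to y sx*sz, to z sx*sy.
    """
    mask = _check_mask(mask)
    sx, sy, sz = (float(s) for s in spacing)
    if method == "voxel_face":
        padded = np.pad(mask, 1)
        n_z = int(np.count_nonzero(np.diff(padded, axis=0)))  # faces perp. to z
        n_y = int(np.count_nonzero(np.diff(padded, axis=1)))
        n_x = int(np.count_nonzero(np.diff(padded, axis=2)))
        return n_z * sx * sy + n_y * sx * sz + n_x * sy * sz
    if method == "mesh":
        area, _ = mesh_area_volume(mask, spacing)
        return area
    raise ValueError(f"unknown surface method {method!r}")


def mesh_area_volume(mask: np.ndarray, spacing) -> tuple[float, float]:
    """Marching-cubes surface area (nm^2) and enclosed volume (nm^3).

    The mask itself is never smoothed; for sub-voxel surface localization the
    iso-surface is extracted at level 0.5 from a lightly anti-aliased copy of
    the 0/1 indicator field (Gaussian, sigma = 1 voxel).  Without this the
    zero-order binary surface overestimates a ball's area by ~8%.  Volume is
    the divergence-theorem sum of signed tetrahedra, which pairs consistently
    with the mesh area (so the isoperimetric bound holds for any closed
    triangulation).
    """
    from scipy.ndimage import gaussian_filter

    mask = _check_mask(mask)
    sx, sy, sz = (float(s) for s in spacing)
    padded = np.pad(mask, 2).astype(np.float32)
    field = gaussian_filter(padded, sigma=1.0, mode="constant")
    verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=(sz, sy, sx))
    area = float(mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = float(abs(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0))
    return area, vol


def sphericity(volume: float, surface_area: float) -> float:
    """Wadell sphericity pi^(1/3) * (6 V)^(2/3) / A (dimensionless)."""
    if volume <= 0 or surface_area <= 0:
        raise ValueError("volume and surface area must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area)


def eq_diameter(volume: float) -> float:
    """Sphere-equivalent diameter (6 V / pi)^(1/3), nm."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return float((6.0 * volume / np.pi) ** (1.0 / 3.0))


def measure_object(mask: np.ndarray, spacing, object_id: int = 0,
                   method: str = "voxel_face") -> MorphometryRecord:
    """Compose volume + area + sphericity + equivalent diameter for one mask.

    The record's volume is always the voxel-count volume.  With the mesh
    method, sphericity is computed from the mesh area together with the
    mesh-enclosed volume (see module docstring).
    """
    vol = measure_volume(mask, spacing)
    if method == "mesh":
        area, mesh_vol = mesh_area_volume(mask, spacing)
        sph = sphericity(mesh_vol, area)
    else:
        area = measure_surface_area(mask, spacing, method=method)
        sph = sphericity(vol, area)
    return MorphometryRecord(object_id=object_id, volume_nm3=vol, surface_area_nm2=area,
                             sphericity=sph, eq_diameter_nm=eq_diameter(vol), method=method)


def measure_synapse(junction_mask: np.ndarray, spacing, object_id: int = 0,
                    method: str = "voxel_face") -> MorphometryRecord:
    """Measure a synaptic junction (PSD + apposed presynaptic membrane).

    Synapse size is the volume of the traced junction object; the same
    volume/area/sphericity composition as any other object.
    """
    return measure_object(junction_mask, spacing, object_id=object_id, method=method)


def _snap_to_mask(mask: np.ndarray, c, reach: int = 2):
    """Nearest in-mask voxel within a small neighborhood of ``c`` (or None)."""
    if mask[c]:
        return c
    z, y, x = c
    best, best_d = None, None
    for dz in range(-reach, reach + 1):
        for dy in range(-reach, reach + 1):
            for dx in range(-reach, reach + 1):
                q = (z + dz, y + dy, x + dx)
                if all(0 <= qi < s for qi, s in zip(q, mask.shape)) and mask[q]:
                    d = dz * dz + dy * dy + dx * dx
                    if best is None or d < best_d:
                        best, best_d = q, d
    return best


def split_branched(spine_mask: np.ndarray, spacing,
                   head_factor: float = 1.2) -> tuple[list[np.ndarray], bool]:
    """Cut a branched spine into individual spines at the shared neck isthmus.

    Heads are skeleton endpoints whose branch carries an inscribed ball larger
    than ``head_factor`` times the neck scale.  With one head the input is
    returned unchanged (branched flag False).  With >= 2 heads the mask is
    partitioned by a watershed on the negated distance transform seeded at the
    head centers: the watershed ridge falls on the thinnest cross-section of
    the shared neck between the branch points.  Output masks are pairwise
    disjoint and their union equals the input.

    Returns (list of masks, branched_flag).
    """
    mask = _check_mask(spine_mask)
    spacing_zyx = (spacing[2], spacing[1], spacing[0])
    a = spine_anatomy(mask, spacing_zyx, head_factor=head_factor)
    head_centers = sorted(set(tuple(c) for c, _ in a["heads"]))
    if len(head_centers) < 2:
        return [mask], False
    edt = edt_nm(mask, spacing_zyx)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, c in enumerate(head_centers, start=1):
        c = _snap_to_mask(mask, c)
        if c is not None:
            markers[c] = i
    labels = watershed(-edt, markers=markers, mask=mask)
    out = [labels == i for i in range(1, len(head_centers) + 1)]
    return [m for m in out if m.any()], True
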