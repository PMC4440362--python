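"""Seed-based segmentation and shaft/spine separation.

DAB-labeled structures are dark, so objects are grown from user seeds on the
blurred companion stack as the 26-connected component of voxels at or below
an absolute intensity threshold containing the seed — no morphological
smoothing before or after, so the object is exactly the thresholded
component.  Synapses and boutons, traced by hand in practice, enter as
painted label volumes with a sidecar category table; touching junction
labels are never merged (each traced junction is one object).

``split_dendrite`` separates the segmented dendrite into its shaft and
candidate spines.  The shaft is modeled as the maximal inscribed tube along
the dendrite's principal path: mask voxels are binned into stations along
the EDT-weighted principal axis (the sampled dendrites are straight
segments by selection) and the thickest voxel per station, within the shaft
corridor, forms the centerline; the tube radius is the median
inscribed-ball radius along it.  Each protrusion left outside the tube is
cut at the base of its neck "in 3D optimal orientation": the cut surface is
the iso-distance shell from the shaft centerline at the smallest distance
whose cross-sectional area is within 5% of the minimum over the first 30% of
the protrusion's length.  Branched spines remain single masks here; they are
individualized later at the shared neck isthmus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .stack import ImageStack

__all__ = [
    "VoxelSegmentation",
    "seed_grow",
    "import_labels",
    "write_labels",
    "split_dendrite",
    "SplitResult",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

CATEGORIES = ("dendrite_shaft", "spine", "synaptic_junction", "bouton")


@dataclass
class VoxelSegmentation:
    """Integer label grid plus the object table describing each label.

    ``labels`` is (z, y, x) with 0 = background; ``objects`` has at least
    columns ``id`` and ``category`` (optionally ``labeled``, ``seed``,
    ``threshold``).  Objects are 26-connected unless flagged otherwise.
    """

    labels: np.ndarray
    objects: pd.DataFrame
    spacing: tuple[float, float, float] = (3.7, 3.7, 25.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3D (z,y,x)")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")
        present = set(np.unique(self.labels)) - {0}
        table = set(int(i) for i in self.objects.get("id", pd.Series(dtype=int)))
        missing = present - table
        if missing:
            raise ValueError(f"labels present in grid but absent from object table: {sorted(missing)[:10]}")

    def mask(self, object_id: int) -> np.ndarray:
        return self.labels == object_id

    def ids_of_category(self, category: str) -> list[int]:
        sel = self.objects[self.objects["category"] == category]
        return [int(i) for i in sel["id"]]


def seed_grow(blurred: ImageStack, seed: tuple[int, int, int],
              intensity_threshold: float, dark: bool = True) -> np.ndarray:
    """Grow the 26-connected thresholded component containing ``seed``.

    ``seed`` is a (z, y, x) voxel index.  With ``dark`` (the DAB convention)
    the predicate is intensity <= threshold; pass ``dark=False`` for bright
    objects.  The seed itself must satisfy the predicate.  No smoothing is
    applied — the mask is exactly the thresholded component.
    """
    grid = blurred.grid
    seed = tuple(int(i) for i in seed)
    if any(i < 0 or i >= s for i, s in zip(seed, grid.shape)):
        raise ValueError(f"seed {seed} outside grid {grid.shape}")
    predicate = grid <= intensity_threshold if dark else grid >= intensity_threshold
    if not predicate[seed]:
        raise ValueError(f"seed intensity {grid[seed]:.4g} fails the threshold "
                         f"predicate ({'<=' if dark else '>='} {intensity_threshold})")
    lab, _ = ndimage.label(predicate, structure=_CONN26)
    return lab == lab[seed]


def import_labels(label_path, sidecar_path, spacing=(3.7, 3.7, 25.0),
                  expected_shape=None) -> VoxelSegmentation:
    """Load a painted label TIFF with its sidecar category CSV.

    The sidecar must map every label id present in the grid to a category
    (columns ``id``, ``category``; optional ``labeled``).  Touching labels
    stay distinct objects — junctions traced independently are never merged.
    """
    labels = tifffile.imread(str(label_path))
    if labels.ndim == 2:
        labels = labels[None]
    if expected_shape is not None and tuple(labels.shape) != tuple(expected_shape):
        raise ValueError(f"label grid shape {labels.shape} does not match "
                         f"stack shape {tuple(expected_shape)}")
    table = pd.read_csv(sidecar_path)
    if "id" not in table.columns or "category" not in table.columns:
        raise ValueError("sidecar must have 'id' and 'category' columns")
    bad = set(table["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories in sidecar: {sorted(bad)}")
    if "labeled" not in table.columns:
        table = table.assign(labeled=True)
    return VoxelSegmentation(labels=labels.astype(np.int32), objects=table, spacing=spacing)


def write_labels(seg: VoxelSegmentation, label_path, sidecar_path) -> None:
    tifffile.imwrite(str(label_path), seg.labels.astype(np.int32),
                     photometric="minisblack")
    seg.objects.to_csv(sidecar_path, index=False)


# ----------------------------------------------------------- shaft vs spine

@dataclass
class SplitResult:
    shaft_radius_nm: float
    cut_distance_nm: list[float] = field(default_factory=list)
    merged_tiny: int = 0


def _principal_axis(coords_nm: np.ndarray, weights: np.ndarray):
    """Weighted principal direction; weighting by the squared inscribed-ball
    radius makes the tube core dominate over spines and heads."""
    w = weights / weights.sum()
    center = w @ coords_nm
    d = (coords_nm - center) * np.sqrt(w)[:, None]
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    return center, vt[0]


def split_dendrite(mask: np.ndarray, spacing,
                   tube_factor: float = 1.08,
                   station_nm: float = 50.0,
                   neck_search_fraction: float = 0.30,
                   area_tolerance: float = 0.05,
                   min_spine_voxels: int = 2,
                   min_spine_length_nm: float = 75.0):
    """Separate a dendrite mask into its shaft and candidate spine masks.

    Returns ``(shaft_mask, spine_masks, SplitResult)``.  The union of the
    outputs equals the input and the outputs are pairwise disjoint (voxel
    conservation).  Protrusions smaller than ``min_spine_voxels`` or
    shorter than ``min_spine_length_nm`` beyond the shaft tube (surface
    roughness, not spines) are merged back into the shaft and counted.
    """
    full = np.asarray(mask).astype(bool)
    if not full.any():
        raise ValueError("empty dendrite mask")
    if full.sum() < 27:
        raise ValueError("mask too small to carry a shaft")
    spacing_zyx = (spacing[2], spacing[1], spacing[0])
    sp = np.asarray(spacing_zyx, dtype=float)

    # work on the tight bounding box, restore at the end
    nzi = np.argwhere(full)
    blo = nzi.min(axis=0)
    bhi = nzi.max(axis=0) + 1
    mask = full[blo[0]:bhi[0], blo[1]:bhi[1], blo[2]:bhi[2]]

    edt = ndimage.distance_transform_edt(mask, sampling=spacing_zyx)
    vox = np.argwhere(mask)
    coords_nm = vox * sp
    radii = edt[tuple(vox.T)]
    center, axis = _principal_axis(coords_nm, radii ** 2)

    # pass 1: thickest mask voxel per station along the principal axis
    t = (coords_nm - center) @ axis
    stations = np.floor(t / station_nm).astype(int)
    order = np.lexsort((radii, stations))  # per station, thickest last
    last = np.concatenate([stations[order][1:] != stations[order][:-1], [True]])
    r_est = float(np.median(radii[order][last]))

    # pass 2: restrict to the shaft corridor around the axis line (the
    # selection targets straight dendritic segments; a thick mushroom head
    # could otherwise outscore the shaft in its station)
    radial = np.linalg.norm((coords_nm - center) - t[:, None] * axis, axis=1)
    corridor = radial <= max(2.0 * r_est, 250.0)
    oc = order[corridor[order]]
    lastc = np.concatenate([stations[oc][1:] != stations[oc][:-1], [True]])
    centerline_idx = oc[lastc]
    r_shaft = float(np.median(radii[centerline_idx]))

    cl_mask = np.zeros(mask.shape, dtype=bool)
    cl_mask[tuple(vox[centerline_idx].T)] = True
    dist_cl = ndimage.distance_transform_edt(~cl_mask, sampling=spacing_zyx)

    tube = mask & (dist_cl <= tube_factor * r_shaft)
    outside = mask & ~tube
    lab, n = ndimage.label(outside, structure=_CONN26)

    spine_masks: list[np.ndarray] = []
    res = SplitResult(shaft_radius_nm=r_shaft)
    claimed = np.zeros(mask.shape, dtype=bool)
    for i in range(1, n + 1):
        prot = lab == i
        size = int(prot.sum())
        d = dist_cl[prot] - tube_factor * r_shaft  # distance beyond the tube
        length = float(d.max())
        if size < min_spine_voxels or length < min_spine_length_nm:
            res.merged_tiny += 1
            continue
        step = max(2.0 * sp.min(), 15.0)
        search = max(length * neck_search_fraction, step)
        nbins = max(1, int(np.ceil(search / step)))
        areas = np.array([np.count_nonzero((d >= k * step) & (d < (k + 1) * step))
                          for k in range(nbins)], dtype=float)
        areas = areas[areas > 0]
        if len(areas) == 0:
            d_cut = 0.0
        else:
            amin = areas.min()
            k_cut = int(np.argmax(areas <= (1.0 + area_tolerance) * amin))
            d_cut = k_cut * step
        spine = prot & (dist_cl - tube_factor * r_shaft >= d_cut)
        # the cut may disconnect fragments: keep the component holding the tip
        lab2, n2 = ndimage.label(spine, structure=_CONN26)
        if n2 > 1:
            tip = np.unravel_index(np.argmax(np.where(prot, dist_cl, -1)), mask.shape)
            keep = lab2[tip]
            spine = lab2 == keep
        if int(spine.sum()) < min_spine_voxels:
            res.merged_tiny += 1
            continue
        spine_masks.append(spine)
        claimed |= spine
        res.cut_distance_nm.append(d_cut)

    def expand(sub):
        out = np.zeros(full.shape, dtype=bool)
        out[blo[0]:bhi[0], blo[1]:bhi[1], blo[2]:bhi[2]] = sub
        return out

    shaft = expand(mask & ~claimed)
    return shaft, [expand(s) for s in spine_masks], res
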