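"""Synthetic FIB/SEM-like phantoms with exact ground truth.

The generator emulates the structures a DAB-labeled granule-cell dendrite
presents in a backscattered-electron FIB/SEM stack: a dark tubular dendritic
shaft with spines of five morphological classes (thin, filopodial, stubby,
mushroom, branched), darkest thin synaptic-junction discs apposed to spine
heads or necks, bright vesicle-textured presynaptic boutons, and — for
multi-synaptic boutons — additional unlabeled postsynaptic elements arranged
along the bouton so that one varicosity contacts 1..10 spines.  Everything is
defined parametrically in nm and rasterized directly onto the anisotropic
voxel grid (default 3.7 x 3.7 x 25 nm), so anisotropy is honored at
rasterization, never by post-hoc scaling.

Spines are unions of implicit primitives: a cylindrical neck capped by a
spherical head (capsule-with-head model); stubby spines are a capsule fused
to the shaft with length comparable to their width; branched spines are one
shared neck bifurcating into 2-3 headed branches.  The spine/shaft boundary
is the plane tangent to the shaft at the attachment point: voxels of the
spine primitives below that plane are labeled shaft, which gives closed-form
ground-truth spine volumes for non-branched spines (sphere + coaxial
cylinder union measured from the plane); branched-spine volumes are obtained
by 3x supersampled rasterization and flagged inexact.

Intensity lookup (arbitrary units in [0, 1]; the real contrast of DAB versus
neuropil is not standardized, so this is a free, documented parameter):
background 0.60, DAB-labeled dendrite/spines 0.15, synaptic junctions 0.05
(darkest), boutons 0.75 with 0.68 vesicle speckles, unlabeled postsynaptic
elements 0.70.

All randomness flows through one ``numpy`` generator seeded from
``PhantomSpec.rng_seed``: identical spec + seed reproduces bit-identical
stacks.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .stack import ImageStack
from .segmentation import VoxelSegmentation

__all__ = [
    "PhantomSpec",
    "GroundTruthTable",
    "AppliedArtifacts",
    "build_phantom",
    "apply_acquisition_artifacts",
    "INTENSITY",
    "GEOMETRY_DEFAULTS",
    "GeometryError",
]

SPINE_TYPES = ("thin", "filopodial", "stubby", "mushroom", "branched")

INTENSITY = {
    "background": 0.60,
    "dendrite": 0.15,
    "synapse": 0.05,
    "bouton": 0.75,
    "bouton_vesicle": 0.68,
    "partner": 0.70,
}

#: Per-type geometry ranges, nm.  neck_len is the exposed neck measured from
#: the shaft tangent plane to where the head sphere begins; for stubby spines
#: neck_len is the total protrusion length and neck_r == head_r (fused head).
#: filopodial head radius is sampled as neck_r * head_ratio to keep the
#: defining head ~ neck property.
GEOMETRY_DEFAULTS = {
    "thin": {"neck_len": (380, 520), "neck_r": (38, 50), "head_r": (90, 110)},
    "filopodial": {"neck_len": (650, 850), "neck_r": (45, 55), "head_ratio": (1.0, 1.12)},
    "stubby": {"neck_len": (230, 300), "neck_r": (145, 175)},
    "mushroom": {"neck_len": (330, 470), "neck_r": (52, 65), "head_r": (190, 215)},
    "branched": {"neck_len": (240, 330), "neck_r": (42, 52), "head_r": (88, 108),
                 "branch_len": (280, 380), "branch_count": (2, 3),
                 "branch_angle_deg": (28, 38)},
}

#: SBi probabilities emulating mature (8-9 week) bouton connectivity: about
#: a quarter of boutons are single-synaptic, most multi-synaptic boutons add
#: 1-3 postsynaptic elements, and a small tail reaches 7-10.
SBI_DEFAULT = {1: 0.28, 2: 0.25, 3: 0.20, 4: 0.11, 5: 0.05,
               6: 0.04, 7: 0.03, 8: 0.02, 9: 0.01, 10: 0.01}

_BOUTON_R = 150.0
_PARTNER_R = 90.0
_CLEFT = 50.0          # bouton/partner surface to postsynaptic surface, nm
_PARTNER_PITCH_Z = 230.0
_PARTNER_AZIMUTHS = (90, 270, 30, 210, 150, 330, 60, 240, 120)  # degrees in x-y radial plane


class GeometryError(ValueError):
    """Requested phantom geometry does not fit the grid or is impossible."""


# --------------------------------------------------------------- primitives

@dataclass
class _Sphere:
    c: np.ndarray
    r: float

    def bbox(self):
        return self.c - self.r, self.c + self.r

    def contains_xyz(self, X, Y, Z):
        cx, cy, cz = self.c
        return ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) <= self.r ** 2

    def shifted(self, off):
        return _Sphere(self.c + off, self.r)


def _segment_t(p0, p1, X, Y, Z, clamp: bool):
    d = p1 - p0
    l2 = float(d @ d)
    if l2 == 0:
        return None, d
    t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / l2
    if clamp:
        t = np.clip(t, 0.0, 1.0)
    return t, d


def _radial2(p0, d, t, X, Y, Z):
    return ((X - p0[0] - t * d[0]) ** 2 + (Y - p0[1] - t * d[1]) ** 2
            + (Z - p0[2] - t * d[2]) ** 2)


@dataclass
class _Capsule:
    p0: np.ndarray
    p1: np.ndarray
    r: float

    def bbox(self):
        lo = np.minimum(self.p0, self.p1) - self.r
        hi = np.maximum(self.p0, self.p1) + self.r
        return lo, hi

    def contains_xyz(self, X, Y, Z):
        t, d = _segment_t(self.p0, self.p1, X, Y, Z, clamp=True)
        if t is None:
            return _Sphere(self.p0, self.r).contains_xyz(X, Y, Z)
        return _radial2(self.p0, d, t, X, Y, Z) <= self.r ** 2

    def shifted(self, off):
        return _Capsule(self.p0 + off, self.p1 + off, self.r)


@dataclass
class _Cylinder:
    """Flat-ended cylinder from p0 to p1."""

    p0: np.ndarray
    p1: np.ndarray
    r: float

    def bbox(self):
        lo = np.minimum(self.p0, self.p1) - self.r
        hi = np.maximum(self.p0, self.p1) + self.r
        return lo, hi

    def contains_xyz(self, X, Y, Z):
        t, d = _segment_t(self.p0, self.p1, X, Y, Z, clamp=False)
        return ((_radial2(self.p0, d, t, X, Y, Z) <= self.r ** 2)
                & (t >= 0.0) & (t <= 1.0))

    def shifted(self, off):
        return _Cylinder(self.p0 + off, self.p1 + off, self.r)


@dataclass
class _Clipped:
    """A primitive intersected with the half-space dot(p - point, n) >= 0."""

    prim: object
    point: np.ndarray
    n: np.ndarray

    def bbox(self):
        return self.prim.bbox()

    def contains_xyz(self, X, Y, Z):
        plane = ((X - self.point[0]) * self.n[0] + (Y - self.point[1]) * self.n[1]
                 + (Z - self.point[2]) * self.n[2]) >= 0.0
        return self.prim.contains_xyz(X, Y, Z) & plane

    def shifted(self, off):
        return _Clipped(self.prim.shifted(off), self.point + off, self.n)


def _paint(grid: np.ndarray, prims, spacing_xyz, value) -> None:
    """Set voxels whose centers fall inside any primitive (bbox-local)."""
    sx, sy, sz = spacing_xyz
    nz, ny, nx = grid.shape
    for prim in prims:
        lo, hi = prim.bbox()
        ix0, ix1 = max(0, int(math.floor(lo[0] / sx))), min(nx - 1, int(math.ceil(hi[0] / sx)))
        iy0, iy1 = max(0, int(math.floor(lo[1] / sy))), min(ny - 1, int(math.ceil(hi[1] / sy)))
        iz0, iz1 = max(0, int(math.floor(lo[2] / sz))), min(nz - 1, int(math.ceil(hi[2] / sz)))
        if ix1 < ix0 or iy1 < iy0 or iz1 < iz0:
            continue
        X = (np.arange(ix0, ix1 + 1) * sx)[None, None, :]
        Y = (np.arange(iy0, iy1 + 1) * sy)[None, :, None]
        Z = (np.arange(iz0, iz1 + 1) * sz)[:, None, None]
        inside = prim.contains_xyz(X, Y, Z)
        sub = grid[iz0:iz1 + 1, iy0:iy1 + 1, ix0:ix1 + 1]
        sub[inside] = value


def _union_volume_supersampled(prims, factor: int, spacing_xyz) -> float:
    """Volume of a primitive union by rasterization at ``factor``x finer grid."""
    los, his = zip(*(p.bbox() for p in prims))
    lo = np.min(los, axis=0)
    hi = np.max(his, axis=0)
    sp = np.asarray(spacing_xyz) / factor
    X = np.arange(lo[0], hi[0] + sp[0], sp[0])[None, None, :]
    Y = np.arange(lo[1], hi[1] + sp[1], sp[1])[None, :, None]
    total = 0
    # chunk over z to bound memory
    zs = np.arange(lo[2], hi[2] + sp[2], sp[2])
    for z0 in range(0, len(zs), 16):
        Z = zs[z0:z0 + 16][:, None, None]
        inside = np.zeros((len(Z), Y.shape[1], X.shape[2]), dtype=bool)
        for p in prims:
            inside |= p.contains_xyz(X, Y, Z)
        total += int(inside.sum())
    return total * float(np.prod(sp))


# --------------------------------------------------------------------- spec

@dataclass
class PhantomSpec:
    """Parameters of one synthetic acquisition.

    ``grid_shape`` is (x, y, z) voxels; None auto-sizes the grid to fit the
    requested geometry.  ``spacing`` is nm per axis (x, y, z).  See module
    docstring for the structural model behind the other fields.
    """

    grid_shape: tuple[int, int, int] | None = None
    spacing: tuple[float, float, float] = (3.7, 3.7, 25.0)
    n_spines_per_type: dict = field(
        default_factory=lambda: {"thin": 2, "filopodial": 1, "stubby": 1,
                                 "mushroom": 1, "branched": 1})
    geometry_ranges: dict = field(default_factory=lambda: copy.deepcopy(GEOMETRY_DEFAULTS))
    sbi_distribution: dict = field(default_factory=lambda: dict(SBI_DEFAULT))
    nonsynaptic_fraction: float = 0.02
    neck_synapse_fraction: float = 0.03
    multi_innervated_fraction: float = 0.0
    shaft_radius_nm: float = 200.0
    background_texture_sd: float = 0.05
    noise_sd: float = 0.02
    slice_jitter_px: int = 3
    intensity_drift: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("spacing must be strictly positive")
        for t, n in self.n_spines_per_type.items():
            if t not in SPINE_TYPES:
                raise GeometryError(f"unknown spine type {t!r}")
            if n < 0:
                raise GeometryError("spine counts must be >= 0")
        total = sum(self.sbi_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise GeometryError(f"sbi_distribution must sum to 1, sums to {total}")
        if any(k < 1 or k > 10 for k in self.sbi_distribution):
            raise GeometryError("SBi support is 1..10")
        for p in (self.nonsynaptic_fraction, self.neck_synapse_fraction,
                  self.multi_innervated_fraction):
            if not 0.0 <= p <= 1.0:
                raise GeometryError("fractions must be probabilities in [0, 1]")
        for t, rng in self.geometry_ranges.items():
            for key, val in rng.items():
                if isinstance(val, tuple) and len(val) == 2 and val[0] > val[1]:
                    raise GeometryError(f"geometry range {t}.{key} has min > max")
        bc = self.geometry_ranges.get("branched", {}).get("branch_count", (2, 3))
        if bc[0] < 2:
            raise GeometryError("a branched spine needs at least 2 heads")
        if self.noise_sd < 0 or self.intensity_drift < 0 or self.slice_jitter_px < 0:
            raise GeometryError("noise, drift and jitter must be >= 0")

    def total_spines(self) -> int:
        return sum(self.n_spines_per_type.values())


@dataclass
class GroundTruthTable:
    """Exact per-object truth for recovery tests.

    ``objects`` has one row per rendered object (dendrite shaft, spines,
    synaptic junctions, boutons, unlabeled postsynaptic elements);
    ``heads`` has one row per spine head (branched spines contribute several)
    with its world-nm centroid, for split/feature oracles.
    """

    objects: pd.DataFrame
    heads: pd.DataFrame
    shaft_center_zyx: tuple[int, int, int] | None = None

    def of_category(self, category: str) -> pd.DataFrame:
        return self.objects[self.objects["category"] == category]

    def sbi_of(self, bouton_id: int) -> int:
        row = self.objects[self.objects["id"] == bouton_id]
        return int(row["sbi"].iloc[0])


# ------------------------------------------------------------ spine builder

def _uniform(rng, lohi):
    return float(rng.uniform(lohi[0], lohi[1]))


class _Assembly:
    """All primitives of one spine plus its synaptic apparatus, local frame.

    Local frame: attachment point at the origin, spine axis +y, dendrite
    surface the plane y = 0.
    """

    def __init__(self):
        self.spine_prims = []          # unclipped (intensity); extend below plane
        self.spine_label_prims = []    # clipped at the tangent plane
        self.head_centers = []         # (3,) local nm, one per head
        self.head_radius = []
        self.synapses = []             # dicts: disc prims, bouton prims, location, ...
        self.true_volume = np.nan
        self.volume_exact = False
        self.features = {}

    def all_prims(self):
        out = list(self.spine_prims)
        for s in self.synapses:
            out.append(s["disc"])
            out.extend(s["bouton_prims"])
            out.extend(p for p, _ in s["partners"])
            out.extend(d for d in s["partner_discs"])
        return out

    def bbox(self):
        los, his = zip(*(p.bbox() for p in self.all_prims()))
        return np.min(los, axis=0), np.max(his, axis=0)


_EY = np.array([0.0, 1.0, 0.0])


def _head_cyl_union_volume(rh, rn, L):
    """Union of a head sphere (radius rh) and a coaxial neck cylinder
    (radius rn) running from the base plane to the sphere center at height L.
    Closed form: V_sphere + V_cyl - half the coaxial sphere/cylinder
    intersection."""
    inter_full = (4.0 * math.pi / 3.0) * (rh ** 3 - (rh * rh - rn * rn) ** 1.5)
    return (4.0 * math.pi / 3.0) * rh ** 3 + math.pi * rn * rn * L - 0.5 * inter_full


def _overlap_nm(direction, spacing) -> float:
    """Disc penetration depth guaranteeing >= 1 voxel of label overlap along
    ``direction`` (the 25 nm Z pitch dominates when the axis tilts into z)."""
    d = np.abs(np.asarray(direction, dtype=float))
    d = d / np.linalg.norm(d)
    return max(12.0, 1.6 * float(d @ np.asarray(spacing, dtype=float)))


def _make_synapse(center, normal, post_r, sbi, rng, spacing, disc_r=None):
    """Synaptic apparatus at a postsynaptic surface point.

    ``center`` is the center of the postsynaptic structure (head sphere or
    neck axis point), ``normal`` the outward direction, ``post_r`` the local
    postsynaptic radius.  Builds the junction disc, the presynaptic bouton
    (a capsule elongated along z when it carries partner elements) and, for
    SBi > 1, the unlabeled partner elements with their own junction discs.
    Discs penetrate both partners just enough to guarantee label adjacency
    at the voxel size in use.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ov = _overlap_nm(normal, (spacing[0], spacing[1], spacing[2]))
    if disc_r is None:
        disc_r = min(0.6 * post_r, 110.0)
    disc = _Cylinder(center + (post_r - ov) * normal,
                     center + (post_r + _CLEFT + ov) * normal, disc_r)
    n_partners = sbi - 1
    bc = center + (post_r + _CLEFT + _BOUTON_R) * normal
    slots = []
    for j in range(n_partners):
        mag = (j // 2 + 1) * _PARTNER_PITCH_Z
        slots.append(mag if j % 2 == 0 else -mag)
    hl = max((abs(s) for s in slots), default=0.0)
    axis_z = np.array([0.0, 0.0, 1.0])
    bouton = _Capsule(bc - hl * axis_z, bc + hl * axis_z, _BOUTON_R)
    partners, partner_discs = [], []
    for j, s in enumerate(slots):
        az = math.radians(_PARTNER_AZIMUTHS[j % len(_PARTNER_AZIMUTHS)])
        w = np.array([math.cos(az), math.sin(az), 0.0])
        ovw = _overlap_nm(w, (spacing[0], spacing[1], spacing[2]))
        anchor = bc + s * axis_z
        pc = anchor + (_BOUTON_R + _CLEFT + _PARTNER_R) * w
        partners.append((_Sphere(pc, _PARTNER_R), pc))
        partner_discs.append(_Cylinder(anchor + (_BOUTON_R - ovw) * w,
                                       anchor + (_BOUTON_R + _CLEFT + ovw) * w,
                                       60.0))
    # vesicle speckle centers inside the bouton (intensity texture only)
    vol = math.pi * _BOUTON_R ** 2 * 2 * hl + (4.0 / 3.0) * math.pi * _BOUTON_R ** 3
    n_ves = max(4, int(vol / 2.0e6))
    lo, hi = bouton.bbox()
    cand = rng.uniform(lo, hi, size=(n_ves * 4, 3))
    inner = _Capsule(bouton.p0, bouton.p1, _BOUTON_R - 35.0)
    keep = inner.contains_xyz(cand[:, 0], cand[:, 1], cand[:, 2])
    cand = cand[keep][:n_ves]
    return {
        "disc": disc,
        "disc_volume": math.pi * disc_r ** 2 * (_CLEFT + 2 * ov),
        "bouton_prims": [bouton],
        "bouton_volume": vol,
        "bouton_center": bc,
        "vesicles": [_Sphere(c, 22.0) for c in cand],
        "partners": partners,
        "partner_discs": partner_discs,
        "sbi": sbi,
        "location": "head",
    }


def _build_assembly(spine_type, rng, spec: PhantomSpec,
                    synapse_plan) -> _Assembly:
    """Sample one spine of ``spine_type`` and its synaptic apparatus."""
    g = spec.geometry_ranges[spine_type]
    asm = _Assembly()
    base = np.zeros(3)
    neck_len = _uniform(rng, g["neck_len"])
    neck_r = _uniform(rng, g["neck_r"])

    if spine_type == "stubby":
        # capsule fused to the shaft: length ~ width, no distinct neck
        r = neck_r
        L = max(neck_len, r + 25.0)
        cap = _Capsule(base - 30.0 * _EY, base + (L - r) * _EY, r)
        asm.spine_prims = [cap]
        asm.spine_label_prims = [_Clipped(cap, base, _EY)]
        asm.head_centers = [base + (L - r) * _EY]
        asm.head_radius = [r]
        asm.true_volume = math.pi * r * r * (L - r) + (2.0 / 3.0) * math.pi * r ** 3
        asm.volume_exact = True
        asm.features = {"neck_len": L, "neck_r": r, "head_r": r}
    elif spine_type == "branched":
        n_heads = int(rng.integers(g["branch_count"][0], g["branch_count"][1] + 1))
        branch_r = 0.9 * neck_r
        junction = base + neck_len * _EY
        prims = [_Cylinder(base - 30.0 * _EY, junction + 10.0 * _EY, neck_r)]
        for j in range(n_heads):
            ang = math.radians(_uniform(rng, g["branch_angle_deg"]))
            if j == 0:
                v = np.array([math.sin(ang), math.cos(ang), 0.0])
            elif j == 1:
                v = np.array([-math.sin(ang), math.cos(ang), 0.0])
            else:
                v = np.array([0.0, math.cos(ang), math.sin(ang)])
            blen = _uniform(rng, g["branch_len"])
            rh = _uniform(rng, g["head_r"])
            hc = junction + (blen + rh) * v
            prims.append(_Cylinder(junction, hc, branch_r))
            prims.append(_Sphere(hc, rh))
            asm.head_centers.append(hc)
            asm.head_radius.append(rh)
        asm.spine_prims = prims
        asm.spine_label_prims = [_Clipped(p, base, _EY) for p in prims]
        asm.true_volume = _union_volume_supersampled(
            [_Clipped(p, base, _EY) for p in prims], 2, np.asarray(spec.spacing))
        asm.volume_exact = False
        asm.features = {"neck_len": neck_len, "neck_r": neck_r,
                        "head_r": float(np.mean(asm.head_radius)), "n_heads": n_heads}
    else:
        if spine_type == "filopodial":
            rh = neck_r * _uniform(rng, g["head_ratio"])
        else:
            rh = _uniform(rng, g["head_r"])
        L = neck_len + rh  # plane -> head center
        hc = base + L * _EY
        neck = _Cylinder(base - 30.0 * _EY, hc, neck_r)
        head = _Sphere(hc, rh)
        asm.spine_prims = [neck, head]
        asm.spine_label_prims = [_Clipped(neck, base, _EY), _Clipped(head, base, _EY)]
        asm.head_centers = [hc]
        asm.head_radius = [rh]
        asm.true_volume = _head_cyl_union_volume(rh, neck_r, L)
        asm.volume_exact = True
        asm.features = {"neck_len": neck_len, "neck_r": neck_r, "head_r": rh}

    # ---- synaptic apparatus
    if synapse_plan["has_synapse"]:
        if spine_type == "branched":
            # every tip carries its own synapse from a distinct bouton (the
            # poly-innervated configuration); branch boutons are kept
            # single-synaptic so the branch clouds cannot collide
            junction = base + asm.features["neck_len"] * _EY
            for hc, rh in zip(asm.head_centers, asm.head_radius):
                v = hc - junction
                v = v / np.linalg.norm(v)
                syn = _make_synapse(hc, v, rh, sbi=1, rng=rng, spacing=spec.spacing)
                asm.synapses.append(syn)
        elif synapse_plan["location"] == "neck":
            # neck-synapse boutons are kept single-synaptic: a partner cloud
            # at neck height would collide with the spine itself
            point = base + 0.5 * asm.features["neck_len"] * _EY
            normal = np.array([0.0, 0.0, 1.0])
            syn = _make_synapse(point, normal, asm.features["neck_r"],
                                sbi=1, rng=rng,
                                spacing=spec.spacing, disc_r=60.0)
            syn["location"] = "neck"
            asm.synapses.append(syn)
        else:
            hc, rh = asm.head_centers[0], asm.head_radius[0]
            syn = _make_synapse(hc, _EY, rh, sbi=synapse_plan["sbi"], rng=rng, spacing=spec.spacing)
            asm.synapses.append(syn)
            if synapse_plan["second_head_synapse"]:
                # second bouton on the same head, tilted into the z plane;
                # both boutons stay single-synaptic to avoid collisions
                u2 = np.array([0.0, math.cos(math.radians(70)), math.sin(math.radians(70))])
                syn2 = _make_synapse(hc, u2, rh, sbi=1, rng=rng, spacing=spec.spacing)
                asm.synapses.append(syn2)
    return asm


# ------------------------------------------------------------------ builder

def build_phantom(spec: PhantomSpec):
    """Render a phantom stack, its label grid, and the ground-truth tables.

    Returns ``(ImageStack, VoxelSegmentation, GroundTruthTable)``.  With all
    spine counts zero the output is pure background with an empty label grid
    and empty tables.  Raises :class:`GeometryError` when a requested
    geometry cannot fit the (given) grid.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    sx, sy, sz = spec.spacing

    obj_rows: list[dict] = []
    head_rows: list[dict] = []

    if spec.total_spines() == 0:
        if spec.grid_shape is None:
            nxv, nyv, nzv = 64, 64, 8
        else:
            nxv, nyv, nzv = spec.grid_shape
        grid = np.full((nzv, nyv, nxv), INTENSITY["background"], dtype=np.float32)
        labels = np.zeros((nzv, nyv, nxv), dtype=np.int32)
        stack = ImageStack(grid=grid, spacing=spec.spacing, provenance=["phantom:empty"])
        seg = VoxelSegmentation(labels=labels, objects=pd.DataFrame(
            columns=["id", "category", "labeled"]), spacing=spec.spacing)
        gt = GroundTruthTable(objects=pd.DataFrame(columns=[
            "id", "category", "spine_type", "labeled", "parent_id", "bouton_id",
            "location", "sbi", "true_volume_nm3", "true_area_nm2", "volume_exact",
            "center_x_nm", "center_y_nm", "center_z_nm"]),
            heads=pd.DataFrame(columns=["spine_id", "head_index", "x_nm", "y_nm",
                                        "z_nm", "radius_nm", "head_type"]))
        return stack, seg, gt

    # ---- sample spines in a deterministic shuffled order
    type_list = [t for t in SPINE_TYPES for _ in range(spec.n_spines_per_type.get(t, 0))]
    order = rng.permutation(len(type_list))
    type_list = [type_list[i] for i in order]

    sbi_vals = np.array(sorted(spec.sbi_distribution))
    sbi_probs = np.array([spec.sbi_distribution[k] for k in sbi_vals])

    assemblies = []
    for t in type_list:
        plan = {
            "has_synapse": bool(rng.random() >= spec.nonsynaptic_fraction),
            "location": "neck" if rng.random() < spec.neck_synapse_fraction else "head",
            "sbi": int(rng.choice(sbi_vals, p=sbi_probs)),
            "second_head_synapse": bool(rng.random() < spec.multi_innervated_fraction),
        }
        assemblies.append((t, _build_assembly(t, rng, spec, plan)))

    # ---- pack along x with 60 nm clearance between assembly bboxes
    margin = 200.0
    clearance = 60.0
    xcursor = margin
    offsets = []
    for _, asm in assemblies:
        lo, hi = asm.bbox()
        xcursor += -lo[0]
        offsets.append(xcursor)
        xcursor += hi[0] + clearance
    total_x = xcursor - clearance + margin

    rs = spec.shaft_radius_nm
    y_surf = 150.0 + 2.0 * rs   # shaft axis at 150 + rs; tangent plane above
    tops = [asm.bbox()[1][1] for _, asm in assemblies]
    zlos = [asm.bbox()[0][2] for _, asm in assemblies]
    zhis = [asm.bbox()[1][2] for _, asm in assemblies]
    total_y = y_surf + max(tops) + 150.0
    z_half = max(rs, max(-min(zlos), max(zhis))) + 120.0

    need = (int(math.ceil(total_x / sx)) + 1,
            int(math.ceil(total_y / sy)) + 1,
            int(math.ceil(2 * z_half / sz)) + 1)
    if spec.grid_shape is None:
        nxv, nyv, nzv = need
    else:
        nxv, nyv, nzv = spec.grid_shape
        if need[0] > nxv or need[1] > nyv or need[2] > nzv:
            raise GeometryError(
                f"geometry needs grid {need} (x,y,z voxels), got {spec.grid_shape}")
    z_c = (nzv - 1) * sz / 2.0

    shaft_axis_y = y_surf - rs
    world = []
    for (t, asm), x0 in zip(assemblies, offsets):
        world.append((t, asm, np.array([x0, y_surf, z_c])))

    grid = np.full((nzv, nyv, nxv), INTENSITY["background"], dtype=np.float32)
    if spec.background_texture_sd > 0:
        # smooth neuropil-like texture: real block-face images are textured
        # everywhere, which is what makes slice-to-slice registration well
        # posed; the texture is tissue, so acquisition jitter translates it
        from scipy import ndimage as _ndi
        tex = rng.standard_normal(size=grid.shape).astype(np.float32)
        tex = _ndi.gaussian_filter(tex, sigma=(3.0, 1.2, 1.2), mode="reflect")
        tex *= spec.background_texture_sd / max(float(tex.std()), 1e-12)
        grid += tex
    labels = np.zeros((nzv, nyv, nxv), dtype=np.int32)
    spacing = (sx, sy, sz)

    shaft = _Cylinder(np.array([-sx, shaft_axis_y, z_c]),
                      np.array([nxv * sx + sx, shaft_axis_y, z_c]), rs)

    # ---- intensity: boutons -> vesicles -> partners -> dendrite -> synapses
    for t, asm, off in world:
        for s in asm.synapses:
            _paint(grid, [p.shifted(off) for p in s["bouton_prims"]], spacing, INTENSITY["bouton"])
            _paint(grid, [v.shifted(off) for v in s["vesicles"]], spacing, INTENSITY["bouton_vesicle"])
            _paint(grid, [p.shifted(off) for p, _ in s["partners"]], spacing, INTENSITY["partner"])
    _paint(grid, [shaft], spacing, INTENSITY["dendrite"])
    for t, asm, off in world:
        _paint(grid, [p.shifted(off) for p in asm.spine_prims], spacing, INTENSITY["dendrite"])
    for t, asm, off in world:
        for s in asm.synapses:
            _paint(grid, [s["disc"].shifted(off)], spacing, INTENSITY["synapse"])
            _paint(grid, [d.shifted(off) for d in s["partner_discs"]], spacing, INTENSITY["synapse"])

    # ---- labels: spine-below-plane & shaft as id 1, spines, partners,
    #      boutons, then synapse discs last (guaranteeing adjacency overlap)
    SHAFT_ID = 1
    for t, asm, off in world:
        _paint(labels, [p.shifted(off) for p in asm.spine_prims], spacing, SHAFT_ID)
    _paint(labels, [shaft], spacing, SHAFT_ID)

    next_id = 10
    obj_rows.append({"id": SHAFT_ID, "category": "dendrite_shaft", "spine_type": None,
                     "labeled": True, "parent_id": None, "bouton_id": None,
                     "location": None, "sbi": None, "true_volume_nm3": np.nan,
                     "true_area_nm2": np.nan, "volume_exact": False,
                     "center_x_nm": total_x / 2, "center_y_nm": shaft_axis_y,
                     "center_z_nm": z_c})

    synapse_paint_queue = []  # (prim, id)
    for t, asm, off in world:
        spine_id = next_id
        next_id += 1
        _paint(labels, [p.shifted(off) for p in asm.spine_label_prims], spacing, spine_id)
        centroid = np.mean([hc + off for hc in asm.head_centers], axis=0)
        obj_rows.append({"id": spine_id, "category": "spine", "spine_type": t,
                         "labeled": True, "parent_id": SHAFT_ID, "bouton_id": None,
                         "location": None, "sbi": None,
                         "true_volume_nm3": asm.true_volume,
                         "true_area_nm2": np.nan, "volume_exact": asm.volume_exact,
                         "center_x_nm": centroid[0], "center_y_nm": centroid[1],
                         "center_z_nm": centroid[2],
                         "base_x_nm": off[0], "base_y_nm": off[1], "base_z_nm": off[2],
                         "neck_r_nm": asm.features.get("neck_r"),
                         "neck_len_nm": asm.features.get("neck_len"),
                         "n_heads": len(asm.head_centers)})
        for j, (hc, rh) in enumerate(zip(asm.head_centers, asm.head_radius)):
            p = hc + off
            head_rows.append({"spine_id": spine_id, "head_index": j,
                              "x_nm": p[0], "y_nm": p[1], "z_nm": p[2],
                              "radius_nm": rh,
                              "head_type": "thin" if t == "branched" else t})
        for s in asm.synapses:
            bouton_id = next_id
            next_id += 1
            _paint(labels, [p.shifted(off) for p in s["bouton_prims"]], spacing, bouton_id)
            bc = s["bouton_center"] + off
            obj_rows.append({"id": bouton_id, "category": "bouton", "spine_type": None,
                             "labeled": False, "parent_id": None, "bouton_id": None,
                             "location": None, "sbi": s["sbi"],
                             "true_volume_nm3": s["bouton_volume"],
                             "true_area_nm2": np.nan, "volume_exact": False,
                             "center_x_nm": bc[0], "center_y_nm": bc[1], "center_z_nm": bc[2]})
            partner_ids = []
            for p_sphere, pc in s["partners"]:
                pid = next_id
                next_id += 1
                _paint(labels, [p_sphere.shifted(off)], spacing, pid)
                pcw = pc + off
                obj_rows.append({"id": pid, "category": "spine", "spine_type": None,
                                 "labeled": False, "parent_id": None, "bouton_id": None,
                                 "location": None, "sbi": None,
                                 "true_volume_nm3": (4.0 / 3.0) * math.pi * _PARTNER_R ** 3,
                                 "true_area_nm2": 4.0 * math.pi * _PARTNER_R ** 2,
                                 "volume_exact": False,
                                 "center_x_nm": pcw[0], "center_y_nm": pcw[1],
                                 "center_z_nm": pcw[2]})
                partner_ids.append(pid)
            # labeled-spine junction plus one junction per partner
            syn_targets = [(s["disc"], spine_id, s["location"])] + [
                (d, pid, "head") for d, pid in zip(s["partner_discs"], partner_ids)]
            for disc, post_id, loc in syn_targets:
                sid = next_id
                next_id += 1
                synapse_paint_queue.append((disc.shifted(off), sid))
                c = (np.asarray(disc.p0) + np.asarray(disc.p1)) / 2 + off
                obj_rows.append({"id": sid, "category": "synaptic_junction",
                                 "spine_type": None, "labeled": False,
                                 "parent_id": post_id, "bouton_id": bouton_id,
                                 "location": loc, "sbi": None,
                                 "true_volume_nm3": math.pi * disc.r ** 2
                                 * float(np.linalg.norm(np.asarray(disc.p1) - np.asarray(disc.p0))),
                                 "true_area_nm2": np.nan, "volume_exact": True,
                                 "center_x_nm": c[0], "center_y_nm": c[1],
                                 "center_z_nm": c[2]})
    for prim, sid in synapse_paint_queue:
        _paint(labels, [prim], spacing, sid)

    objects = pd.DataFrame(obj_rows)
    heads = pd.DataFrame(head_rows)
    _check_adjacency(labels, objects)

    seg_table = objects[["id", "category", "labeled"]].copy()
    stack = ImageStack(grid=grid, spacing=spec.spacing,
                       provenance=[f"phantom:seed={spec.rng_seed}"])
    seg = VoxelSegmentation(labels=labels, objects=seg_table, spacing=spec.spacing)
    shaft_zyx = (int(round(z_c / sz)), int(round(shaft_axis_y / sy)),
                 int(round((total_x / 2) / sx)))
    gt = GroundTruthTable(objects=objects, heads=heads, shaft_center_zyx=shaft_zyx)
    return stack, seg, gt


def _check_adjacency(labels: np.ndarray, objects: pd.DataFrame) -> None:
    """Verify each rendered junction touches its bouton and its postsynaptic
    element in the label grid (26-adjacency); a violation means the requested
    geometry collapsed at this voxel size."""
    from scipy import ndimage
    syn = objects[objects["category"] == "synaptic_junction"]
    slices = ndimage.find_objects(labels)
    for _, row in syn.iterrows():
        sid = int(row["id"])
        sl = slices[sid - 1]
        if sl is None:
            raise GeometryError(f"synapse {sid} rendered to zero voxels")
        pad = tuple(slice(max(0, s.start - 1), min(dim, s.stop + 1))
                    for s, dim in zip(sl, labels.shape))
        sub = labels[pad]
        dil = ndimage.binary_dilation(sub == sid, structure=np.ones((3, 3, 3), bool))
        neigh = set(np.unique(sub[dil])) - {0, sid}
        for col in ("bouton_id", "parent_id"):
            want = int(row[col])
            if want not in neigh:
                raise GeometryError(
                    f"synapse {sid} not adjacent to object {want} in the label grid")


# ---------------------------------------------------------------- artifacts

@dataclass
class AppliedArtifacts:
    """Record of the degradations applied, for oracle tests: per-slice
    integer jitter (dy, dx), multiplicative drift gain, and the noise SD."""

    jitters: np.ndarray
    drifts: np.ndarray
    noise_sd: float


def apply_acquisition_artifacts(stack: ImageStack, spec: PhantomSpec):
    """Degrade a clean stack with per-slice jitter, intensity drift and noise.

    Slice 0 is the anchor: its jitter is (0, 0) and its drift gain 1, so the
    recorded jitters are directly comparable with cumulative alignment
    shifts.  Translation is integer, filled with the background level.
    Returns ``(ImageStack, AppliedArtifacts)``.
    """
    grid = np.asarray(stack.grid, dtype=np.float32)
    nz, ny, nx = grid.shape
    if nz == 0:
        raise ValueError("empty stack")
    j = int(spec.slice_jitter_px)
    if j >= min(ny, nx):
        raise GeometryError("slice jitter exceeds the slice extent")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed) % (2**31), 77]))
    jitters = np.zeros((nz, 2), dtype=int)
    if j > 0:
        jitters[1:] = rng.integers(-j, j + 1, size=(nz - 1, 2))
    drifts = np.ones(nz, dtype=np.float64)
    if spec.intensity_drift > 0:
        drifts[1:] = rng.uniform(1.0 - spec.intensity_drift,
                                 1.0 + spec.intensity_drift, size=nz - 1)
    out = np.empty_like(grid)
    bg = INTENSITY["background"]
    for z in range(nz):
        dy, dx = jitters[z]
        sl = np.full((ny, nx), bg, dtype=np.float32)
        ys = slice(max(0, dy), min(ny, ny + dy))
        xs = slice(max(0, dx), min(nx, nx + dx))
        ys_src = slice(max(0, -dy), min(ny, ny - dy))
        xs_src = slice(max(0, -dx), min(nx, nx - dx))
        sl[ys, xs] = grid[z][ys_src, xs_src]
        out[z] = sl * drifts[z]
    if spec.noise_sd > 0:
        out += rng.normal(0.0, spec.noise_sd, size=out.shape).astype(np.float32)
    degraded = stack.with_grid(out, note=f"artifacts:jitter<={j},drift={spec.intensity_drift},"
                                         f"noise={spec.noise_sd}")
    return degraded, AppliedArtifacts(jitters=jitters, drifts=drifts,
                                      noise_sd=float(spec.noise_sd))


# ------------------------------------------------------------------- export

def save_phantom(outdir, stack: ImageStack, seg: VoxelSegmentation,
                 gt: GroundTruthTable, spec: PhantomSpec,
                 artifacts: AppliedArtifacts | None = None) -> None:
    """Write a phantom bundle: TIFF stacks, ground-truth CSVs, spec YAML."""
    import pathlib
    import yaml
    from .stack import write_stack
    from .segmentation import write_labels

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(stack, out / "stack.tif")
    write_labels(seg, out / "labels.tif", out / "labels.csv")
    gt.objects.to_csv(out / "ground_truth_objects.csv", index=False)
    gt.heads.to_csv(out / "ground_truth_heads.csv", index=False)
    d = asdict(spec)
    d["grid_shape"] = list(spec.grid_shape) if spec.grid_shape else None
    d["spacing"] = list(spec.spacing)
    with open(out / "phantom_spec.yaml", "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
    if artifacts is not None:
        pd.DataFrame({"slice": np.arange(len(artifacts.drifts)),
                      "jitter_dy": artifacts.jitters[:, 0],
                      "jitter_dx": artifacts.jitters[:, 1],
                      "drift_gain": artifacts.drifts}).to_csv(
            out / "applied_artifacts.csv", index=False)
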