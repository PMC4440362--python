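"""Spine shape features and assignment to the five morphological classes.

The classes — thin, filopodial, stubby, mushroom, branched — are defined in
the literature by qualitative criteria (small round head on a small neck;
long with head ~ neck; length ~ neck width; large head; more than one head on
a shared neck).  This module operationalizes them with quantitative features
measured on the 3D skeleton and Euclidean distance transform of the
individualized spine mask, in physical units:

* total length: geodesic skeleton path from the neck base to the farthest
  tip, extended by the local inscribed-ball radii at both ends (so a bare
  sphere scores its diameter);
* neck diameter: twice the minimal inscribed-ball radius along the basal
  60% of the path;
* head diameter: twice the maximal inscribed-ball radius over the distal
  third of the skeleton;
* head count: skeleton endpoints whose branch is locally thicker than
  1.2x the neck scale.

The numeric thresholds of the decision cascade are package defaults, not
literature constants — the source classifications are qualitative — and are
exposed in :class:`ClassificationThresholds` so they can be overridden from
configuration; outputs should always report the thresholds used.  The
cascade order (branched, stubby, mushroom, filopodial, thin) resolves
ambiguous overlaps and makes the classification total: every feature vector
receives exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np

from ._centerline import spine_anatomy

__all__ = [
    "SpineFeatures",
    "SpineRecord",
    "ClassificationThresholds",
    "MaskTooSmallError",
    "extract_features",
    "classify_spine",
    "type_composition",
    "largest_remainder_percent",
]

CANONICAL_TYPES = ("thin", "filopodial", "stubby", "mushroom", "branched")


class MaskTooSmallError(ValueError):
    """Mask cannot be skeletonized; the spine is not fully reconstructable."""


@dataclass
class SpineFeatures:
    length_nm: float
    neck_diameter_nm: float
    head_diameter_nm: float
    head_count: int

    def __post_init__(self):
        if min(self.length_nm, self.neck_diameter_nm, self.head_diameter_nm) <= 0:
            raise ValueError("all feature lengths must be positive")
        if self.head_count < 1:
            raise ValueError("head count must be >= 1")

    @property
    def head_neck_ratio(self) -> float:
        return self.head_diameter_nm / self.neck_diameter_nm

    @property
    def length_neck_ratio(self) -> float:
        return self.length_nm / self.neck_diameter_nm


@dataclass
class SpineRecord:
    spine_id: int
    parent_dendrite_id: int | None
    spine_type: str
    features: SpineFeatures | None
    fully_reconstructed: bool = True
    synapse_ids: list[int] | None = None
    synapse_locations: list[str] | None = None


def extract_features(spine_mask: np.ndarray, spacing,
                     base_point=None) -> SpineFeatures:
    """Measure shape features of one individualized spine mask.

    ``spacing`` is (sx, sy, sz) nm; ``base_point`` an optional (z, y, x)
    voxel index of the neck base (e.g. the attachment recorded when the
    spine was cut from the shaft).  Without it the base is taken as the
    skeleton endpoint with the thinnest branch.  Deterministic.  Raises
    :class:`MaskTooSmallError` for masks below 8 voxels or without a
    skeleton.
    """
    mask = np.asarray(spine_mask).astype(bool)
    if mask.sum() < 8:
        raise MaskTooSmallError(f"mask has {int(mask.sum())} voxels (< 8)")
    spacing_zyx = (spacing[2], spacing[1], spacing[0])
    a = spine_anatomy(mask, spacing_zyx, base_point=base_point)
    return SpineFeatures(length_nm=a["length_nm"],
                         neck_diameter_nm=2 * a["neck_radius_nm"],
                         head_diameter_nm=2 * a["head_radius_nm"],
                         head_count=len(a["heads"]))


@dataclass
class ClassificationThresholds:
    """Decision-cascade cut-offs (package defaults; config-overridable)."""

    stubby_max_length_neck: float = 1.5    # stubby: length/neck <= this
    mushroom_min_head_nm: float = 350.0    # mushroom: head diameter >= this ...
    mushroom_min_head_neck: float = 1.5    # ... and head/neck >= this
    filopodial_max_head_neck: float = 1.2  # filopodial: head ~ neck ...
    filopodial_min_length_neck: float = 3.0  # ... and long relative to neck


def classify_spine(features: SpineFeatures,
                   thresholds: ClassificationThresholds | None = None) -> str:
    """Assign one of the five classes by the documented decision cascade."""
    t = thresholds or ClassificationThresholds()
    if features.head_count >= 2:
        return "branched"
    if features.length_neck_ratio <= t.stubby_max_length_neck:
        return "stubby"
    if (features.head_diameter_nm >= t.mushroom_min_head_nm
            and features.head_neck_ratio >= t.mushroom_min_head_neck):
        return "mushroom"
    if (features.head_neck_ratio < t.filopodial_max_head_neck
            and features.length_neck_ratio >= t.filopodial_min_length_neck):
        return "filopodial"
    return "thin"


def largest_remainder_percent(counts: Sequence[int]) -> list[int]:
    """Integer percentages summing exactly to 100 (largest-remainder)."""
    total = sum(counts)
    if total == 0:
        raise ValueError("empty composition")
    raw = [100.0 * c / total for c in counts]
    floors = [int(np.floor(r)) for r in raw]
    short = 100 - sum(floors)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - floors[i]), i))
    for i in order[:short]:
        floors[i] += 1
    return floors


def type_composition(types: Iterable[str]) -> dict[str, int]:
    """Percentage of spines per class, integers summing to 100.

    All five canonical classes appear in the result (zeros included); order
    is invariant to the input order.
    """
    types = list(types)
    if not types:
        raise ValueError("no spine records")
    extra = [t for t in dict.fromkeys(types) if t not in CANONICAL_TYPES]
    keys = list(CANONICAL_TYPES) + extra
    counts = [sum(1 for t in types if t == k) for k in keys]
    pct = largest_remainder_percent(counts)
    return dict(zip(keys, pct))
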