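"""Spine-synapse-bouton graph and the Synaptic Bouton index (SBi).

Each traced synaptic junction is linked to exactly one presynaptic bouton
and one postsynaptic element by voxel adjacency (26-connectivity between
label voxels, minimum contact one voxel by default — tracing in practice is
resolved by eye, so the digital criterion is deliberately permissive).  A
bouton's SBi is the number of distinct postsynaptic elements it innervates:
SBi = 1 defines a single-synaptic bouton (SSB), SBi >= 2 a multi-synaptic
bouton (MSB).  Only the varicosity presynaptic to the labeled spine is
scored; whatever the same axon does elsewhere is out of scope.  Spines
without any junction are flagged non-synaptic (vacant), and spines may carry
several synapses from different boutons (multi-innervated heads, or a head
plus a neck synapse) — each synapse stays its own record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import VoxelSegmentation

__all__ = [
    "SynapseRecord",
    "BoutonRecord",
    "ConnectivityGraph",
    "AmbiguousSynapseError",
    "build_graph",
    "synapse_location",
    "ssb_msb_summary",
    "SsbMsbSummary",
    "ssb_msb_by_type",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class AmbiguousSynapseError(ValueError):
    """A junction touches zero or several boutons (or no postsynaptic element)."""


@dataclass
class SynapseRecord:
    synapse_id: int
    bouton_id: int
    post_id: int
    post_labeled: bool
    location: str | None = None   # "head" | "neck" | None (not yet assigned)
    size_nm3: float | None = None
    sphericity: float | None = None


@dataclass
class BoutonRecord:
    bouton_id: int
    synapse_ids: list[int]
    sbi: int

    def __post_init__(self):
        if self.sbi < 1:
            raise ValueError("SBi must be >= 1")

    @property
    def klass(self) -> str:
        return "SSB" if self.sbi == 1 else "MSB"


@dataclass
class ConnectivityGraph:
    synapses: list[SynapseRecord]
    boutons: list[BoutonRecord]
    spine_synapses: dict[int, list[int]] = field(default_factory=dict)
    nonsynaptic_spines: list[int] = field(default_factory=list)


def _touching_ids(labels: np.ndarray, mask_id: int, sl) -> dict[int, int]:
    """ids touching label ``mask_id`` (26-adjacency) with contact voxel counts."""
    pad = tuple(slice(max(0, s.start - 1), min(dim, s.stop + 1))
                for s, dim in zip(sl, labels.shape))
    sub = labels[pad]
    dil = ndimage.binary_dilation(sub == mask_id, structure=_CONN26)
    neigh = sub[dil & (sub != mask_id) & (sub != 0)]
    ids, counts = np.unique(neigh, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts)}


def build_graph(seg: VoxelSegmentation, min_contact: int = 1) -> ConnectivityGraph:
    """Link every junction to its bouton and postsynaptic element.

    Raises :class:`AmbiguousSynapseError` when a junction touches zero or
    more than one bouton with at least ``min_contact`` voxels.  When a
    junction touches several postsynaptic candidates the one with the
    largest contact is taken (ties to the smallest id).  Labeled spines with
    no junction are flagged non-synaptic.
    """
    labels = seg.labels
    cat = dict(zip(seg.objects["id"].astype(int), seg.objects["category"]))
    labeled_col = (dict(zip(seg.objects["id"].astype(int), seg.objects["labeled"]))
                   if "labeled" in seg.objects.columns else {})
    syn_ids = seg.ids_of_category("synaptic_junction")
    if not syn_ids:
        raise ValueError("segmentation contains no synaptic junction objects")
    slices = ndimage.find_objects(labels)

    synapses: list[SynapseRecord] = []
    bouton_map: dict[int, list[SynapseRecord]] = {}
    for sid in sorted(syn_ids):
        sl = slices[sid - 1]
        if sl is None:
            continue
        contacts = {i: c for i, c in _touching_ids(labels, sid, sl).items()
                    if c >= min_contact}
        bts = sorted(i for i in contacts if cat.get(i) == "bouton")
        if len(bts) != 1:
            raise AmbiguousSynapseError(
                f"junction {sid} touches {len(bts)} boutons {bts}; expected exactly 1")
        posts = [i for i in contacts
                 if cat.get(i) in ("spine", "dendrite_shaft")]
        if not posts:
            raise AmbiguousSynapseError(f"junction {sid} touches no postsynaptic element")
        post = max(posts, key=lambda i: (contacts[i], -i))
        rec = SynapseRecord(synapse_id=sid, bouton_id=bts[0], post_id=post,
                            post_labeled=bool(labeled_col.get(post, True)))
        synapses.append(rec)
        bouton_map.setdefault(bts[0], []).append(rec)

    boutons = [BoutonRecord(bouton_id=b, synapse_ids=[r.synapse_id for r in recs],
                            sbi=len({r.post_id for r in recs}))
               for b, recs in sorted(bouton_map.items())]

    spine_syn: dict[int, list[int]] = {}
    for r in synapses:
        spine_syn.setdefault(r.post_id, []).append(r.synapse_id)
    nonsyn = [int(i) for i, c in cat.items()
              if c == "spine" and bool(labeled_col.get(int(i), True)) and int(i) not in spine_syn]
    return ConnectivityGraph(synapses=synapses, boutons=boutons,
                             spine_synapses=spine_syn, nonsynaptic_spines=sorted(nonsyn))


def synapse_location(spine_mask: np.ndarray, junction_mask: np.ndarray,
                     head_mask: np.ndarray) -> str:
    """Assign a junction to the head or the neck of its spine.

    ``head_mask`` partitions the spine: head region = spine & head_mask,
    neck region = the rest.  The junction's contact voxels (junction voxels
    26-adjacent to the spine) vote for the region they touch; the majority
    wins and ties go to the head (most junctions sit on heads).
    """
    spine = np.asarray(spine_mask, dtype=bool)
    junc = np.asarray(junction_mask, dtype=bool)
    head = spine & np.asarray(head_mask, dtype=bool)
    neck = spine & ~head
    near_spine = junc & ndimage.binary_dilation(spine, structure=_CONN26)
    if not near_spine.any():
        raise ValueError("junction does not touch the spine")
    head_votes = int(np.count_nonzero(near_spine & ndimage.binary_dilation(head, structure=_CONN26)))
    neck_votes = int(np.count_nonzero(near_spine & ndimage.binary_dilation(neck, structure=_CONN26)))
    return "head" if head_votes >= neck_votes else "neck"


@dataclass
class SsbMsbSummary:
    n_boutons: int
    pct_ssb: int
    pct_msb: int
    sbi_histogram: dict[int, int]
    mean_msb_contacts: float


def ssb_msb_summary(boutons: list[BoutonRecord]) -> SsbMsbSummary:
    """SSB/MSB split (integer percent), SBi histogram and mean MSB contacts.

    %SSB is rounded to the nearest integer and %MSB = 100 - %SSB, so the
    pair always sums to 100.
    """
    if not boutons:
        raise ValueError("no boutons")
    n = len(boutons)
    n_ssb = sum(1 for b in boutons if b.sbi == 1)
    pct_ssb = int(round(100.0 * n_ssb / n))
    sbis = [b.sbi for b in boutons]
    hist = {k: sbis.count(k) for k in sorted(set(sbis))}
    msb = [s for s in sbis if s >= 2]
    return SsbMsbSummary(n_boutons=n, pct_ssb=pct_ssb, pct_msb=100 - pct_ssb,
                         sbi_histogram=hist,
                         mean_msb_contacts=float(np.mean(msb)) if msb else float("nan"))


def ssb_msb_by_type(synapses: list[SynapseRecord], boutons: list[BoutonRecord],
                    spine_types: dict[int, str]) -> pd.DataFrame:
    """SSB/MSB fractions per postsynaptic spine type, plus the overall row.

    A bouton contributes to the type of the labeled spine(s) it contacts.
    Raises ``KeyError`` when a labeled spine has no recorded type.
    """
    by_bouton: dict[int, list[SynapseRecord]] = {}
    for r in synapses:
        by_bouton.setdefault(r.bouton_id, []).append(r)
    rows = []
    per_type: dict[str, list[int]] = {}
    for b in boutons:
        labeled_posts = {r.post_id for r in by_bouton.get(b.bouton_id, []) if r.post_labeled}
        for pid in labeled_posts:
            if pid not in spine_types:
                raise KeyError(f"labeled spine {pid} has no type")
            per_type.setdefault(spine_types[pid], []).append(b.sbi)
    for t, sbis in sorted(per_type.items()):
        n = len(sbis)
        n_ssb = sum(1 for s in sbis if s == 1)
        rows.append({"spine_type": t, "n_boutons": n,
                     "frac_ssb": n_ssb / n, "frac_msb": 1 - n_ssb / n})
    all_sbis = [s for sbis in per_type.values() for s in sbis]
    n = len(all_sbis)
    n_ssb = sum(1 for s in all_sbis if s == 1)
    rows.append({"spine_type": "overall", "n_boutons": n,
                 "frac_ssb": n_ssb / n if n else float("nan"),
                 "frac_msb": 1 - n_ssb / n if n else float("nan")})
    return pd.DataFrame(rows)
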