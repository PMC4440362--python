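import numpy as np
import pandas as pd
import pytest

from spinemorph.connectivity import (AmbiguousSynapseError, BoutonRecord,
                                     SynapseRecord, build_graph, ssb_msb_by_type,
                                     ssb_msb_summary, synapse_location)
from spinemorph.phantom import PhantomSpec, build_phantom
from spinemorph.segmentation import VoxelSegmentation


def _seg(labels, rows):
    return VoxelSegmentation(labels=labels, objects=pd.DataFrame(rows))


# -------------------------------------------------------------- the graph

def test_graph_recovery_exact_on_phantom(default_phantom):
    _, _, seg, gt = default_phantom
    graph = build_graph(seg)
    truth = gt.of_category("synaptic_junction").set_index("id")
    assert len(graph.synapses) == len(truth)
    for rec in graph.synapses:
        row = truth.loc[rec.synapse_id]
        assert rec.bouton_id == int(row["bouton_id"])
        assert rec.post_id == int(row["parent_id"])
    gt_sbi = {int(r["id"]): int(r["sbi"]) for _, r in gt.of_category("bouton").iterrows()}
    assert {b.bouton_id: b.sbi for b in graph.boutons} == gt_sbi
    # every synapse is counted exactly once across boutons
    assert sum(len(b.synapse_ids) for b in graph.boutons) == len(graph.synapses)


def test_nonsynaptic_spines_flagged():
    spec = PhantomSpec(rng_seed=5, nonsynaptic_fraction=1.0,
                       n_spines_per_type={"thin": 2, "mushroom": 1})
    _, seg, gt = build_phantom(spec)
    with pytest.raises(ValueError, match="no synaptic junction"):
        build_graph(seg)  # nothing to link — all spines vacant


def test_two_boutons_on_one_spine_yield_two_records():
    # labeled spine 1; bouton 2 with junction 4 on the head side, bouton 3
    # with junction 5 on the neck side — two independent synapse records
    labels = np.zeros((3, 9, 9), np.int32)
    labels[1, 2:7, 4] = 1
    labels[1, 2, 5] = 4
    labels[1, 2, 6] = 2
    labels[1, 6, 5] = 5
    labels[1, 6, 6] = 3
    seg = _seg(labels, {
        "id": [1, 2, 3, 4, 5],
        "category": ["spine", "bouton", "bouton",
                     "synaptic_junction", "synaptic_junction"],
        "labeled": [True, False, False, False, False]})
    graph = build_graph(seg)
    assert len(graph.synapses) == 2
    assert {r.bouton_id for r in graph.synapses} == {2, 3}
    assert all(r.post_id == 1 for r in graph.synapses)
    assert graph.spine_synapses[1] == [4, 5]


def test_junction_touching_two_boutons_is_ambiguous():
    labels = np.zeros((1, 3, 5), np.int32)
    labels[0, 1, 0] = 1   # spine
    labels[0, 1, 1] = 4   # junction
    labels[0, 1, 2] = 2   # bouton A
    labels[0, 0, 1] = 3   # bouton B also touches the junction
    seg = _seg(labels, {"id": [1, 2, 3, 4],
                        "category": ["spine", "bouton", "bouton", "synaptic_junction"],
                        "labeled": [True, False, False, False]})
    with pytest.raises(AmbiguousSynapseError, match="junction 4"):
        build_graph(seg)


# --------------------------------------------------------------- location

def _spine_with_head():
    spine = np.zeros((3, 12, 5), bool)
    spine[1, 1:11, 2] = True
    head = np.zeros_like(spine)
    head[:, :4, :] = True  # distal third is the head region
    return spine, head


def test_synapse_location_head_neck_and_tie():
    spine, head = _spine_with_head()
    junc = np.zeros_like(spine)
    junc[1, 1, 3] = True
    assert synapse_location(spine, junc, head) == "head"
    junc2 = np.zeros_like(spine)
    junc2[1, 9, 3] = True
    assert synapse_location(spine, junc2, head) == "neck"
    # straddle: equal contact on both sides of the boundary -> head
    junc3 = np.zeros_like(spine)
    junc3[1, 3, 3] = True
    junc3[1, 4, 3] = True
    assert synapse_location(spine, junc3, head) == "head"


def test_location_requires_contact():
    spine, head = _spine_with_head()
    junc = np.zeros_like(spine)
    junc[0, 0, 0] = True
    spine2 = spine.copy()
    spine2[0, 0, 0] = False
    with pytest.raises(ValueError, match="touch"):
        synapse_location(np.roll(spine, 2, axis=2), junc, head)


def test_phantom_neck_synapse_located_on_neck():
    spec = PhantomSpec(rng_seed=4, n_spines_per_type={"thin": 1},
                       neck_synapse_fraction=1.0, nonsynaptic_fraction=0.0)
    _, seg, gt = build_phantom(spec)
    row = gt.of_category("synaptic_junction").iloc[0]
    assert row["location"] == "neck"
    spine = seg.labels == int(row["parent_id"])
    junc = seg.labels == int(row["id"])
    # head partition: distal third of the spine in y
    ys = np.where(spine)[1]
    head = np.zeros_like(spine)
    head[:, int(ys.min() + 2 * (np.ptp(ys) / 3)):, :] = True
    assert synapse_location(spine, junc, head) == "neck"


# ---------------------------------------------------------------- summary

def _boutons(sbis):
    return [BoutonRecord(bouton_id=i + 1, synapse_ids=list(range(s)), sbi=s)
            for i, s in enumerate(sbis)]


def test_ssb_msb_split_of_printed_bouton_table():
    # 25 axon terminals of which 6 contact only the labeled spine
    summary = ssb_msb_summary(_boutons([1] * 6 + [2] * 11 + [3] * 4 + [4] * 4))
    assert summary.pct_ssb == 24
    assert summary.pct_msb == 76
    assert summary.pct_ssb + summary.pct_msb == 100


def test_ssb_msb_edge_cases():
    assert ssb_msb_summary(_boutons([1, 1, 1])).pct_ssb == 100
    s = ssb_msb_summary(_boutons([1, 3, 7]))
    assert s.mean_msb_contacts == pytest.approx(5.0)
    assert s.sbi_histogram == {1: 1, 3: 1, 7: 1}
    with pytest.raises(ValueError):
        ssb_msb_summary([])


def test_bouton_record_invariants():
    with pytest.raises(ValueError):
        BoutonRecord(bouton_id=1, synapse_ids=[], sbi=0)
    assert BoutonRecord(bouton_id=1, synapse_ids=[1], sbi=1).klass == "SSB"
    assert BoutonRecord(bouton_id=1, synapse_ids=[1, 2], sbi=2).klass == "MSB"


# ---------------------------------------------------------------- by type

def _wiring(spine_sbis):
    """records for labeled spines i with bouton of given SBi each."""
    synapses, boutons = [], []
    for i, (spine, sbi) in enumerate(spine_sbis):
        sid, bid = 100 + i, 200 + i
        synapses.append(SynapseRecord(synapse_id=sid, bouton_id=bid,
                                      post_id=spine, post_labeled=True))
        boutons.append(BoutonRecord(bouton_id=bid, synapse_ids=[sid], sbi=sbi))
    return synapses, boutons


def test_uniform_sbi_gives_equal_fractions_per_type():
    spine_types = {1: "thin", 2: "thin", 3: "mushroom", 4: "mushroom"}
    syn, bts = _wiring([(1, 1), (2, 2), (3, 1), (4, 2)])
    table = ssb_msb_by_type(syn, bts, spine_types).set_index("spine_type")
    assert table.loc["thin", "frac_ssb"] == table.loc["mushroom", "frac_ssb"] \
        == table.loc["overall", "frac_ssb"] == 0.5


def test_type_bias_recovered_and_single_type_table():
    spine_types = {1: "thin", 2: "thin", 3: "mushroom"}
    syn, bts = _wiring([(1, 1), (2, 1), (3, 4)])
    table = ssb_msb_by_type(syn, bts, spine_types).set_index("spine_type")
    assert table.loc["thin", "frac_ssb"] == 1.0
    assert table.loc["mushroom", "frac_msb"] == 1.0
    single = ssb_msb_by_type(*_wiring([(1, 2)]), {1: "stubby"})
    assert list(single["spine_type"]) == ["stubby", "overall"]


def test_spine_without_type_rejected():
    syn, bts = _wiring([(1, 1)])
    with pytest.raises(KeyError):
        ssb_msb_by_type(syn, bts, {})
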