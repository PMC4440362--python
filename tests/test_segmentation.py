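import numpy as np
import pandas as pd
import pytest
import tifffile

from spinemorph.prep import blur_stack
from spinemorph.segmentation import (import_labels, seed_grow, split_dendrite,
                                     write_labels, VoxelSegmentation)
from spinemorph.stack import ImageStack


def _flood26(predicate, seed):
    """Brute-force BFS flood fill (26-connectivity), independent oracle."""
    from collections import deque
    out = np.zeros_like(predicate, dtype=bool)
    if not predicate[seed]:
        return out
    q = deque([seed])
    out[seed] = True
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in offs:
            p = (z + dz, y + dy, x + dx)
            if all(0 <= pi < s for pi, s in zip(p, predicate.shape)) \
                    and predicate[p] and not out[p]:
                out[p] = True
                q.append(p)
    return out


# -------------------------------------------------------------- seed_grow

def test_uniform_dark_cube_recovered_exactly():
    grid = np.full((8, 16, 16), 200.0, np.float32)
    grid[2:6, 4:10, 5:12] = 10.0
    stack = ImageStack(grid=grid, spacing=(1, 1, 1))
    mask = seed_grow(stack, (3, 6, 8), 100.0)
    expect = np.zeros_like(grid, bool)
    expect[2:6, 4:10, 5:12] = True
    np.testing.assert_array_equal(mask, expect)


def test_only_seeded_blob_returned():
    rng = np.random.default_rng(0)
    grid = np.full((10, 24, 24), 200.0, np.float32)
    grid[2:5, 2:8, 2:8] = 10.0       # blob A
    grid[6:9, 14:20, 14:20] = 10.0   # blob B
    stack = ImageStack(grid=grid, spacing=(1, 1, 1))
    mask = seed_grow(stack, (3, 4, 4), 100.0)
    oracle = _flood26(grid <= 100.0, (3, 4, 4))
    np.testing.assert_array_equal(mask, oracle)
    assert not mask[7, 16, 16]


def test_seed_grow_invariant_to_seed_within_component():
    grid = np.full((6, 20, 20), 200.0, np.float32)
    grid[1:5, 3:15, 3:15] = 10.0
    stack = ImageStack(grid=grid, spacing=(1, 1, 1))
    a = seed_grow(stack, (2, 4, 4), 100.0)
    b = seed_grow(stack, (4, 14, 14), 100.0)
    np.testing.assert_array_equal(a, b)


def test_seed_grow_errors():
    grid = np.full((4, 8, 8), 200.0, np.float32)
    stack = ImageStack(grid=grid, spacing=(1, 1, 1))
    with pytest.raises(ValueError, match="predicate"):
        seed_grow(stack, (1, 1, 1), 100.0)
    with pytest.raises(ValueError, match="outside"):
        seed_grow(stack, (9, 0, 0), 100.0)


def test_blurred_mask_voxel_count_close_to_truth(default_phantom):
    """Seed growth on the radius-10 blurred stack recovers the DAB object
    within 5% of the ground-truth voxel count."""
    from skimage.filters import threshold_otsu
    spec, stack, seg, gt = default_phantom
    blurred = blur_stack(stack, radius_px=10)
    thr = float(threshold_otsu(blurred.grid))
    mask = seed_grow(blurred, gt.shaft_center_zyx, thr)
    labeled_ids = [1] + gt.objects[(gt.objects["category"] == "spine")
                                   & gt.objects["labeled"]]["id"].astype(int).tolist()
    truth = int(np.isin(seg.labels, labeled_ids).sum())
    assert mask.sum() == pytest.approx(truth, rel=0.05)


# ---------------------------------------------------------- import_labels

def _write_label_fixture(tmp_path, labels, table):
    lp, sp = tmp_path / "labels.tif", tmp_path / "labels.csv"
    tifffile.imwrite(lp, labels.astype(np.int32))
    pd.DataFrame(table).to_csv(sp, index=False)
    return lp, sp


def test_import_labels_roundtrip(tmp_path):
    labels = np.zeros((2, 6, 6), np.int32)
    labels[0, :2, :2] = 1
    labels[1, 2:4, 2:4] = 2
    labels[1, 4:, 4:] = 3
    lp, sp = _write_label_fixture(tmp_path, labels, {
        "id": [1, 2, 3],
        "category": ["spine", "synaptic_junction", "bouton"]})
    seg = import_labels(lp, sp)
    assert len(seg.objects) == 3
    assert seg.ids_of_category("bouton") == [3]


def test_touching_junction_labels_stay_distinct(tmp_path):
    labels = np.zeros((1, 4, 6), np.int32)
    labels[0, 1:3, 1:3] = 1
    labels[0, 1:3, 3:5] = 2  # touches label 1
    lp, sp = _write_label_fixture(tmp_path, labels, {
        "id": [1, 2], "category": ["synaptic_junction", "synaptic_junction"]})
    seg = import_labels(lp, sp)
    assert set(np.unique(seg.labels)) == {0, 1, 2}
    assert len(seg.ids_of_category("synaptic_junction")) == 2


def test_import_labels_errors(tmp_path):
    labels = np.zeros((1, 4, 4), np.int32)
    labels[0, 0, 0] = 5
    lp, sp = _write_label_fixture(tmp_path, labels, {"id": [1], "category": ["spine"]})
    with pytest.raises(ValueError, match="absent from"):
        import_labels(lp, sp)
    lp2, sp2 = _write_label_fixture(tmp_path, np.zeros((1, 4, 4), np.int32),
                                    {"id": [], "category": []})
    with pytest.raises(ValueError, match="shape"):
        import_labels(lp2, sp2, expected_shape=(2, 4, 4))


def test_write_labels_roundtrip(tmp_path, default_phantom):
    _, _, seg, _ = default_phantom
    write_labels(seg, tmp_path / "l.tif", tmp_path / "l.csv")
    back = import_labels(tmp_path / "l.tif", tmp_path / "l.csv")
    np.testing.assert_array_equal(back.labels, seg.labels)


# --------------------------------------------------------- split_dendrite

def test_bare_cylinder_has_no_spines():
    z, y, x = np.ogrid[:12, :40, :120]
    mask = (z - 6) ** 2 * 25 ** 2 + (y - 20) ** 2 * 10 ** 2 <= 140 ** 2
    mask = np.broadcast_to(mask, (12, 40, 120)).copy()
    shaft, spines, _ = split_dendrite(mask, (10.0, 10.0, 25.0))
    assert spines == []
    np.testing.assert_array_equal(shaft, mask)


def test_split_recovers_spines_exactly_on_binary_phantom(default_phantom):
    spec, _, seg, gt = default_phantom
    sp_rows = gt.objects[(gt.objects["category"] == "spine") & gt.objects["labeled"]]
    dendrite = np.isin(seg.labels, [1] + sp_rows["id"].astype(int).tolist())
    shaft, spines, res = split_dendrite(dendrite, spec.spacing)
    # voxel conservation and disjointness
    total = shaft.astype(int).copy()
    for s in spines:
        total += s
    assert total.max() == 1
    assert total.sum() == dendrite.sum()
    assert len(spines) == len(sp_rows)
    sx, sy, sz = spec.spacing
    # each ground-truth head centroid falls inside exactly one spine mask;
    # branched spines stay single masks at this stage
    owner = {}
    for _, h in gt.heads.iterrows():
        c = (int(round(h["z_nm"] / sz)), int(round(h["y_nm"] / sy)),
             int(round(h["x_nm"] / sx)))
        hits = [i for i, s in enumerate(spines) if s[c]]
        assert len(hits) == 1
        owner.setdefault(int(h["spine_id"]), set()).add(hits[0])
    assert all(len(v) == 1 for v in owner.values())
    # per-spine recovery and neck-base cut position
    for _, row in sp_rows.iterrows():
        gtm = seg.labels == int(row["id"])
        i = max(range(len(spines)), key=lambda i: int((spines[i] & gtm).sum()))
        iou = (spines[i] & gtm).sum() / (spines[i] | gtm).sum()
        assert iou >= 0.9
        if row["spine_type"] != "stubby":  # stubby has no neck to cut at
            cut_y_nm = np.where(spines[i])[1].min() * sy
            assert abs(cut_y_nm - row["base_y_nm"]) <= 50.0


def test_split_dendrite_empty_mask_rejected():
    with pytest.raises(ValueError):
        split_dendrite(np.zeros((4, 4, 4), bool), (1, 1, 1))


def test_segmentation_invariants():
    with pytest.raises(ValueError, match="absent"):
        VoxelSegmentation(labels=np.ones((1, 2, 2), np.int32),
                          objects=pd.DataFrame({"id": [], "category": []}))
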