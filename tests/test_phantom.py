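import numpy as np
import pytest
from scipy import ndimage

from spinemorph.morphometry import measure_volume
from spinemorph.phantom import (GeometryError, PhantomSpec,
                                apply_acquisition_artifacts, build_phantom)


def test_empty_spec_gives_pure_background():
    spec = PhantomSpec(n_spines_per_type={}, rng_seed=0)
    stack, seg, gt = build_phantom(spec)
    assert np.all(stack.grid == stack.grid.flat[0])
    assert seg.labels.max() == 0
    assert len(gt.objects) == 0


def test_single_mushroom_with_sbi_seven():
    """A bouton with SBi 7 contacts the labeled spine plus six unlabeled elements."""
    spec = PhantomSpec(rng_seed=3, n_spines_per_type={"mushroom": 1},
                       sbi_distribution={7: 1.0}, nonsynaptic_fraction=0.0,
                       neck_synapse_fraction=0.0)
    _, seg, gt = build_phantom(spec)
    boutons = gt.of_category("bouton")
    assert len(boutons) == 1
    assert int(boutons["sbi"].iloc[0]) == 7
    partners = gt.objects[(gt.objects["category"] == "spine") & (~gt.objects["labeled"])]
    assert len(partners) == 6
    syns = gt.of_category("synaptic_junction")
    assert len(syns) == 7
    assert set(syns["bouton_id"]) == {boutons["id"].iloc[0]}


def test_same_seed_bit_identical_different_seed_differs():
    a = build_phantom(PhantomSpec(rng_seed=11, n_spines_per_type={"thin": 1}))
    b = build_phantom(PhantomSpec(rng_seed=11, n_spines_per_type={"thin": 1}))
    c = build_phantom(PhantomSpec(rng_seed=12, n_spines_per_type={"thin": 1}))
    np.testing.assert_array_equal(a[0].grid, b[0].grid)
    np.testing.assert_array_equal(a[1].labels, b[1].labels)
    assert not np.array_equal(a[0].grid, c[0].grid)


def test_ground_truth_sbi_matches_label_adjacency(default_phantom):
    """SBi in the table equals the number of junction labels touching each
    bouton label in the rendered grid (checked by direct dilation)."""
    _, _, seg, gt = default_phantom
    labels = seg.labels
    cat = gt.objects.set_index("id")["category"]
    syn_ids = set(gt.of_category("synaptic_junction")["id"].astype(int))
    for _, row in gt.of_category("bouton").iterrows():
        bid = int(row["id"])
        nzi = np.argwhere(labels == bid)
        pad = tuple(slice(max(0, int(lo) - 1), min(d, int(hi) + 2))
                    for lo, hi, d in zip(nzi.min(0), nzi.max(0), labels.shape))
        sub = labels[pad]
        dil = ndimage.binary_dilation(sub == bid, structure=np.ones((3, 3, 3), bool))
        touching = set(np.unique(sub[dil])) - {0, bid}
        assert len(touching & syn_ids) == int(row["sbi"])


def test_rasterized_volume_converges_to_analytic():
    """A spine head of 20 voxels radius rasterizes to within 1% of the
    closed-form union volume (isotropic 10 nm grid)."""
    spec = PhantomSpec(rng_seed=2, spacing=(10.0, 10.0, 10.0),
                       n_spines_per_type={"mushroom": 1},
                       geometry_ranges={"mushroom": {"neck_len": (400, 400),
                                                     "neck_r": (60, 60),
                                                     "head_r": (200, 200)}},
                       nonsynaptic_fraction=1.0)
    _, seg, gt = build_phantom(spec)
    row = gt.objects[(gt.objects["category"] == "spine") & gt.objects["labeled"]].iloc[0]
    assert row["volume_exact"]
    measured = measure_volume(seg.labels == int(row["id"]), spec.spacing)
    assert measured == pytest.approx(row["true_volume_nm3"], rel=0.01)


def test_artifacts_identity_when_disabled(default_phantom):
    spec, stack, _, _ = default_phantom
    quiet = PhantomSpec(rng_seed=spec.rng_seed, slice_jitter_px=0,
                        intensity_drift=0.0, noise_sd=0.0)
    out, applied = apply_acquisition_artifacts(stack, quiet)
    np.testing.assert_array_equal(out.grid, stack.grid)
    assert (applied.jitters == 0).all()


def test_artifacts_jitter_reproducible_and_bounded(default_phantom):
    spec, stack, _, _ = default_phantom
    cfg = PhantomSpec(rng_seed=9, slice_jitter_px=3, intensity_drift=0.0, noise_sd=0.0)
    _, a = apply_acquisition_artifacts(stack, cfg)
    _, b = apply_acquisition_artifacts(stack, cfg)
    np.testing.assert_array_equal(a.jitters, b.jitters)
    assert np.abs(a.jitters).max() <= 3
    assert tuple(a.jitters[0]) == (0, 0)


def test_artifacts_noise_raises_slice_variance(default_phantom):
    spec, stack, _, _ = default_phantom
    cfg = PhantomSpec(rng_seed=9, slice_jitter_px=0, intensity_drift=0.0, noise_sd=0.05)
    out, _ = apply_acquisition_artifacts(stack, cfg)
    assert np.all(out.grid.var(axis=(1, 2)) > stack.grid.var(axis=(1, 2)))
    out2, _ = apply_acquisition_artifacts(stack, PhantomSpec(
        rng_seed=10, slice_jitter_px=0, intensity_drift=0.0, noise_sd=0.05))
    assert not np.array_equal(out.grid, out2.grid)  # seeds differ -> noise differs


@pytest.mark.parametrize("bad", [
    {"spacing": (0, 3.7, 25)},
    {"n_spines_per_type": {"thin": -1}},
    {"n_spines_per_type": {"weird": 1}},
    {"sbi_distribution": {1: 0.5}},
    {"nonsynaptic_fraction": 1.5},
    {"geometry_ranges": {"thin": {"neck_len": (500, 400)}}},
    {"geometry_ranges": {"branched": {"branch_count": (1, 1)}}},
])
def test_invalid_specs_rejected(bad):
    with pytest.raises(GeometryError):
        PhantomSpec(**bad).validate()


def test_geometry_overflow_raises():
    spec = PhantomSpec(rng_seed=0, grid_shape=(32, 32, 4),
                       n_spines_per_type={"mushroom": 2})
    with pytest.raises(GeometryError, match="geometry"):
        build_phantom(spec)
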