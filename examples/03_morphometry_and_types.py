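"""Measure and classify the spines of a phantom from its exact label grid.

Prints, per spine: voxel volume (nm^3), Wadell sphericity, the extracted
shape features and the assigned class, against the generator's ground truth.
Branched spines are individualized at their shared neck isthmus first.
"""

from spinemorph import (PhantomSpec, build_phantom, classify_spine,
                        extract_features, measure_object, split_branched,
                        type_composition)

spec = PhantomSpec(rng_seed=1)
_, seg, truth = build_phantom(spec)

labeled = truth.objects[(truth.objects.category == "spine") & truth.objects.labeled]
types = []
print(f"{'true type':<11} {'assigned':<11} {'vol (1e6 nm3)':>13} "
      f"{'sphericity':>10} {'neck nm':>8} {'head nm':>8}")
for _, row in labeled.iterrows():
    mask = seg.mask(int(row["id"]))
    parts, branched = split_branched(mask, spec.spacing)
    rec = measure_object(mask, spec.spacing, object_id=int(row["id"]))
    feats = extract_features(mask, spec.spacing)
    label = classify_spine(feats)
    types.append(label)
    print(f"{row['spine_type']:<11} {label:<11} {rec.volume_nm3 / 1e6:>13.2f} "
          f"{rec.sphericity:>10.3f} {feats.neck_diameter_nm:>8.0f} "
          f"{feats.head_diameter_nm:>8.0f}"
          + (f"   ({len(parts)} heads split)" if branched else ""))

print("\ncomposition (%):", type_composition(types))
# sphericity uses the unsmoothed voxel surface, so even round heads score
# well below 1 — comparisons are valid within the constant voxel size.
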