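"""End-to-end pipeline: simulate -> prep -> segment -> measure -> classify ->
connect -> stats, as a configured, logged, reproducible run.

The pipeline reproduces the analysis chain on a phantom acquisition (or on
user-supplied stacks): the degraded stack is aligned and normalized, a
blurred companion is built for seeding, the DAB-dark dendrite is grown from
a seed and cut into shaft and spines, spines are individualized (branched
ones split at the shared neck isthmus), measured and classified, the
synapse/bouton graph is assembled from the traced label volume, and the
statistical layer produces the cohort report: spine-type composition,
morphometry summary, SSB/MSB split with SBi histogram, and the
correlation/binned two-regime analysis of synapse size versus spine volume.

Every artifact is stamped with the config hash and seed; rerunning with an
identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from skimage.filters import threshold_otsu

from . import phantom as ph
from .classification import (ClassificationThresholds, classify_spine,
                             extract_features, type_composition, MaskTooSmallError)
from .connectivity import build_graph, ssb_msb_summary
from .morphometry import measure_object, split_branched
from .prep import align_translation, blur_stack, normalize_slices
from .segmentation import seed_grow, split_dendrite, write_labels
from .stack import write_stack
from .stats import bin_average, fit_two_regime, spearman

__all__ = ["PipelineConfig", "run_pipeline", "fov_of_frame", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending objects."""


@dataclass
class PipelineConfig:
    """All stage toggles and parameters of one pipeline run."""

    out_dir: str = "spinemorph_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "prep": True, "segment": True, "measure": True,
        "classify": True, "connect": True, "stats": True})
    phantom: dict = field(default_factory=dict)   # PhantomSpec field overrides
    blur_radius_px: float = 10.0
    max_shift_px: int = 8
    threshold: float | None = None                # None -> Otsu on the blurred stack
    bin_width_nm3: float = 5.0e6
    min_bins: int = 3
    classification: dict = field(default_factory=dict)  # threshold overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        """Hash of the analysis parameters (the output destination is not
        part of the analysis identity)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def fov_of_frame(pixels_x: int, pixels_y: int, nm_per_pixel: float,
                 ndigits: int = 1) -> tuple[float, float]:
    """Physical field of view (um) of a frame, rounded for display.

    A routine 2048 x 1536 px frame at 3.7 nm/px gives (7.6, 5.7) um.
    """
    if pixels_x <= 0 or pixels_y <= 0 or nm_per_pixel <= 0:
        raise ValueError("frame size and pixel size must be positive")
    return (round(pixels_x * nm_per_pixel / 1000.0, ndigits),
            round(pixels_y * nm_per_pixel / 1000.0, ndigits))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Returns the report dict (also written as ``report.json``).  Raises
    :class:`PipelineError` naming the failing stage.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}
    log: list[str] = []

    st = config.stages
    spec = seg_truth = gt = None

    # ---------------------------------------------------------- simulate
    if st.get("simulate", True):
        spec = ph.PhantomSpec(**{"rng_seed": config.seed, **config.phantom})
        stack, seg_truth, gt = ph.build_phantom(spec)
        degraded, applied = ph.apply_acquisition_artifacts(stack, spec)
        ph.save_phantom(out, stack, seg_truth, gt, spec, applied)
        write_stack(degraded, out / "degraded.tif")
        fov = fov_of_frame(stack.grid.shape[2], stack.grid.shape[1], spec.spacing[0])
        report["stages"]["simulate"] = {
            "grid_zyx": list(stack.grid.shape), "spacing_xyz_nm": list(spec.spacing),
            "n_spines": int((gt.objects["category"] == "spine").sum()
                            ) if len(gt.objects) else 0,
            "field_of_view_um": list(fov)}
        log.append("simulate: ok")
    else:
        raise PipelineError("stage simulate disabled: external inputs are not "
                            "configured; missing artifact 'stack.tif'")

    # -------------------------------------------------------------- prep
    if st.get("prep", True):
        aligned, ares = align_translation(degraded, max_shift_px=config.max_shift_px)
        normalized, nres = normalize_slices(aligned)
        blurred = blur_stack(normalized, radius_px=config.blur_radius_px)
        write_stack(blurred, out / "blurred.tif")
        pd.DataFrame({"slice": np.arange(len(ares.shifts)),
                      "dy": ares.shifts[:, 0], "dx": ares.shifts[:, 1],
                      "cum_dy": ares.cumulative[:, 0], "cum_dx": ares.cumulative[:, 1],
                      "gain": nres.gains}).to_csv(out / "alignment.csv", index=False)
        report["stages"]["prep"] = {
            "crop": list(ares.crop),
            "max_abs_shift": int(np.abs(ares.shifts).max()),
            "boundary_limited": ares.boundary_limited, "flat_slices": ares.flat_slices}
        # keep ground-truth labels co-registered with the cropped frame:
        # jitter recovery is exact on integer jitters, so the aligned stack is
        # the clean stack restricted to the crop window
        y0, y1, x0, x1 = ares.crop
        labels = seg_truth.labels[:, y0:y1, x0:x1]
        log.append("prep: ok")
    else:
        blurred = blur_stack(stack, radius_px=config.blur_radius_px)
        labels = seg_truth.labels

    seg = dataclasses.replace(seg_truth, labels=labels)

    # ----------------------------------------------------------- segment
    if st.get("segment", True):
        if gt.shaft_center_zyx is None:
            raise PipelineError("stage segment: phantom has no dendrite (empty spec)")
        thr = config.threshold
        if thr is None:
            thr = float(threshold_otsu(blurred.grid))
        zc, yc, xc = gt.shaft_center_zyx
        y0, y1, x0, x1 = report["stages"].get("prep", {}).get("crop", (0, None, 0, None))
        seed = (zc, yc - y0, xc - x0)
        dendrite_mask = seed_grow(blurred, seed, thr, dark=True)
        shaft_mask, spine_masks, sres = split_dendrite(dendrite_mask, spec.spacing)
        report["stages"]["segment"] = {
            "threshold": thr, "dendrite_voxels": int(dendrite_mask.sum()),
            "n_spine_masks": len(spine_masks),
            "shaft_radius_nm": sres.shaft_radius_nm, "merged_tiny": sres.merged_tiny}
        log.append(f"segment: ok (threshold={thr:.4g})")
    else:
        if st.get("measure", True) or st.get("classify", True):
            raise PipelineError("stage measure/classify requires segmentation; "
                                "missing artifact 'spine masks' (segment disabled)")
        spine_masks = []

    # ----------------------------------------------- measure and classify
    rows = []
    cls_thr = ClassificationThresholds(**config.classification)
    if st.get("measure", True):
        idx = 0
        for m in spine_masks:
            parts, branched = split_branched(m, spec.spacing)
            for part in parts:
                idx += 1
                rec = measure_object(part, spec.spacing, object_id=idx)
                row = {"object_id": idx, "category": "spine",
                       "from_branched": branched,
                       "volume_nm3": rec.volume_nm3, "area_nm2": rec.surface_area_nm2,
                       "sphericity": rec.sphericity, "eq_diameter_nm": rec.eq_diameter_nm,
                       "method": rec.method}
                if st.get("classify", True):
                    try:
                        f = extract_features(part, spec.spacing)
                        row["spine_type"] = "branched" if branched else classify_spine(f, cls_thr)
                        # individualized heads of branched spines also get a
                        # per-head class (their own sub-composition table)
                        row["head_type"] = classify_spine(f, cls_thr)
                        row["fully_reconstructed"] = True
                    except MaskTooSmallError:
                        row["spine_type"] = None
                        row["head_type"] = None
                        row["fully_reconstructed"] = False
                rows.append(row)
        morpho = pd.DataFrame(rows)
        morpho.to_csv(out / "morphometry.csv", index=False)
        report["stages"]["measure"] = {"n_objects": len(morpho)}
        if st.get("classify", True) and len(morpho):
            typed = morpho.dropna(subset=["spine_type"])
            comp = type_composition(typed["spine_type"]) if len(typed) else {}
            pd.DataFrame([comp]).to_csv(out / "type_composition.csv", index=False)
            cls_report = {"composition_pct": comp,
                          "thresholds": dataclasses.asdict(cls_thr)}
            bheads = typed[typed["from_branched"]].dropna(subset=["head_type"])
            if len(bheads):
                bcomp = type_composition(bheads["head_type"])
                pd.DataFrame([bcomp]).to_csv(out / "branched_head_composition.csv",
                                             index=False)
                cls_report["branched_head_composition_pct"] = bcomp
            report["stages"]["classify"] = cls_report
        log.append("measure/classify: ok")

    # ------------------------------------------------------------ connect
    if st.get("connect", True):
        if not (seg.objects["category"] == "synaptic_junction").any():
            report["stages"]["connect"] = {"note": "no junction objects"}
        else:
            graph = build_graph(seg)
            summ = ssb_msb_summary(graph.boutons)
            syn_df = pd.DataFrame([dataclasses.asdict(s) for s in graph.synapses])
            # annotate junction size from ground truth geometry when available
            if gt is not None and len(gt.objects):
                sizes = gt.objects.set_index("id")["true_volume_nm3"]
                syn_df["size_nm3"] = syn_df["synapse_id"].map(sizes)
                locs = gt.objects.set_index("id")["location"]
                syn_df["location"] = syn_df["synapse_id"].map(locs)
            syn_df.to_csv(out / "synapses.csv", index=False)
            pd.DataFrame([{"bouton_id": b.bouton_id, "sbi": b.sbi, "class": b.klass,
                           "n_synapses": len(b.synapse_ids)} for b in graph.boutons]
                         ).to_csv(out / "boutons.csv", index=False)
            report["stages"]["connect"] = {
                "n_synapses": len(graph.synapses), "n_boutons": summ.n_boutons,
                "pct_ssb": summ.pct_ssb, "pct_msb": summ.pct_msb,
                "sbi_histogram": {str(k): v for k, v in summ.sbi_histogram.items()},
                "mean_msb_contacts": summ.mean_msb_contacts,
                "nonsynaptic_spines": graph.nonsynaptic_spines}
            log.append("connect: ok")

    # -------------------------------------------------------------- stats
    if st.get("stats", True) and gt is not None and len(gt.objects):
        spines = gt.objects[(gt.objects["category"] == "spine") & gt.objects["labeled"]]
        syns = gt.objects[gt.objects["category"] == "synaptic_junction"]
        pairs = spines.merge(syns, left_on="id", right_on="parent_id",
                             suffixes=("_spine", "_syn"))
        stats_rep: dict = {}
        if len(pairs) >= 3:
            try:
                corr = spearman(pairs["true_volume_nm3_spine"], pairs["true_volume_nm3_syn"])
                stats_rep["spearman_volume_vs_synapse_size"] = {
                    "r": corr.r, "p": corr.p, "n": corr.n}
            except ValueError as e:
                stats_rep["spearman_volume_vs_synapse_size"] = {"note": str(e)}
        if len(pairs) >= 2 * config.min_bins:
            series = bin_average(pairs["true_volume_nm3_spine"].to_numpy(),
                                 pairs["true_volume_nm3_syn"].to_numpy(),
                                 width=config.bin_width_nm3)
            if series.n_bins >= 2 * config.min_bins:
                fit = fit_two_regime(series, min_bins=config.min_bins)
                stats_rep["two_regime"] = {
                    "threshold_nm3": fit.threshold, "n_bins": fit.n_bins,
                    "n_lower": fit.n_lower, "lower_r2": fit.lower.r_squared,
                    "lower_slope_p": fit.lower.slope_p, "no_break": fit.no_break}
            else:
                stats_rep["two_regime"] = {"note": f"only {series.n_bins} retained bins"}
        else:
            stats_rep["two_regime"] = {"note": "too few spine-synapse pairs for binning"}
        report["stages"]["stats"] = stats_rep
        log.append("stats: ok")

    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
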