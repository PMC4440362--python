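# Methods

`spinemorph` reimplements, as a tested library, the 3D morphometric and
connectivity analysis of dendritic spines and synapses from labeled
volume-EM (FIB/SEM) stacks: slice alignment and normalization, seed-based
segmentation of DAB-dark dendrites, spine isolation and individualization,
volume/surface/sphericity measurement, five-class spine typing,
synaptic-bouton connectivity (SBi, SSB/MSB), and the binned two-regime
threshold regression. Because no suitable public volume-EM dataset with
per-spine ground truth exists at this scale, every stage is exercised
against a synthetic phantom generator that renders the same structural
repertoire with exact ground truth.

## Coordinate and unit conventions

Arrays are stored `(z, y, x)`; voxel spacing is quoted `(x, y, z)` in nm
(default 3.7, 3.7, 25 — the routine acquisition geometry: ~4 nm/px in the
imaging plane, 25 nm removed per milling cycle). World coordinates are voxel
centers at `index * spacing`, 0-based, half-open ranges. All measurements are
nm-based (nm³ volumes, nm² areas).

## The phantom generator

The generator (`spinemorph.phantom`) renders, on the anisotropic grid and in
physical units:

* a dendritic **shaft**: a dark tube (default radius 200 nm) along x;
* **spines** of five classes built from implicit primitives (cylindrical
  necks, spherical heads, capsules): thin (neck radius 38–50 nm, head
  90–110 nm), filopodial (head = 1.00–1.12 × neck, 650–850 nm long), stubby
  (a capsule 230–300 nm long and 290–350 nm wide fused to the shaft),
  mushroom (head 190–215 nm on a 52–65 nm neck), branched (one shared neck
  splitting into 2–3 headed branches). The class geometry ranges are package
  choices: published class definitions are qualitative, so the generator
  realizes them with canonical, well-separated parameters;
* **synaptic junctions**: darkest thin discs apposed to spine heads (or, for
  a small fraction, necks), penetrating both partners just enough to
  guarantee 26-adjacency of labels across the 25 nm Z spacing;
* **boutons**: bright vesicle-textured capsules; a bouton with SBi = k
  contacts the labeled spine plus k−1 unlabeled postsynaptic elements
  arranged along its axis, each through its own junction disc. The default
  SBi distribution emulates mature connectivity: 28% single-synaptic, most
  multi-synaptic boutons adding 1–3 elements, a small tail reaching 7–10;
* a **neuropil-like background texture** (SD 0.05 around the 0.60 background
  level, fine-grained in-plane and coherent across Z). Real block-face
  images are textured everywhere; without texture, translation registration
  of structure-free slices is ill-posed.

The spine/shaft boundary is the plane tangent to the shaft at the attachment
point; spine-primitive voxels below it are labeled shaft. Ground-truth spine
volumes are closed-form for non-branched spines (head sphere ∪ coaxial neck
cylinder measured from the plane); branched volumes come from 2× supersampled
rasterization and are flagged inexact. Intensity contrast is a free
parameter (real DAB/neuropil statistics are not standardized); the lookup is
documented in `phantom.INTENSITY`.

Geometric simplifications chosen for tractability: neck-synapse boutons and
the per-tip boutons of branched spines are single-synaptic (a partner cloud
at neck height or between branch tips would collide with the spine);
multi-innervated heads get a second single-synaptic bouton tilted 70° toward
Z. One seeded generator drives all randomness: identical spec + seed gives
bit-identical stacks. `apply_acquisition_artifacts` then adds per-slice
integer jitter (slice 0 anchored at zero), multiplicative intensity drift,
and white noise, returning the applied values for oracle tests.

What the phantom does **not** emulate: electron-optics (charging, curtaining,
defocus), membrane ultrastructure (PSD perforation, spine apparatus), curved
or branching dendrites, partial-volume grey levels at object boundaries, and
structured (non-white) detector noise. Passing recovery tests therefore show
the algorithms are correct on well-posed geometry, not that they are robust
to every failure mode of real material.

## Stack preparation

* **Alignment** is rigid translation only: each slice is matched to its
  predecessor by exhaustive normalized cross-correlation over a ±`max_shift`
  integer window (skimage `match_template`; ties resolve toward zero shift),
  shifts are accumulated into the slice-0 frame, and the stack is cropped to
  the always-valid window. Flat slices get shift (0,0) plus a warning flag;
  argmaxima on the window border are flagged boundary-limited. Sub-pixel
  refinement is off: block-face stacks are nearly aligned by construction.
  On noiseless integer-jittered phantoms without oblique presynaptic
  structures, recovery is exact; oblique structures (boutons, partner
  elements) can legitimately displace the correlation optimum by ±1 px
  between slices, which is a property of the images, not the estimator.
* **Normalization** rescales each slice affinely to the stack reference
  (median of slice means and SDs; robust to outlier slices). Zero-SD slices
  are mean-shifted only. The operation is idempotent. Note that per-slice
  gain recovery is only identifiable when slice content statistics are
  stationary; on content-varying stacks the operation equalizes statistics
  rather than inverting the physical drift.
* The **blurred companion** stack (per-slice 2D Gaussian; "radius 10 px"
  interpreted as sigma = radius/2, the common imaging-GUI convention;
  reflective boundaries) is used only to grow seeds — never for measurement.

## Segmentation

`seed_grow` returns the 26-connected component of voxels at or below an
absolute intensity threshold containing the seed (dark-object convention,
invertible), with no morphological clean-up. When no threshold is supplied
the pipeline logs an Otsu threshold computed on the blurred stack.

`split_dendrite` models the shaft as the maximal inscribed tube along the
dendrite's principal path: voxels are binned into 50 nm stations along the
EDT²-weighted principal axis (the sampled dendrites are deliberately
straight segments; the weighting makes the tube core dominate over spines);
the thickest voxel per station within a corridor around the axis forms the
centerline, and the tube radius is the median inscribed-ball radius along
it. Each protrusion outside the tube is cut at its neck base "in 3D optimal
orientation": the cut is the iso-distance shell from the centerline at the
smallest distance whose cross-sectional area is within 5% of the minimum
over the first 30% of the protrusion length (the tolerance stands in for an
exact-tie rule, which rasterization noise would otherwise defeat).
Protrusions under 2 voxels or shorter than 75 nm beyond the tube (surface
roughness) merge back into the shaft. Outputs are pairwise disjoint and
union to the input. Branched spines stay single masks here.

## Centerline anatomy (shared by splitting and classification)

3D thinning is unreliable on 25-vs-3.7 nm anisotropic voxels (parallel
thinning can erase symmetric even-diameter tubes entirely), so spine anatomy
uses a geodesic centerline instead: the mask is resampled to an isotropic
working grid (nearest-neighbor, twice the finest spacing), and paths are
traced by minimum-cost walks whose cost penalizes proximity to the boundary,
so they hug the medial axis. The neck base is either supplied (the
attachment recorded at splitting) or found as the thinnest of up to four
geodesic extremities. Tips are found TEASAR-style — walk to the farthest
unvisited voxel, mark the tube swept by the local inscribed ball as visited,
repeat — so a bumpy head contributes one tip. The neck radius is the minimal
rolling-median inscribed-ball radius along the basal 60% of the main path,
ignoring points whose ball is limited by the cut face; head radius is the
maximal radius in the distal half. A genuine extra head must exceed 1.2× the
neck scale and half the primary head radius.

## Morphometry

* volume = voxel count × (sx·sy·sz);
* surface area, `voxel_face` (default): exposed voxel faces with anisotropic
  face areas. It overestimates smooth surfaces (≈1.5× for a ball — the
  staircase factor) but the bias is shared at constant voxel size, so
  within-study comparisons stand; records carry the method tag and
  sphericities are comparable only within one method;
* surface area, `mesh`: marching-cubes iso-surface at level 0.5 of a lightly
  anti-aliased copy of the 0/1 indicator (Gaussian, sigma = 1 voxel — a
  sub-voxel surface localizer, not object smoothing; the raw binary surface
  overestimates a ball's area by ~8%). The mesh-enclosed volume
  (divergence-theorem sum of signed tetrahedra) pairs with the mesh area in
  the sphericity, so the isoperimetric bound (sphericity ≤ 1) holds exactly
  for every closed triangulation;
* Wadell sphericity = π^(1/3)·(6V)^(2/3)/A; sphere-equivalent diameter =
  (6V/π)^(1/3). (A reported 1.8e8 nm³ spine "around 0.60 μm in diameter"
  corresponds to a 0.70 μm sphere-equivalent diameter; this package always
  reports the sphere-equivalent value.)
* `split_branched` individualizes multi-headed spines by a watershed on the
  negated distance transform seeded at the detected head centers: the ridge
  falls on the thinnest cross-section of the shared neck. Volume is
  conserved exactly (voxel partition).

## Classification

The five classes are assigned by a total decision cascade on the centerline
features: branched (≥2 heads) → stubby (length/neck ≤ 1.5) → mushroom (head
≥ 350 nm and head/neck ≥ 1.5) → filopodial (head/neck < 1.2 and length/neck
≥ 3) → thin. All cut-offs are package defaults, config-exposed and echoed in
output provenance: the source class definitions are qualitative, so exact
reproduction of any published composition is impossible by construction.
Composition tables use largest-remainder integer percentages (they always
sum to 100). Masks under 8 voxels are flagged not fully reconstructable and
excluded.

## Connectivity

Junction labels are linked to boutons and postsynaptic elements by
26-adjacency of label voxels (minimum contact 1 voxel, configurable); a
junction touching zero or several boutons raises an ambiguity error naming
the ids. SBi = number of distinct postsynaptic elements of a bouton; SSB ⇔
SBi = 1; only the varicosity presynaptic to the labeled spine is scored.
Head/neck synapse location is a majority vote of the junction's contact
voxels over a caller-supplied head/neck partition, ties to the head. %SSB is
rounded to the nearest integer and %MSB = 100 − %SSB. Spines without any
junction are flagged non-synaptic (vacant).

## Statistics

Spearman rank correlation (midrank ties, two-tailed) and the Mann–Whitney U
test (pair counting with ½ for ties; full-enumeration exact p when both
samples are under 8, normal approximation with tie and continuity correction
otherwise). The two-regime analysis pools (x, y) points into fixed-width
bins (default 5.0e6 nm³), excludes single-point bins with a logged reason,
and fits an OLS line to the bins below each candidate threshold (interior
bin boundaries leaving ≥ 3 bins per side). The threshold maximizes the
lower-range R². Exact ties — a break-free series — resolve to the smallest
candidate and set `no_break`; near-ties within `plateau_rtol = 5e-4` of the
maximum resolve to the largest candidate, because R² saturates approaching
the true break and collapses beyond it, so the longest equally-good lower
range is the break. On synthetic two-regime data (200 points, break at
5.0e7 nm³) the median threshold error over 100 seeds is zero bins and 92–100%
of seeds land within one bin width, depending on noise. 95% confidence bands
use the t distribution of the lower fit; no multiple-testing adjustment is
applied anywhere (raw p-values, noted in provenance).

## Pipeline and reproducibility

`run_pipeline` chains simulate → prep → segment → measure → classify →
connect → stats from one config (YAML-serializable); every artifact is
stamped with the SHA-256 config hash (output paths excluded from the hash)
and the seed, and identical configs reproduce byte-identical tables. Stage
preconditions fail loudly with the stage name. A thin `spinemorph` CLI wraps
the same functions per stage.

## Problem sizes

Defaults are desk-scale: the default phantom (six spines, one per class plus
a second thin) renders to roughly 970×570×60 voxels (≈3.6×2.1×1.5 μm);
recovery tests run on one to three such phantoms per property, the
breakpoint study on 100 simulated datasets of 200 points, and the null/power
study of the cohort comparison on 100 replicates of n = 50 per arm. Full
acquisitions (2048×1536×442) are out of scope for routine testing but
supported by the same code paths.

## Known limitations

* Classification through the full noisy segmentation path (blur, Otsu
  threshold, noise) is less accurate than on clean masks: blur-grown
  boundaries shrink dark heads below the mushroom cut-off and ragged masks
  perturb neck estimates. The ≥90% recovery property is stated for clean
  geometry.
* The tube model of `split_dendrite` assumes a straight, untapered shaft
  segment (which matches how segments are selected for acquisition).
* Exact jitter recovery is guaranteed only when slice-to-slice content
  displacement is dominated by the in-plane texture (see Alignment).
* Mann–Whitney exact enumeration is O(C(n+m, n)) and restricted to small
  samples by design.
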