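# Methods

## Problem and model

Grading gastrointestinal neuroendocrine tumors (GI-NETs) under WHO 2017 rests
on the Ki-67 index: the percentage of Ki-67-positive tumor nuclei among all
tumor nuclei in a hot-spot, the tumor field with the highest density of
positive tumor cells. Manual practice — pick a hot-spot by eye, count 500 to
2000 cells — is slow and variable, particularly near the G1/G2 boundary at
3 %. This package automates the procedure on paired sections: a
double-immunostained (DS) section in which synaptophysin (Permanent Red)
marks tumor tissue and DAB marks Ki-67-positive nuclei, and the adjacent
H&E section, used for counting total tumor nuclei because hematoxylin-only
nuclei are poorly contrasted against Permanent Red on the DS section.
Adjacent sections are assumed to differ by a similarity transform and to
carry essentially the same tumor content; nuclei inside
synaptophysin-positive regions are all treated as tumor nuclei.

## Pipeline stages and numerical choices

**Registration.** The similarity transform (scale, rotation, translation) is
estimated from ≥ 2 user-supplied landmark pairs by the closed-form Umeyama
least-squares solution (`skimage.transform.SimilarityTransform`), which is
exact on noiseless correspondences; reflections cannot occur because the
estimator is constrained to proper rotations. The H&E image is warped into
the DS frame (the DS frame is the reference for all window coordinates) with
bilinear interpolation and white fill, white being histology background.
Registration runs at full resolution.

**Stain separation.** Optical density is `OD_c = −log10((I_c + 1) / 255)`
per channel; the +1 keeps OD finite at zero intensity. Stains mix linearly
in OD (Beer–Lambert), so concentrations are recovered by inverting a 3 × 3
matrix of unit stain vectors. Defaults: published hematoxylin
(0.650, 0.704, 0.286) and DAB (0.268, 0.570, 0.776) vectors; the Permanent
Red vector (0.214, 0.851, 0.478) is the one the synthetic palette is built
from — real slides should supply their own via config. Deconvolution and
whole-slide masks run at ¼ scale, where stain boundaries remain clearly
resolvable; this cuts memory and time 16-fold. Masks use Otsu thresholds
with an absolute OD floor (default 0.15) so near-empty channels cannot
produce spurious thresholds, followed by the smallest morphology that cleans
the fixtures and remains configurable: opening radius 1 and minimum area
4 px for Ki-67 nuclei; closing radius 2, hole filling and minimum area 64 px
for the tumor region (isolated red specks are not tumor).

**Hot-spot detection.** Centroids of connected components of the
Ki-67-positive-AND-tumor mask are binned into a 2D histogram whose bin side
equals the hot-spot side (500 µm default). Because a true hot-spot can
straddle a bin boundary, candidates are re-scored by exact in-window centroid
counts on a half-window-stride grid; up to five pairwise non-overlapping
windows are selected greedily by descending count, ties broken by row-major
origin (fully deterministic). A window is tumor-eligible when its center is
inside the tumor mask and ≥ 50 % of its pixels are tumor (both configurable);
zero-count windows are never returned.

**Nuclei counting.** On the registered H&E field, k-means with k = 3
clusters pixels into white background, hematoxylin and eosin. Initialization
is deterministic: greedy farthest-point seeding over pixel colors, fitted on
a regular subsample of at most 200 000 pixels, then predicted over the whole
field; roles are assigned by luminance (background) and the R−B channel
difference (hematoxylin = most blue). Because nuclei clump, counts use an
area ratio: `D = round(total nuclei-mask area / A_nuc)`, with `A_nuc` the
median area of "single" components, defined as components at or below the
75th percentile of component areas (configurable). Components touching the
field border are excluded from the single-nucleus area distribution — a
clipped nucleus's area is not a nucleus area — but their pixels stay in the
total, so border effects largely cancel in the ratio. With disjoint
identical nuclei the estimator is exact.

*N* is counted by the same area-ratio rule (per component,
`max(1, round(area / A_pos))`), which degenerates to component counting for
disjoint positives; a `components` mode is available via config. Whole-slide
masks at ¼ scale quantise a single nucleus to a handful of pixels, which
destabilises the per-component ratio, so the selected window's positive mask
is recomputed at full resolution (same threshold rule, morphology radii and
minimum area scaled by the downscale factor). The ¼-scale mask still drives
hot-spot localisation, where only centroid positions matter.

**Grading.** The index is graded unrounded (a 2.96 % index stays G1 even
though it prints as 3.0 %): G1 below 3 %, G2 from 3 % to 20 % inclusive, G3
above. The inclusive reading of both boundaries is adopted; rounding to one
or two decimals is presentation-only, and reports carry both raw and rounded
values. The highest-ranked candidate with D ≥ 500 is reported; if none
qualifies, the rank-1 candidate is returned flagged invalid with a warning.

**Tile heatmap.** Non-overlapping hot-spot-sized tiles (ragged remainders
dropped) are labelled with strict precedence: class 0 if > 70 % background
pixels, class 1 if < 20 % synaptophysin, otherwise class 2/3 by the
tile-local index against the 3 % cut. "Background pixel" is defined in HSV
(saturation < 0.05 and value > 0.85, configurable) since whiteness is what
distinguishes glass from counterstained tissue. Tiles with index above 20 %
are flagged rather than given a fifth class (the intended use covers G1/G2
tumors); eligible tiles with no detected nuclei fall back to class 1 with a
flag, as a tile index is undefined there. Tile labels are designed for
hot-spot-sized tiles: on tiles only a few nucleus diameters across,
components straddling tile borders visibly bias the tile-local counts.

**Statistics.** Linear-weighted Cohen's κ is computed from its definition
(weights |i−j|/(k−1) on observed vs chance-expected proportions); the
interpretation bands are none (< 0), slight [0, 0.21), fair [0.21, 0.41),
moderate [0.41, 0.61), substantial [0.61, 0.81), near perfect [0.81, 1],
with touching boundaries assigned to the upper band. Clopper–Pearson
intervals apply to proportions and use the beta-quantile characterisation;
since the exact method does not define a κ interval, κ gets a seeded
case-resampling bootstrap CI instead, and the distinction is deliberate.

## The synthetic fixtures

The generator emulates what the pipeline consumes, not tissue realism: one
elliptical Permanent-Red tumor blob inside a larger counterstained tissue
ellipse, soft-edged elliptical nuclei (blue negatives, DAB-brown positives),
distractor positives outside the tumor (emulating Ki-67-positive
endothelium/lymphocytes that the tumor-mask intersection must exclude), and
an H&E counterpart rendered in its own frame displaced by a known similarity
transform. Images are synthesised as stain-concentration fields in OD space
and converted to RGB through the configured stain vectors, so deconvolution
is well-posed by construction. Everything is recorded: per-nucleus center,
axes, tumor membership and Ki-67 status, landmark pairs, the transform, and
derived per-window counts and tile classes.

Benchmark defaults (the conditions all accuracy figures refer to):
2000 × 2000 px at 0.5 µm/px; tumor-nucleus density 4000/mm² (≈ 1000 nuclei
per 500-µm window, i.e. twice the 500-cell validity floor); non-tumor
density 1000/mm²; nucleus radius 8 ± 0.5 px (GI-NET nuclei are
characteristically monomorphic, hence the small dispersion); 20 % of nuclei
in sub-diameter clump pairs; 40 distractor positives; hot-spot positive
fraction 5 % versus 1 % elsewhere; misalignment s = 1.015, θ = 0.04 rad,
t = (18, −12) px; Gaussian RGB noise σ = 1.5. Positivity is planted as an
exact count — `round(p · n)` nuclei inside (outside) the hot-spot window —
so the planted window fraction equals p up to rounding and index-recovery
error measures estimation error, not binomial sampling noise; the generator
verifies by brute force that the planted window dominates every half-stride
window. A separate exactness fixture (no clumps, zero radius dispersion,
integer-quantised centers, no noise, identity transform, whole-image field)
probes the regime where area-ratio counting must be exact.

What the fixtures do **not** emulate — stain variability across slides,
texture inside nuclei and stroma, tissue folds and section artifacts,
non-rigid deformation between adjacent sections, out-of-focus regions —
bounds what passing tests show: the pipeline's geometry, selection and
counting logic are correct under the stated model, not that the default
thresholds transfer to arbitrary real slides. Stain vectors, thresholds and
morphology radii are all config values for that reason. One tumor blob is
planted per fixture (multi-blob mask behaviour is exercised directly with
constructed mask images in the stain tests), and the per-nucleus size
distribution is Gaussian with clipping at ±50 %.

## Problem sizes used by the test suite and acceptance script

Unit tests run on 800-px fixtures with 200-µm windows; the accuracy suite
runs the full pipeline on twenty 2000-px benchmark fixtures (seeds 0–19);
the acceptance script analyses twelve 2000-px fixtures end to end plus three
exactness fixtures, with all fixture seeds derived from `--seed`. These
sizes keep a complete run to a few minutes on one CPU while leaving every
window large enough for the 500-cell validity rule to bind.

## Known limitations

- All nuclei inside synaptophysin-positive regions count as tumor nuclei;
  heavy intratumoral inflammation would inflate D.
- Landmarks are manual by design; there is no automatic landmark detection
  or non-rigid registration.
- Default stain vectors (especially Permanent Red) are palette-derived;
  real slides need measured vectors for accurate unmixing.
- Images are loaded whole: no pyramidal WSI formats or tiled streaming.
- The area-ratio counter assumes a unimodal nucleus-size distribution;
  strongly bimodal populations would bias the median-of-singles estimate.
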