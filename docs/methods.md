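# Methods

## Scope and model

`scpnscreen` analyzes plate-based immunofluorescence screens for enhancers
of SCPN (subcerebral/corticospinal projection neuron) subtype refinement.
The biological readout is the transition of immature CTIP2⁺/SATB2⁺ "dual
expressor" neurons into refined CTIP2⁺/SATB2⁻ neurons; CTIP1 serves as a
second exclusionary marker on an independent axis. The analysis consumes
one Hoechst nuclear channel plus up to three marker channels per field,
produces per-nucleus measurements, and aggregates them into per-well
statistics and a ranked compound list. Because no public image set exists
for this assay, the package ships a generative simulator whose defaults
encode the documented study conditions; every quantitative claim made by
the test suite is a claim about recovery of that generator's ground truth
or agreement with an independent oracle (connected-component labeling,
brute-force predicates, closed-form statistics).

## Synthetic plate generator

A field's candidate nuclei are drawn Poisson(density); default density is
300 nuclei per 675×512 px field at 0.65 µm/px (a typical 20× camera
field), matching the ~300-candidate fields of the original assay.
Intensities live on a 12-bit scale (0–4095) in 16-bit TIFF containers —
the only scale on which the fixed classification bands (e.g. SATB2 high
500–1500, Hoechst viability ceiling 900) are plausible.

Each candidate is viable with probability `fraction_viable` (default 0.6,
the stated per-field baseline). Viable nuclei take one of four subtypes
with default fractions (CTIP2-only, SATB2-only, dual, unlabeled) =
(0.05, 0.15, 0.20, 0.60), chosen to reproduce the reported primary-culture
baselines of 20–30 % CTIP2 positivity (here 25 %) and 30–40 % SATB2
positivity (here 35 %) with a majority of each immunopositive population
being dual. Non-viable candidates are fragments (12–30 µm²), fused
doublets (104–155 µm²), or pyknotic nuclei (small and Hoechst-bright), in
a 0.4/0.4/0.2 mix. Viable nuclei have areas 55 ± 8 µm² truncated to
(38, 94) µm² — inside the viability window with margin, so that the ±5 %
area error of half-maximum pixel counting does not flip true labels — and
eccentricities uniform on (0.3, 0.7). Viable Hoechst means are 500 ± 80
truncated to (300, 820); pyknotic means 1200 ± 120 truncated above 960.

Marker intensities come in two modes. *Trimodal* (primary-neuron-like)
wells draw from per-marker Gaussian components whose locations sit inside
the printed classification bands (CTIP2 negative/low/high at 10/110/400;
SATB2 at 25/300/800; CTIP1 at 8/70/200), with spreads small enough that
band classification recovers the true component on ≥ 95 % of nuclei —
the self-consistency the fixed-band policy assumes. *Continuum*
(mES-derived-like) wells draw from two broad overlapping log-normals, the
regime for which the 20 %-of-maximum calibration exists. The latent
positive/negative assignment is the ground-truth label in both modes.

A `CompoundEffect` carries the treatment: `refinement_shift` δ converts a
δ fraction of dual expressors to CTIP2-only (so f′_co = f_co + δ·f_dual and
f′_dual = (1−δ)·f_dual; CTIP2 positivity is conserved exactly — conversion,
never creation), and toxicity removes a `kill_fraction` of cells and
renders a `pyknotic_fraction` of survivors small and bright. An optional
EC50 applies Hill scaling dose/(dose+EC50) to all three, giving
dose-dependent conversion; by default effects are dose-independent so a
planted effect size is realized exactly at every tested dose.

Rendering places cells by dart-throwing with a 10 µm hard-core spacing; a
configurable `clump_fraction` (default 0.1) of nuclei are instead placed
as overlapping pairs at 0.8–1.0× the sum of effective radii, specifically
to exercise clump splitting. Footprints are anti-aliased ellipses whose
per-pixel coverage ramps over ~1 px at the boundary, so the half-maximum
contour encloses the true area; overlaps combine by maximum (avoiding
additive ridges that would defeat per-object re-thresholding); Gaussian
readout noise (σ = 5) sits on a constant background (20). The simulator
deliberately omits optics (PSF, chromatic shift), spatial organization
(rosettes), and illumination gradients — passing tests therefore certify
algorithmic correctness on well-formed fields, not robustness to flat-field
artifacts or out-of-focus data.

All randomness flows from one plate seed through `SeedSequence` children,
one per (well, field): identical seeds give bit-identical plates. A
table-level route (`sample_plate_truth` + `truth_to_candidates`) feeds the
true per-nucleus measurements directly into the analysis stack, which is
how large multi-seed benchmarks avoid re-rendering thousands of images.

## Segmentation semantics

The five screening parameters are given fixed, published meanings:

* foreground = Hoechst ≥ `common_threshold` (0.1) × robust maximum, where
  the robust maximum is the 99.9th percentile (hot-pixel resistance; the
  absolute maximum is selectable);
* connected components are split by watershed on the distance transform,
  with seed maxima closer than `split_factor` (5.0 µm) merged;
* each region is re-thresholded at `individual_threshold` (0.5) × its own
  peak Hoechst value, keeping the connected part containing the peak — on
  anti-aliased nuclei this recovers the half-maximum contour and hence the
  true area;
* regions are discarded below `min_area` (10 µm²) or when
  (mean − local background)/robust maximum < `contrast` (0.05), with local
  background the median in a 2 µm annulus;
* labels are assigned in raster order of first pixel (determinism).

"Object width" is the minor-axis length of the best-fit ellipse. Pixel
coordinates are 0-based with x = column; areas are always µm². No
flat-field correction is applied. On fields of isolated nuclei the
splitter provably reduces to connected-component labeling (tested against
that oracle exactly); note a fused doublet is one blob whose elongation
the splitter may legitimately cut, which is why the oracle fixture
excludes the doublet class.

## QC, classification, scoring, triage

Viability uses the printed strict inequalities (area ∈ (33, 100) µm²,
width > 3.7 µm, Hoechst < 900); boundary values are excluded, and the
recorded exclusion reason is the first failing criterion in the order
area, width, intensity. Well toxicity — a blinded visual judgment in the
original assay — is operationalized as: severe if the viable count falls
below 0.4× the median control-well viable count or the pyknotic fraction
exceeds 0.30; moderate below 0.7× or above 0.15; configurable. Rosette
disruption is not scored.

Band classification uses half-open [lo, hi) intervals; the shared boundary
belongs to the high band and values above the high ceiling are clamped to
high rather than discarded. "Positive" = low ∪ high. The 20 %-of-max
policy calibrates per well, per marker ("other nuclei" = the same well's
nuclei), and reports positives as low, with no high tier.

The refinement ratio is computed from counts pooled across a well's
fields; wells with zero dual expressors have an undefined ratio and are
flagged and excluded from condition means, never imputed. Normalization
divides by the baseline condition's mean: ratio → untreated, CTIP2 total →
Fezf2-modRNA, SATB2 total → GFP-modRNA. Replicate comparisons use the
two-sided pooled-variance Student t (the conventional reading of
"unpaired t-test" at N = 3), with Welch selectable; two identical groups
return t = 0, p = 1 by convention even when within-group variance
vanishes.

Triage runs per (compound, dose): toxicity exclusion (worst replicate
grade), then normalized ratio > `min_norm_ratio`, normalized CTIP2 total ≥
`min_norm_ctip2` (default 0.8 — a noise tolerance on "maintain"), and
normalized SATB2 total ≤ `max_norm_satb2` (default 1.0). Hits are ranked
by descending normalized ratio, ties by ascending normalized SATB2, then
compound id. The default `min_norm_ratio` = 1.0 encodes the qualitative
"enhanced vs unchanged" reading, but 1.0 is the exact center of the null
distribution of a normalized statistic, so any screen at that setting
passes ~half of inert compounds on noise alone. When the expected effect
size is known, the operating threshold should sit between the null noise
band and the effect; the planted-recovery benchmarks use 2.0, the
(rounded) geometric midpoint between the null (1.0) and the ~6-fold
normalized ratio a δ = 0.5 conversion produces, and any threshold in
roughly [2, 4] gives identical results. Note the pooled-count ratio is
right-skewed (denominator noise), so its upper null tail is heavier than
a Gaussian approximation suggests; with ~2,000 candidates per well across
duplicate wells, null excursions to ~1.7 occur at per-plate rates.

## Benchmark sizes and numerical choices

The shipped benchmarks choose sizes that keep the whole suite on one CPU:
segmentation accuracy on a handful of default-density fields (precision
and recall ≥ 0.95 at 2 µm centroid matching, 10 % clumped pairs included);
a rendered 96-well plate at 400×300 px and density 120 for the end-to-end
partition and viability checks; 10,000-nucleus samples for ratio recovery
(within 3 delta-method SEs of the closed form, SE = R·√(1/X + 1/Y)); and
50 table-level screen replicates (30 compounds, duplicate wells at three
doses, ~1,000 candidates per well, four control wells per condition) for
planted-hit recovery. Exact identities (count partitions, normalization
invariances, threshold formulas) are asserted to 1e-12 or exactly; the t
statistic is checked against the textbook formula to 1e-10.

## Limitations

* The toxicity grade quantifies only count depression and pyknosis; the
  original visual criteria (inter-cluster area, rosette disruption) are
  out of scope.
* Segmentation is 2-D, single-plane, intensity-based; no machine-learned
  or 3-D segmentation.
* The simulator's noise model (Gaussian on constant background, no PSF)
  is deliberately simple; performance numbers measured on it are upper
  bounds for real microscopy.
* No multiple-testing correction is applied across the compound library,
  matching the assay's design (a priori triage criteria rather than
  per-compound inference); dose–response curves are not fitted.
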