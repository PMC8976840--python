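# Methods

This note documents the measurement definitions, generator models, default
parameters and numerical choices implemented in `myomam`, together with
their known limitations.

## 1. Contour model

All inputs are membrane traces in nanometre coordinates, not raster
images: closed `mitochondrion` outlines, open `er` polylines and open
`crista` polylines, grouped into imaging fields. Closed contours must be
simple polygons; they are normalized to counter-clockwise orientation on
construction, and an explicitly repeated closing vertex is dropped. The
"ribosome-free" part of the MERC definition is treated as a curation
criterion on the input ER traces (the `assume_ribosome_free` field records
the assumption in outputs); it is not a geometric test.

## 2. Morphometry

**Shape descriptors.** Area and perimeter come from the exact shoelace and
chord-length formulas. Circularity is `4πA/P²` (1 for a circle; bounded by
1 for any simple polygon by the isoperimetric inequality). Aspect ratio is
the major/minor axis ratio of the ellipse sharing the section's second
central moments, computed from the Green's-theorem moment integrals of the
polygon — the ImageJ descriptor family. Units: µm² and µm.

**Cristae abundance.** Total cristae trace length divided by outline area
(µm/µm²). Every crista vertex must lie inside or on the outline within a
10⁻⁶ nm containment tolerance; violations raise instead of silently
clipping.

**MERC detection.** A contact is a maximal arc of the outline whose
minimum distance to any ER trace lies in the gap band. The outline is
resampled at uniform arc spacing ≤ `step`; per sample the minimum
point-to-polyline distance to each ER trace is evaluated (nearest trace
wins, distance ties to the lexicographically lowest ER id). Maximal
in-band runs are taken on the circular sample sequence; runs separated by
less than `merge_gap` of out-of-band arc are merged (digitization
flicker), runs shorter than `min_length` are dropped, and a run crossing
the arc-length origin is split there so every reported segment has
`arc_start < arc_end`. Defaults: band 10–30 nm, `step` 1 nm, `min_length`
10 nm, `merge_gap` 5 nm.

**Coverage and thickness.** Coverage is `100 × Σ segment lengths /
perimeter`. Cleft thickness per contact is the mean of the in-band
distance profile (`full_mean`), or the mean of three seeded random
positions (`three_point`) mirroring the manual protocol. Thickness samples
are restricted to positions whose nearest-point projection falls on the
interior of the ER polyline: at a cut end of a trace the point-to-polyline
distance measures distance to the terminus rather than a membrane-to-
membrane cleft width, and including such flank samples biases thickness
upward. If a segment has no interior-projecting samples the in-band
samples are used as a fallback so a thickness is always defined.

## 3. Synthetic ultrastructure generator

Each mitochondrion is an ellipse whose axis ratio is solved (bisection on
the complete elliptic integral) from the preset circularity target, with a
smooth low-order Fourier radial perturbation (modes 3–6, amplitude ≤ 1%
each) and per-mitochondrion log-normal area scatter. The boundary is
discretized at 512 vertices and every placed vertex is quantized to a
pixel grid (default 2 nm) to mimic digitization. Fields hold up to ten
mitochondria on a 4 µm grid with random rotation.

**Contacts.** Per mitochondrion a target coverage fraction is drawn from
the preset via a log-normal latent factor, split over `1 + Poisson(0.15)`
contiguous arcs (Dirichlet proportions, ≥ 150 nm of guaranteed free arc
between contacts). The cleft width along an arc interpolates truncated-
normal knot draws (knots every 50 nm, truncated to the 10–30 nm band) and
the ER trace is laid at that outward-normal offset with 4 nm vertex
spacing.

**End-trim calibration.** A band-based detector also captures a short
flank beyond each ER terminus: an outline point at arc distance `d` past
the end of a trace laid at gap `g` has distance `√(g² + d²)` to the
terminus, which stays within the band up to `d = √(band_max² − g²)`. Each
generated ER arc is therefore shortened at each end by exactly that
analytic overhang so that the *detected* arc spans the target interval.
This is an a-priori geometric calibration, not a tuned constant; measured
recovery biases are ≤ ~0.5 coverage points and ≤ ~0.3 nm across presets.

**Cristae.** Lamellar cristae are modelled as lightly wiggled chords
perpendicular to the major axis, kept inside 82 % of the local ellipse
half-height, totalling the preset density target (µm/µm²) scaled by a
latent factor correlated with the coverage factor (coupling 0.6), which
reproduces the pooled coverage–cristae correlation.

**Presets.** The six (tissue × age) presets encode the study conditions:
coverage fraction 0.26 → 0.20 → 0.13 in heart and 0.26 → 0.21 → 0.15 in
gastrocnemius for young → middle → old; cleft width 15 → 21 → 23 nm (SD
2 nm, truncated to the band); cristae density falling with age; area and
circularity shifts (larger, rounder heart sections; longer gastrocnemius
sections with age) at magnitudes typical for striated-muscle TEM.

**Limitations.** The generator produces convex-ish perturbed ellipses, not
the occasional highly irregular or donut-shaped profiles of real sections;
ER traces are single-sided offsets (no tubular two-membrane profiles);
within-animal clustering is not modelled (every mitochondrion is an
independent draw, `animal_id = "pooled"`); cristae are lamellar chords
only. These limits are intentional: the generator exists to give the
estimation pipeline a known ground truth, not to be photorealistic.

## 4. Group statistics

Two groups: two-tailed two-sample t-test (Welch by default). Three or
more: one-way ANOVA plus Bonferroni-adjusted pairwise t-tests
(`min(1, m·p)`). Regressions are ordinary least squares with the Pearson r
and its t-based p-value. Mitochondria are treated as pooled independent
observations; outputs carry an explicit note that within-animal clustering
is not modelled. Aging summaries report per-group mean ± SD and percent
change versus young, with a flag (not an error) when the young mean is 0.

## 5. Proteome quantification

Median normalization scales each channel so its median equals the grand
median of the pre-scaling channel medians (idempotent; errors on a
non-positive median, naming the sample). Differential expression per
tissue: fold change = mean(old)/mean(young) of normalized intensities;
p-value from a two-sided Welch t-test on log2 intensities (vectorized);
proteins with any zero channel are excluded and logged. Deregulation rule:
ratio > 1.2 or < 0.83 with raw P < 0.05 — no multiple-testing correction,
matching isobaric-label practice for this design. Cross-tissue
meta-analysis combines the two per-tissue p-values with Fisher's method
(χ² = −2Σln p, df = 2k, upper-tail χ² p; zeros floored at 1e-300 with a
warning) and the geometric-mean fold change, then applies the same
cutoffs. Fraction yield is volume × concentration / tissue mass (mg/g).

## 6. Compartment mapping

Categorical sources vote only when they list exactly one location
(multi-location entries are excluded per source); the consensus is the
strict plurality (tie → `ambiguous`, no votes → `unknown`). Profile-based
mapping follows the MetaMass strategy: row-sum-normalized reference
fractionation profiles are clustered with k-means (k = 8, 10 seeded
restarts), clusters take the plurality compartment of their markers
(lexicographic tie-break, `unassigned` if markerless) and each query
protein inherits the label of its nearest centroid. Compartment
over-representation uses the one-sided hypergeometric tail with
Benjamini–Hochberg correction across compartments.

## 7. Preranked GSEA and enrichment map

The ranking metric is `−log10(p) × sign(log2 FC)` (per tissue or from the
meta-analysis). The enrichment score is the weighted Kolmogorov–Smirnov
statistic (hit steps ∝ |score|^p with p = 1, miss steps uniform; maximum
deviation of the running sum). Significance uses **gene-set permutation**
(random same-size sets from the ranked universe): with three channels per
group, phenotype permutation is degenerate. Implementation notes:

* the observed and null ES are computed from hit positions only — the
  running sum is piecewise linear between hits, so its extrema occur just
  before or just after a hit; this vectorizes the permutation null and is
  verified exactly against the full running-sum computation and against
  `gseapy`;
* null distributions are shared between sets of equal size;
* NES = ES / mean(|null ES| of matching sign); nominal p uses add-one
  smoothing, `(tail count + 1)/(n_perm + 1)`; FDR q follows the standard
  pooled null-NES procedure, clipped at 1.
* sets are filtered to 10–500 members *present in the ranking*.

Enrichment-map edges connect significant sets (q < 0.1) whose combined
coefficient `0.5·O + 0.5·J` (O = overlap coefficient, J = Jaccard) exceeds
0.375; clusters are the connected components of that graph.

## 8. Synthetic proteome generator

Two 6-plex tables (3 young vs 3 old channels per tissue) with log-normal
baselines, per-channel loading biases (so normalization has real work to
do), and planted log2 fold changes (default |FC| ≈ 1.8, 12 % of proteins,
60 % shared across tissues). Compartments follow a mitochondria-
predominant mix (45 % mitochondrion, 20 % ER); categorical sources carry
8 % mislabeling and 10 % multi-location listings; the fractionation
reference uses one well-separated centroid per compartment with 25 markers
each. One gene set is planted among the concordantly up-regulated proteins
plus 30 random background sets. All stages are scored against the recorded
truth table in the test suite.

## 9. Problem sizes and numerical choices

* Outline discretization at 512 vertices keeps vertex spacing (~6 nm)
  safely above the 2 nm pixel quantization, avoiding self-intersections.
* Detection resampling at 1 nm bounds endpoint error by one step; the test
  suite compares against a 0.1 nm dense brute-force classifier.
* Test-suite simulation sizes (typically 40–100 mitochondria, 200–800
  proteins per replicate) are chosen so the whole suite runs in minutes on
  one CPU while keeping Monte-Carlo error well inside the asserted
  tolerances; the acceptance targets use the prescribed n = 100.
* All stochastic code takes explicit seeds; pipeline runs are
  byte-identical for identical config + seed and record parameters, seed,
  package version and input digests in `manifest.json`.
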