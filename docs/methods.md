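# Methods

## Scope and model

The pipeline quantifies the coupling between interphase chromosome-territory
(CT) contact and translocation formation in a three-chromosome painted
system (X, 2, 3; male diploid, so one X and two copies of each autosome).
Three measurement arms share one statistical layer:

1. **Imaging arm** — 3D segmentation of nuclei and painted CTs, per-cell
   intermixing volumes, and a binary contact call per chromosome pair.
2. **Karyotyping arm** — junction detection and rearrangement
   classification on metaphase spreads, giving per-population translocation
   frequencies.
3. **Hi-C arm** — per-chromosome-pair averages of KR-normalized 5 kb
   contact matrices and their relative change between two conditions.

The generative model of the cohort simulator is contact-limited breakage:
per cell and pair, contact ~ Bernoulli(f); translocation | contact ~
Bernoulli(q); no translocation without contact. Expected translocation
frequency is f·q, so regressing translocation frequency (%) on contact
frequency (%) across populations estimates q as the slope.

## Synthetic nuclei

Each nucleus is an axis-aligned ellipsoid (default semiaxes 3 × 4 × 4 µm,
volume ≈ 201 µm³) sampled on an anisotropic grid (voxels 0.3 × 0.15 × 0.15
µm, stack 24 × 64 × 64). Territories are grown by seeded region growth
under a voxel budget: each step 26-dilates the blob and takes the admissible
frontier, so blobs are connected and compact with irregularity contributed
by seed placement, the ellipsoid boundary, anisotropy, and inter-territory
constraints. Two constraint types shape the growth:

* **Exclusion** — pairs drawn *not in contact* may never share a voxel, so
  their true overlap is exactly zero.
* **Overlap quota** — pairs drawn *in contact* absorb partner voxels
  greedily until a per-cell quota is met; the quota is drawn from
  N(target, 0.2·target) (clipped ≥ 1 µm³ so a planned contact always
  exceeds the 0.5 µm³ call threshold), with target defaulting to 5% of
  nuclear volume. A top-up pass after the budget is reached claims any
  remaining quota from partner-adjacent voxels, so the realised median
  intermixing matches the target (the territory then ends slightly over
  its nominal volume budget). Growth occasionally starves when a blob is
  boxed in; placement and growth are retried (up to 5 times) with the
  contact plan held fixed, so population calibration is unaffected.

Default territory volume fraction is 0.18 of the nucleus per chromosome —
comfortably under the 0.28 ceiling observed in this cell system (no single
chromosome fills more than 28% of the nucleus) — and the generator
validates that ceiling as a hard invariant. Truth masks, volumes, pairwise
overlaps (exact voxel intersections) and contact booleans (overlap > 0.5
µm³) are recorded before rendering.

Rendering applies a Gaussian PSF (σ = 0.1 µm, the effective blur of a
deconvolved widefield stack), optional Poisson shot noise, and additive
Gaussian read noise (σ = 0.1 of signal amplitude, i.e. SNR ≈ 10).
A `split_homologs` toggle grows two mutually exclusive half-size blobs per
channel, emulating the unpaired-homolog state (two CTs per autosome).

What the generator does *not* emulate: optical anisotropy of the real PSF,
chromatin substructure within territories, nucleolus/lamina exclusion
zones, segmentation-adversarial artifacts (hot pixels, bleed-through),
or cell-to-cell volume variation beyond the quota draw. Passing recovery
tests therefore demonstrates correctness of the measurement chain on
well-posed inputs, not robustness to every real-microscopy pathology.

## Segmentation

Nuclei: dual-threshold hysteresis on the DNA channel. Thresholds are
fractions (defaults 0.25 / 0.5) of the channel's robust maximum (99.9th
percentile — resists hot pixels); a voxel survives if it is ≥ high, or
≥ low and connected (26-connectivity by default) to a ≥ high voxel through
≥ low voxels. Components smaller than `min_object_volume` (0.5 µm³) are
dropped. Lowering the low threshold can only grow the mask (monotonicity is
asserted in tests).

Territories: per paint channel, Gaussian smoothing (σ = 0.1 µm), thresholds
as fractions of the robust max *inside the nucleus* (defaults 0.45 / 0.7),
markers taken as connected components of the ≥ high region, and marker
watershed on inverted intensity over the ≥ low support restricted to the
nucleus mask. Marker components closer than `seed_min_distance` (1 µm) are
merged. At most `max_objects` (2) largest objects are kept (merged vs split
homologs), extra survivors are QC-flagged.

Two deliberate choices deserve notice. First, the territory thresholds sit
higher than the nucleus defaults: a blurred, nearly binary paint signal has
its true boundary near half-maximum, and a 0.25 support would annex the PSF
skirt and inflate CT volumes by ~25%; 0.45/0.7 recovers volumes to within a
few percent. Second, markers come from high-threshold components rather
than pointwise local maxima: a blurred binary blob tops out in an intensity
plateau on which pointwise maxima are arbitrary ties, fragmenting one
territory into many watershed seeds; high-components are plateau-safe and
give exactly one marker per separated object.

Channels are segmented independently and may overlap — two fluorophores can
occupy the same voxel, and that shared volume *is* the intermixing
measurement. Containment of territories in the nucleus mask is enforced by
construction and asserted exactly in tests.

## Metrics

Volume = voxel count × voxel volume. Intermixing(A, B) = |A ∩ B| × voxel
volume over all objects of each channel pooled (a chromosome-level, not
object-level, quantity, so split homolog pairs sum). Contact is strict:
intermixing > threshold, default 0.5 µm³ (at 0.5 exactly the call is
false). Population summaries report contact frequency and the median
intermixing over all measured cells, zeros included; cells with a missing
territory are excluded from that pair and QC-flagged. Contact frequency is
invariant to uniformly inflating above-threshold overlaps while the median
is not — the two statistics carry independent information, which is why
both are reported.

## Karyotype classification

Spreads are structural: ordered segment lists (color, length in Mb,
intensity, DNA-colocalization flag, both-chromatids flag) per chromosome,
with dm3 arm lengths (X 22.4; 2L 23.0, 2R 21.1; 3L 24.5, 3R 27.9 Mb) and an
unlabeled pericentric block (3–4 Mb) the paints do not tile. A candidate
junction is a color change between painted runs; it is accepted only if
both flanking segments are above k×background (k = 2), DNA-covered, and on
both chromatids. An unlabeled gap between same-color arms is a centromeric
gap, not a junction.

Classification: zero junctions → normal. Junctions group by color pair; a
group whose per-color painted totals are conserved within ε = 5% against
the normal karyotype, with an even junction count on ≥2 chromosomes, reads
as reciprocal events (two junctions each); otherwise each junction is an
independent one-derivative event. One event between two chromosomes is
*compound* when its junction sits at an arm boundary — operationally, the
color change spans unlabeled pericentric material, or lies within δ = 5% of
the containing painted run's length from its edge — and *discrete*
otherwise; ≥2 events or >2 chromosomes is *complex*. A spread is reciprocal
iff all its events are.

Both tolerances (δ, ε) are declared conventions for "seemingly whole-arm"
and "seemingly equal exchange"; they are parameters of `KaryotypeParams`.
Two corner cases are documented rather than hidden: (1) a non-reciprocal
exchange whose lost fragment is below ε of the color's total painted length
is mathematically indistinguishable from a reciprocal one, so the simulator
samples non-reciprocal breakpoints ≥ 25% of the arm from the telomere;
(2) a whole-arm fusion at the centromere of the telocentric X would leave a
paintless centric fragment and a cytologically invisible junction count, so
simulated compound events are restricted to metacentric partners.

## Statistics

OLS with two-sided slope t-test (n−2 df) via `scipy.stats.linregress`;
degenerate SS_tot = 0 is defined as r² = 0, p = 1, flagged. The Fisher test
is computed by exact integer enumeration: all 2×2 tables with the observed
margins are weighted C(r1,k)·C(r2,c1−k) and the two-sided p is the weight
fraction of tables whose weight does not exceed the observed one — integer
comparisons make tie handling exact (the probability-mass-ordering
convention; scipy's implementation agrees to ~1e-7 and is cross-checked in
tests). Percent values ride the 0–100 scale throughout; percent reduction
is reported to the nearest whole percent when mirroring published text.
Regression points are (pair × replicate population) and are unweighted.

## Hi-C change metric

Per pair, the average runs over all stored bins excluding NAs (cis matrices
over the full square including the diagonal by default; an upper-triangle
switch exists). Relative change = (KD − WT)/WT, negative = decrease. The
simulator draws a shared base signal per pair (cis: amp·(1+|i−j|)^−α decay;
trans: flat), applies the condition scales multiplicatively, adds
independent lognormal noise per condition (mean 1, given CV), and masks an
exact count round(na_fraction × bins) of bins NA identically in both
conditions. Noiseless, the recovered change is exactly scale − 1; zeros are
ordinary values, only NA is excluded.

## Problem sizes and determinism

Default problem sizes are chosen to make the full validation cheap on a
laptop: 24 × 64 × 64 stacks (≈ 0.1 s to generate and segment one nucleus),
50–300 nuclei for recovery tests, 1000–1402 structural spreads, 5 kb toy
genomes of 80–120 bins per chromosome. Every generator takes an explicit
seed and is bit-reproducible; cohort seeds are spawned from a root seed, and
the pipeline manifest records parameter snapshots and output hashes so a
rerun is byte-identical.

## Known limitations

* The contact→translocation model is structural, not mechanistic: q lumps
  breakage, proximity during repair, and misjoining into one number.
* The imaging simulator validates the measurement chain, not biological
  shape realism; territory boundaries are smoother than chromatin.
* Reciprocity detection needs the reference painted totals of the normal
  karyotype; aneuploid spreads would need per-spread ploidy inference
  first (only a tetraploidy flag is provided).
* The Hi-C arm consumes already-normalized matrices; balancing and raw
  contact extraction are upstream concerns.
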