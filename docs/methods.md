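# Methods

## Exact-mass lipid database

Species are represented at sum-composition level: a class, total acyl carbons
C_t and total double-bond equivalents D_t. Each class carries the elemental
formula of its virtual 0:0 species; the species formula is

    formula(class, C_t, D_t) = base + C_t · C + (2·C_t − 2·D_t) · H.

The base formulas (e.g. PC C8H16NO8P, PE C5H10NO8P, PI C9H15O13P,
PS C6H10NO10P, PG C6H11O10P, PA C3H5O8P, SM C5H13N2O6P, Cer HNO3) are chosen
so this rule reproduces literature compositions — PC 34:1 = C42H82NO8P,
PI 38:4 = C47H83O13P — and are validated in the test suite against an
independent mass calculator (pyteomics) for ten reference species to
1×10⁻³ Da. Ether classes (PCe/PEe) use the diacyl base +2H −O; plasmenyl
species are folded into the ether class with one extra double-bond equivalent
(the usual shorthand convention). Lyso bases are the diacyl bases +2H −O with
single-chain carbon ranges. Hydroxylated sphingolipid series carry a ";O3"
suffix (one O above the d-backbone). Monoisotopic element masses are fixed
constants (C 12 exactly, H 1.0078250319, …); negative-mode adduct deltas are
electron-corrected constants: [M−H]⁻ −1.00727646, [M+Cl]⁻ +34.96940,
[M+HCOO]⁻ +44.99820, [M−CH₃]⁻ −15.02293 (choline-bearing classes only).

The default enumeration is deliberately combinatorial rather than curated: 25
diacyl-increment classes (the six diacyl glycerophospholipid classes, two
ethers, PIP/PIP2, PGP as the cardiolipin half-unit, and a sphingolipid block
spanning SM/Cer/CerP, Hex1–3Cer, sulfatides, their ;O3 forms and GM1–GM3)
over C 20–50 / DB 0–12, eight lyso classes over C 12–26 / DB 0–6, and free
fatty acids, with D_t capped at ⌊C_t/2⌋. This yields 34,198 species–adduct
entries. The breadth buys completeness at the price of chemically implausible
entries; the ppm tolerance (default 10 ppm, configurable — commensurate with
R ≈ 60,000 instruments) and a fixed class-priority order (brain-abundance
ranked, PC > PE > PI > PS > …) keep annotation deterministic.

**Exact isobars.** Chemistry forces annotation degeneracies: the anion of
PC X:Y after methyl loss is compositionally identical to deprotonated
PE (X+2):Y (and to other combinations such as CerP+formate). Candidates whose
|ppm| ties the best hit within 0.01 ppm are ranked by class priority, and all
species within 0.1 ppm of the top hit are reported as one joined label
("PC 34:1/PE 36:1"). Class aggregation uses the top-ranked species; an
acyl-evidence table (the stand-in for LC-MS/MS identifications) can override
membership for fatty-acyl pooling.

## Datacube processing

Datacubes hold one sparse centroid spectrum per pixel on a row-major, 0-based
grid (10 µm/pixel default) within a 300–1300 Da window. Processed-mode imzML
is read and written via pyimzml; continuous-mode files are rejected because
the chain operates on centroided peak lists. No baseline subtraction, peak
alignment or smoothing is applied anywhere.

TIC normalization divides each pixel by its summed intensity; zero-TIC pixels
are flagged invalid and excluded from all downstream means. The mean spectrum
pools all peaks, sorted by m/z, into bins by a greedy rule: a peak joins the
current bin while its gap to the running intensity-weighted centroid is at
most m/(2R). Channels are local maxima of the binned spectrum; a neighboring
bin competes only when it lies within two bin-widths (2m/R) of the candidate,
so isolated peaks in sparse spectra remain maxima — plain index adjacency
would suppress every second genuine peak once spectra are sparse. Plateau
ties break toward lower m/z. The threshold is chosen as the largest intensity
retaining at least the target number of channels (default 400); the
equivalent fraction-of-maximum is reported for comparison with the
0.5 %-of-maximum convention, and a fixed-fraction mode is available. Feature
matrices assign each peak to the nearest channel center (ties toward lower
m/z) if within the channel half-width m/(2R); the rest is discarded, so row
sums are ≤ 1 with equality only when every peak lands in a window.

## Segmentation

One bisection step is a k = 2 k-means on the feature-matrix rows of the
segment: initial centroids are the rows of two distinct random pixels,
assignment is by Euclidean distance (ties to the first cluster), and
assignment/centroid updates iterate to label convergence (max 100
iterations — convergence subsumes the single assign-and-recompute pass and is
never worse). Each bisection takes the best of 10 seeded restarts by
within-cluster sum of squares; on small segments the restarts enumerate
distinct initialization pairs, which makes the unit-level optimality check
against exhaustive 2-partition search meaningful. An emptied cluster is
re-seeded with the farthest point; identical rows are declared unsplittable.

Supervised segmentation steers the bisection with a guide mask (a truth mask
for phantoms, a hand-drawn mask for real data): at each depth the leaf with
the largest overlap fraction with the guide is split, the Dice coefficient of
the best leaf against the guide is tracked, and a split that fails to improve
it is reverted before stopping (max depth 10 default). The stopping rule
automates the visual "until the neurons sit in one segment" criterion; which
leaf to split when several touch the guide is an interpretation (one leaf per
depth, the max-overlap one). Distances are computed on TIC-normalized rows
without further scaling, mirroring the processing order of the acquisition
software. All seeds are logged; identical seeds give identical trees.

On the phantom suite the packed-blob archetype (fold change 3, pixel CV 20 %)
is recovered with Dice ≥ 0.9 across a 10-seed suite. The micro-soma archetype
(1–4-pixel bodies) is *expected* to defeat automatic segmentation — recorded
as an expected-failure test — and is served by the manual-mask path, as are
the isolated large somas when needed.

## Fingerprint statistics

The ROI fingerprint is the arithmetic per-channel mean over ROI pixels.
Unannotated channels are dropped and the remainder renormalized so identified
species sum to 1 (channels resolving to the same label are summed first).
Left/right hemisphere fingerprints are averaged per (animal, nucleus,
section); singletons pass through with a warning. Class abundances are sums
over species per class and preserve the total; fatty-acyl pools sum species
whose acyl evidence contains the query chain (20:4 for AA, 22:6 for DHA),
with uncovered species counted in a coverage report.

Group comparisons run per feature: classic mean-centered Levene (the SPSS
default; Brown–Forsythe behind a flag) gates the post hoc family — strict
p < α routes to Games–Howell, otherwise Tukey's HSD (Tukey–Kramer under
unequal n) — with a one-way ANOVA F/p attached and stars at raw
p < 0.05/0.01/0.001. The gate had to resolve an ambiguity at exactly
p = 0.05 (both "≥ 0.05 → Tukey" and "≤ 0.05 → Games-Howell" are stated
conventions); strict < 0.05 → Games–Howell was chosen. No multiple-testing
correction is applied by default (stars reflect raw thresholds);
Benjamini–Hochberg q-values are optional. Levene, ANOVA and Tukey are
delegated to scipy; Games–Howell (pairwise Welch standard errors,
Welch–Satterthwaite df, studentized-range p at q = t√2) is implemented here
and cross-checked against pingouin to 1×10⁻⁶. Under 1,000 null cohorts the
full chain's per-feature star rate is calibrated to α = 0.05 within
[0.035, 0.065], and a planted 0.7× SM effect at n = 5 animals/sex is detected
in ≥ 80 % of 200 replicates.

PCA min-max scales each feature to [0, 1] over the analyzed samples (constant
features map to 0), mean-centers, and decomposes via SVD; component signs
follow the largest-|loading|-positive convention so results are
reproducible. Explained-variance fractions are non-increasing and sum to 1
over full rank.

## Synthetic phantoms and cohorts

The generator emulates the *statistical* structure of the acquisitions, not
the instrument physics. Defaults: a 64×64 grid at 10 µm/pixel; a background
lipidome of 31 abundant negative-mode brain species (PC/PE dominant, then
PI, PS, ethers, SM, sulfatides; choline classes observed as [M−CH₃]⁻, others
as [M−H]⁻) normalized to sum 1; per-pixel intensities = abundance ×
unit-mean lognormal species noise (CV 20 %) × lognormal pixel TIC factor
(CV 15 %) + ~40 uniform-m/z chemical-noise peaks per pixel at 2 % of the mean
species signal; centroid jitter 5 ppm SD (consistent with R ≈ 60,000
centroiding). The background avoids planting both members of any exact
isobar pair (e.g. PE 36:2 rather than PE 36:1 alongside PC 34:1) so
annotation recovery is well-posed; the isobar behavior itself is tested
separately. ROI archetypes: packed blob (disc, radius 15 px), isolated somas
(5–7-px components ≥ 10 px apart), micro-somas (1–4-px components). Fold
changes default to the population signatures (LC-like: PI 38:4 ×3,
PI 38:6 ×0.4; Me5-like: PI 38:6 ×3, PI 38:4 ×0.5; SNc-like: PI 38:4 ×2.5).
In the noise-free limit, TIC normalization recovers the planted proportions
exactly, and recorded fold changes equal ratios of noise-free means by
construction.

Cohorts add animals × sections × hemispheres (default 5 animals/sex, 1
section, L+R): a per-animal lognormal random effect (CV 10 %, shared between
hemispheres — typical animal-to-animal variability of class-level relative
abundances), a per-sample residual (CV 5 %), and multiplicative sex effects
on configured classes in male ROIs (e.g. SM ×0.7). Because fingerprints are
compositional, a ×0.7 class effect appears slightly damped after
renormalization; effects are recorded as applied. `make_cohort` renders full
datacubes; `sample_cohort_fingerprints` draws the ROI fingerprints from the
same factor model without pixel rendering, and is what the repeated-cohort
simulations (1,000 null replicates, 200 power replicates) use — the two paths
share the abundance and factor model, and a smoke test ties them together.
Randomness comes exclusively from seeded NumPy PCG64 generators (child seeds
via SeedSequence), so all outputs are bit-reproducible across platforms.

What passing phantom tests do *not* show about real data: no anatomy (masks
are geometric), no isotope envelopes or in-source fragments, no matrix or
ionization physics, no section-to-section thickness or matrix-deposition
drift, and chemical noise that is white in m/z rather than structured.

## Numerical and degenerate-input choices

Zero-TIC pixels stay zero and are excluded from means; an empty candidate
list is a valid annotation result; fingerprint renormalization requires at
least one annotated channel with positive signal; constant features are
skipped in group tests (reason recorded) and map to zero loadings in PCA;
fewer mean-spectrum peaks than the channel target keeps all peaks with a
warning. The pipeline manifest records versions of nothing but the run
itself: parameters, per-stage record counts, seeds and SHA-256 hashes of
every output, and contains no timestamps so that identical config + seed
reproduces byte-identical output trees.

## Problem sizes

Default test/illustration sizes: 64×64-pixel phantoms (~291k peaks), 400
extracted channels, ~34k-entry database, cohorts of 20 samples (5
animals/sex × L/R). Repeated-cohort calibration uses the fingerprint-level
sampler at the same design sizes.
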