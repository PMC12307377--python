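# Methods

## Trait model

The registry holds 25 foxtail millet descriptors: 11 quantitative traits
(seedling-to-spike period STC and growth period GP in days; main spike
length MPL and main stem length MTL in cm; stem thickness ST in mm;
single-spike weight SSW, single-spike grain weight SGW and 1000-grain
weight TGW in g; CIELAB grain color L*/a*/b*, dimensionless) and 14
qualitative characters coded as consecutive positive integers against a
descriptor list (e.g. leaf sheath color 1=Green, 2=Red, 3=Violet). Two
conventions deserve note:

* **Hull color is renumbered 1–7.** The source descriptor list assigns the
  same code to two hull colors; since seven distinct classes are observed,
  the registry renumbers them consecutively.
* **Seta length (SL) and bristle color (BC) are kept as distinct coded
  traits.** Published summaries are ambiguous about which physical
  character each frequency row describes ("seta color" vs "seta length");
  the registry does not assert an identification beyond the two codes.

Qualitative codes are treated as numeric downstream — their CVs, their use
in component-score formulas, and the clustering distances are all defined
on the integer codes. This is the convention under which the published
summary statistics are internally consistent.

Multi-year observations are aggregated to final trait values by the
arithmetic mean (quantitative) or the modal code with earlier-year
tie-break (qualitative). The tie-break is a determinism choice; no
aggregation rule for coded traits is standard.

Missing values are permitted (NaN). Statistics delete missing cells
pairwise and log the count; accessions with any missing trait are excluded
from composite scoring and clustering.

## Diversity statistics

* Sample SD with the n−1 denominator throughout. Recomputing the published
  qualitative CVs from their printed class counts matches to 2 dp only
  under n−1, which fixes the convention.
* CV = 100·S/X̄, undefined at X̄ = 0 (error).
* 10-class stratification: cut points at X̄ + kS for
  k ∈ {−2, −1.5, …, +2}. Class 1 is x ≤ X̄ − 2S and class 10 is
  x ≥ X̄ + 2S (both closed, as published); interior classes are half-open
  [lower, upper), so a value exactly at the mean falls in class 6 and a
  value exactly on an interior cut point falls in the upper class. Only
  the extreme closures are prescribed by the source; the half-open interior
  is this package's documented choice.
* H′ = −Σ pᵢ ln pᵢ over occupied classes with 0·ln 0 := 0 (natural log).
  For a standard normal trait the exact class probabilities give
  H′ = 2.0878, which the implementation reproduces on 10⁶ draws to ±0.01.
* A zero-SD trait yields a degenerate profile (all mass in class 6,
  H′ = 0) with a warning rather than an error.

Known inconsistencies in the published qualitative table, handled by
asserting the recomputed (not printed) values: the leaf-sheath-color and
seedling-leaf-color rows have their CV/H′ values transposed (recomputed:
LSC H′ 0.87 / CV 51.86; SLC H′ 0.44 / CV 31.71); hull color's printed
H′ 0.44 does not follow from its own printed counts (recomputed 0.48);
spike neck shape's printed CV 7.44 likewise does not recompute (7.94),
though its H′ 0.04 does. All other rows recompute exactly to the printed
precision.

## Correlation and PCA

Pearson correlations are computed pairwise-complete with two-sided
p-values from t = r√((n−2)/(1−r²)); cells with fewer than three complete
pairs are undefined. No multiple-testing correction is applied by default
(an optional Benjamini-Hochberg flag exists) — raw p-values are the
convention in descriptor surveys.

PCA is the eigendecomposition of the 25-trait correlation matrix (coded
qualitative traits included). Conventions:

* eigenvalues sorted descending; Σλ = 25 (trace);
* loadings = v√λ (trait-component correlations), so L Lᵀ reconstructs the
  correlation matrix when all components are kept;
* score coefficients = unit eigenvector elements = loading/√λ. A component
  score Fᵢ = z·vᵢ therefore has sample variance λᵢ on the fitting data.
  (Published coefficient tables verify this convention: 0.54/√3.31 ≈ 0.298.)
* contribution rate = 100·λ/25, cumulative = running sum;
* retention: λ > 0.95 and component index ≤ 10, both configurable;
* sign fix: the trait with the largest |loading| per component loads
  positively (signs are otherwise arbitrary);
* eigenvalue ties (measure-zero in practice) resolve by the deterministic
  LAPACK ordering of `numpy.linalg.eigh`.

The published loading and coefficient tables are mutually consistent
within their printed rounding: with loadings at 2 dp (±0.005),
coefficients at 3 dp (±0.0005·√λ after scaling) and eigenvalues at 2 dp
(±0.0025·|coef|/√λ through the square root), the per-cell envelope is
≈0.006–0.008, and 96 % of cells agree within the loading's own 0.005. The
consistency test asserts the propagated envelope per cell rather than a
blanket 0.005, which the compound rounding cannot guarantee.

## Composite scoring

Weights are the retained contribution rates normalized by their sum
(equivalently by the cumulative rate of the last retained component);
F = Σ wᵢFᵢ; ranking is dense by descending F with ties ordered by
accession id. Rounding weights to 3 dp — as published formulas do — makes
them sum to 0.999; the package computes with unrounded weights by default
and exposes rounding as a replication option.

Two normalizations feed the score coefficients: z-scores (default — the
convention under which the coefficients are derived) and mean-centered
membership functions u = (x − min)/(max − min). Because Pearson
correlation is affine-invariant, the PCA is identical either way; only the
per-trait scaling of the scores differs, and on well-conditioned panels
the two rankings agree closely (Spearman ρ > 0.9 on the test fixture).
Adding a constant to any raw trait leaves z-score-based F unchanged.

## Hierarchical clustering

Ward linkage on Euclidean distances over z-scored traits (average and
complete linkage available), cut at k = 5 by default. Neither linkage nor
distance is prescribed by the source; Ward/Euclidean is the standard
choice for trait dendrograms. Labels are renumbered by descending cluster
size (then first member) so outputs are stable across runs and row
permutations. A config option excludes any single trait to mimic a
24-trait sensitivity run. The merge history exports as newick with branch
lengths derived from merge heights.

## Synthetic cohorts

The generator emulates the published marginals of the 1,558-accession
panel:

* **Quantitative traits** are truncated normals on the published
  [min, max]. The parent (μ, σ) is *moment-matched*: solved (via
  `scipy.stats.truncnorm` + root finding) so the truncated distribution
  has the published mean and SD, since those moments describe data already
  confined to the observed range. Naive truncation of N(mean, SD) would
  shrink the SD by up to ~6 % for traits whose range sits close to the
  mean (e.g. growth period, min at 2.2 SD). Sampling is by rejection
  (cap 1000 rounds per cell, then clip).
* **Qualitative traits** are categorical draws with the published class
  frequencies (counts normalized by their column sum; one published row
  accounts for 1,557 of 1,558 accessions).
* **Correlation** (optional): a positive semi-definite unit-diagonal
  matrix over the quantitative traits couples the underlying normal draws
  via Cholesky. Out-of-range cells are redrawn from the trait's marginal,
  which slightly dilutes tail correlation — negligible here because the
  published ranges sit ≥2.2 SD from the means. An injected r = 0.8
  between SSW and SGW is recovered within [0.75, 0.85] at n = 10⁴.
* **Material classes** are sampled with the published panel composition
  (847/432/256/4/19).
* **Seeding**: one master seed; per-trait substreams derived from
  SeedSequence((seed, sha256(trait name))), so adding or removing a trait
  does not perturb the other columns. Identical spec + seed ⇒ identical
  table.

What the generator does *not* emulate: year-to-year environment effects,
genotype/pedigree structure, quantitative-qualitative dependence, and the
real panel's inter-trait correlation structure (independent by default).
Consequently, passing tests demonstrate the correctness of the statistics
and the pipeline plumbing on distributionally faithful marginals — not
that the pipeline reproduces the real panel's PCA spectrum (the default
synthetic cumulative contribution of the top 10 PCs is ≈45 %, below the
64.3 % observed on the correlated field data) or its cluster memberships.

## Problem sizes used in verification

The test suite exercises: moment recovery at n = 10⁵ (single trait) and
n = 2×10⁴ (all traits), entropy of 10⁶ standard-normal draws, 100 random
25-trait panels against an SVD oracle, 1,000 random vectors against a
brute-force binning oracle, Ward merge histories on 6-point instances
against an exhaustive agglomeration oracle, and planted 5-centroid
recovery at the study size n = 1,558 (adjusted Rand > 0.95, planted MPL
centroids recovered within ±0.5 cm). These sizes keep the statistical
envelopes tight (binomial/χ² sampling error well inside the asserted
tolerances) while the whole suite runs in seconds.

## Known limitations

* Published accession-level results (top-10 F values, real cluster
  memberships, the real panel's Tables of loadings) are not reproducible
  without the raw data; the package verifies instead every published
  number that is a pure function of other published numbers, plus
  statistical properties on synthetic panels.
* Ordinal qualitative codes are treated as numeric throughout (no
  polychoric correlations, no factor rotation) — deliberately, to match
  the published methodology.
* The composite score inherits PCA's sign conventions; F values are
  comparable within a fitted panel, not across panels.
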