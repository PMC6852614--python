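# Methods

This note documents the models, estimators, numerical choices and known
limitations of phnatlas, in the order data flows through the pipeline.

## Marker-gene-normalized prevalence

Gene-catalogue profiles carry, per sample, read counts mapped to each
catalogue gene divided by the gene's length (reads per base, arbitrary
per-sample scale). For a function *F*, the abundances of all catalogue
genes assigned to *F* are **summed** and divided by the summed abundance
of the single-copy marker recA (COG0468), ×100. Summation (rather than
averaging) across a function's catalogue entries is deliberate: distinct
entries are sequence variants of the same gene carried by different
organisms, so their reads are disjoint contributions to the community
total. Because every genome carries exactly one recA, the ratio is a
consistent estimator of the mean copy number of *F* per organism; for a
single-copy function it is the fraction of organisms carrying it, and
values above 100% read as multiple copies per genome (copies per cell =
percent / 100). The estimator is invariant to any per-sample rescaling of
the profile, so the catalogue's unspecified per-sample normalization
constant is irrelevant to every downstream quantity.

Samples whose marker abundance is zero yield a *missing* prevalence,
never zero: a zero denominator is a data failure, whereas 0% is a
biological claim.

Depth stratification uses the sampled horizons only: epipelagic (EPZ) is
the 5 m surface plus the 17–183 m deep-chlorophyll-maximum layer;
mesopelagic (MPZ) is 200–1000 m; anything else (including the unsampled
6–16 m gap) is OTHER. No interpolation between zones is invented.

## Synthetic communities and what they do (not) show

The generator draws a community of `n_genomes` genomes. Copy numbers: one
copy of recA and of each of the 40 universal single-copy marker genes per
genome; focal-function copies from a configurable distribution (default
{0: 0.5, 1: 0.4, 2: 0.1} — half the genomes are carriers, a fifth of the
carriers duplicated). Gene lengths are uniform on [600, 2400] bp,
bracketing typical bacterial coding sequences so length normalization is
exercised nontrivially. Each genome belongs to one of 8 taxon bins named
after lineages in which C–P lyase actually occurs.

Per sample, latitude is uniform on ±65° and phosphate follows a
deterministic log-linear field in |latitude| — depleted in the
low-latitude gyres, replete poleward — which makes Pi log-uniform over
`pi_range` (default 0.02–1.0 µmol kg⁻¹, a balanced design for the
log–log regression) and lets the same field generate the synthetic
climatology grid, so station matching recovers in-situ Pi up to grid
discretization. Community composition is Dirichlet with total
concentration 200 and carrier-block expectation equal to the target
`f(Pi) = 10^(a + b·log10 Pi) / 100` (defaults a = −0.5, b = −1.0, keeping
prevalence in the ~0.3–16% range observed for C–P lyase at sea). The
*realized* composition is recorded as truth; all recovery tests compare
against realized, not target, values.

Sequencing noise is Poisson on length-proportional expectations: gene
*g* of genome *i* receives `Poisson(depth · ab_i · copies_ig · len_g / T)`
reads, `T` the abundance-weighted community genome length, so the
expected total is exactly `read_depth` (default 10⁶, configurable — a
typical survey-scale depth). A `noise_free` switch substitutes the
expectations themselves, separating estimator correctness (exact
recovery to machine precision) from sampling error. Poisson is the
minimal sequencing model and keeps every oracle analytic; it omits GC
bias, read errors, mapping ambiguity and overdispersion, so passing
tests demonstrate estimator correctness under ideal mapping, not
robustness to real library artefacts.

One consequence of the Dirichlet composition model worth knowing when
reading demo output: the relative standard deviation of the realized
carrier fraction is `sqrt((1−f)/(conc·f))`, which grows as `f` shrinks.
On the log scale this asymmetric noise pulls low-prevalence
(phosphate-replete) samples downward, so log–log fits on *community*
simulations are systematically somewhat steeper than the generative
exponent. Slope-recovery validation therefore uses the direct
log-Gaussian design (`y = a + b·x + N(0, σ)`), where the fitted slope is
unbiased; the community simulator's role is exercising the full pipeline
against known realized truth.

## Alignment preprocessing

Columns whose gap fraction is **strictly greater** than 10% are removed
(a column at exactly 10% is kept — literal reading of "more than 10%"),
then rows identical *after* trimming are collapsed, keeping the
first-seen name. The operation reports (unique sequences, positions).
Note it is not strictly idempotent in pathological cases: removing
duplicate rows can push a column's gap fraction across the 10% threshold
on a second pass. The synthetic untrimmed-alignment fixture (a
constructed stand-in for a redundant PhnJ protein alignment, truth known
by construction: 440 unique sequences × 276 surviving positions) places
its boundary columns so the threshold is stable under deduplication.

## Taxon classification and enrichment

Query leaves (tree leaves absent from the reference taxonomy map) are
assigned the taxon of the reference leaf at minimum patristic distance.
Distance ties — compared with a 1e-9 relative tolerance, since float
path sums over different routes can differ in the last ulps — fall back
to the longest common prefix of the tied references' semicolon-delimited
rank paths, truncating whole ranks only ("Alpha;SAR11" vs "Alpha;SAR116"
→ "Alpha"); an empty shared prefix yields "unclassified". Patristic
distance is a path-length sum, so the assignment is provably independent
of root placement (verified by rerooting tests). This operationalizes,
as a deterministic rule, what is in practice a conservative manual
reading of a reference tree; it is an approximation, and a query whose
true lineage has no reference nearby will be attracted to whatever is
closest.

Taxon **contribution** is the taxon's share of total focal-gene
abundance per sample (unclassified genes pooled; shares sum to 1 by
construction, missing when total abundance is 0). Taxon **enrichment**
divides the taxon's summed focal abundance by the mean over the 40
marker *functions* of the taxon-matched, per-function-summed marker
abundance — the mean is over the 40 functions (absent combinations count
as zero), not over individual genes, so a taxon missing some markers in
a sample is penalized rather than silently inflated. Merging of related
bins (e.g. a family with a genus-level clade inside it) is done on
abundances, before normalization.

## Coverage-based population quantification

Mean per-base depth of a gene = summed overlap of read intervals with
the gene's interval / gene length, on 0-based half-open coordinates
(gene tables arrive 1-based inclusive and are converted by start−1).
Depth, not breadth or median, because the copy-number interpretation
requires it. Reads are unstranded, count once each (multi-mapping is
upstream's concern), and contribute only overlapping bases. The
population percent is focal coverage over the mean of the 40 marker-gene
coverages; it is invariant to rescaling all coverages and to splitting
reads into abutting fragments. The read simulator places Poisson counts
of fixed-length reads uniformly over all start positions overlapping a
gene, which makes the expected depth exactly the requested coverage at
every base of the gene; gene tables generated for it pad contigs by one
read length so edge clipping never biases the fixture.

## Climatology matching

The nearest non-missing grid node by planar Euclidean distance in
(latitude, longitude) degrees — longitude wrapped at ±180 — then the
nearest depth level, accepted only if |Δlat|, |Δlon| and |Δdepth| fall
inside the per-axis tolerance box. Presets: `woa` (1°, 1°, 5 m, annual)
and `pisces` (0.3°, 0.3°, 5 m, monthly; candidates restricted to the
sample's month). Planar degree distance mirrors a kd-tree
nearest-neighbour search on degree coordinates and is documented as an
approximation to great-circle distance; within ≤1° boxes the
discrepancy cannot change acceptance, only rare tie orderings. Missing
cells are skipped (next-nearest non-missing node wins); remaining ties
break lexicographically on (lat, lon, depth) for determinism. Matching
is per-station and therefore permutation-invariant, and tightening any
tolerance can only lose matches. Ratio covariates (Fe:Pi, N:P) are
missing wherever an operand is missing or the denominator is zero — a
zero concentration is legal data, but not a divisor.

## Statistical layer

* **Pearson** correlations with two-sided p from the t transform on n−2
  df; incomplete pairs dropped; zero variance is an error, not r = 0.
* **Log–log OLS** of log10(percent) on log10(Pi). Non-positive or
  missing values are dropped and counted in `zero_dropped` — no
  pseudo-counts, which would bias slopes; the count is always reported
  so the reader sees what the fit ignored.
* **Slope difference**: z = (b₁−b₂)/√(se₁²+se₂²), two-sided normal p,
  judged at 0.05. Valid for independent fits only.
* **Two-predictor model**: log10(percent) ~ region + log10(Pi), Type II
  sums of squares for the per-predictor F tests (the conventional choice
  for unbalanced designs without interactions). A single-region input
  degenerates exactly to the plain fit (F = t²).
* **Kruskal–Wallis** (tie-corrected, χ² with k−1 df; all-identical
  values give H = 0, p = 1) across regions, then pairwise two-sided
  rank-sum (Mann–Whitney) tests — exact for groups of ≤8 without ties,
  normal approximation with tie correction otherwise — adjusted by
  Benjamini–Hochberg over the k(k−1)/2 pairs of one gene within one
  depth zone; families are never pooled across genes. A region is
  *enriched relative to all other regions* iff every adjusted pairwise p
  is < 0.05 **and** its median exceeds every other region's median; the
  two-sided test plus the median ordering encodes direction without
  assuming sidedness. Rank-sum (not signed-rank) because regions are
  independent groups.
* BH adjustment is monotone and never below the raw p, but it is *not*
  idempotent in general — re-adjusting an adjusted vector can inflate
  it — so adjusted p-values are never fed back through the correction.

Null-calibration suites (type-I error ≈ 5% for Pearson, Kruskal–Wallis,
rank-sum, the slope-z test and the region F test) run as seeded
stochastic tests with 3× binomial-standard-error tolerances.

## Pipeline

Stages run in a fixed order (quantify → taxonomy → coverage → climatology
→ statistics), communicate only through TSV files, skip gracefully when
optional inputs are absent, and leave a `<stage>.partial` marker on
failure. A manifest records input SHA-256 checksums, package version,
seed and per-stage row counts. All floats are written at 12 significant
digits, which makes reruns under a fixed seed byte-identical and profile
round-trips exact at that precision.

## Problem sizes

Validation uses communities of 40–500 genomes and 6–200 samples at
10⁵–10⁶ reads per sample, 500-sequence alignments, 40–64-leaf reference
trees with up to 30 planted queries, interval instances up to a few
thousand bases (checked base-by-base against a counting oracle), and
1000-replicate calibration loops — sizes at which every oracle is exact
or its Monte-Carlo error is controlled, and the full suite plus the
acceptance script run in about a minute.

## Known limitations

* Prevalence is relative to recA-carrying organisms; genome-size and
  completeness corrections, absolute cell densities, and viruses/archaea
  lacking the marker set are out of scope.
* The classifier is only as good as the reference tree's coverage;
  support values are distances, not probabilities.
* The simulator does not emulate realistic read error profiles,
  taxonomic abundance distributions (e.g. log-normal rank curves), or
  spatial autocorrelation between stations; correlations and p-values on
  synthetic data are calibrated under independence.
* Climatology matching does no interpolation (nearest node only) and
  reads TSV grids, not native NetCDF distributions.
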