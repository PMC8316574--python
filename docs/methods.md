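# Methods

This note documents the statistical procedures implemented in
`phosphoprio`, the assumptions behind them, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical conventions that matter for reproducing results.

## Differential phosphorylation calling

**Model.** Each phosphoisoform carries a vector of light/heavy isotope
ratios per genotype, one per technical replicate. Ratios are strictly
positive and their measurement error is multiplicative, so all location
comparisons are made on medians and all spread estimates on log₂ ratios.
Ratios are first normalized per technical replicate: the ratio vector of
one MS run is divided by its own median, removing per-run mixing-ratio
offsets and centering each run at 1.

**Control assembly.** An isoform is eligible when it has at least
`min_quant` (default 3) measurements in the test genotype. If the control
genotype itself has ≥ 3 measurements, those form the control ("control-1");
with only 1–2 control measurements, the control is the pool of the control
plus auxiliary genotypes ("control-2", plain pooling, unweighted). Zero
control measurements excludes the isoform explicitly — never silently —
because the excluded set matters for enrichment backgrounds.

**Spread estimation.** The population of log₂ fold changes
log₂(median test / median control) over all eligible isoforms is
summarized by its median and NIQ = 0.7413·(Q₃ − Q₁). The constant is
1/(2·z₀.₇₅), making NIQ a consistent, outlier-resistant estimate of the
standard deviation under normality; the test suite verifies convergence to
σ within 1% on 10⁶ Gaussian draws. Quantiles use linear interpolation
between order statistics (the numpy default); the convention is recorded
in run metadata since quartile conventions differ across software.

**Decision rule.** An isoform is called regulated when either
(a) its log₂FC lies outside median ± 1.5·NIQ *and* the one-tailed Wilcoxon
rank-sum p (in the matching direction) is < α, or (b) outside
median ± 1.0·NIQ with two-tailed p < α (α default 0.05). The two tiers
trade effect-size and significance evidence off against each other;
either suffices. Wilcoxon p-values are exact (by the null permutation
distribution of the rank sum) for pooled samples up to 20 observations
without ties, and otherwise use the normal approximation with tie and
continuity corrections. Exactness matters here because typical designs
have 3–6 replicates per arm, far outside asymptotic territory.

**Isoform → site expansion.** A site is regulated if any isoform
containing it is regulated. When different isoforms pull the same site in
opposite directions, the site is reported once per direction with a
`conflict` flag on both rows, and the run manifest warns; collapsing the
conflict silently would hide a genuinely ambiguous measurement.

## Conservation score

RCS = MBL × Np/N. The conserved set at a site's alignment column contains
the species whose residue is phosphoacceptor-equivalent to the site
residue; by default serine and threonine form one equivalence class while
tyrosine matches only itself, because S/T and Y kinases are distinct
enzyme families (`--strict-residue` switches to exact-residue matching).
MBL is the largest patristic distance between any two conserved species on
the species tree, with all tied endpoint pairs reported. N is defined as
the number of *analysis* species — species contributing a row to the
alignment — inside the smallest clade (MRCA subtree) spanning the
conserved set, and Np the conserved count within it. The clade definition
makes N well defined even when several pairs tie for MBL; species without
an ortholog contribute to neither count, so a missing genome neither
inflates nor deflates the ratio. Tree branch lengths are used exactly as
given (no re-scaling or ultrametricization). A site conserved only in the
reference species has MBL = 0 and hence RCS = 0.

## Feature encoding

Eight numeric columns per site: UKF count (distinct kinase families with a
predicted edge to the site; set semantics, so duplicate prediction rows do
not inflate the count), RCS, IDM count (sum of interaction-partner counts
over the domains containing the site, 0 outside any domain; summation over
overlapping domains is the default, `max` available by config), ASC flag
(any acetylation site within ±15 residues on the same protein, inclusive),
RSA in [0,1], and the three secondary-structure probabilities. No scaling
or standardization is applied before regression: coefficients stay
directly interpretable on the raw encodings, and the fitted model is
portable between runs.

Missing value-type annotations (RCS, RSA, SS) follow an explicit policy:
`impute-zero` (default; SS imputes as pure coil) with a logged count, or
`error`, which names the first offending site. Count-type features have a
natural zero and are never "missing".

## Scorer training and normalization

The positive class (curated functional sites) is small, so training uses a
benchmark protocol: negatives are drawn without replacement from the
non-positive pool at `ratio` negatives per positive (default 5), ten
independent benchmark sets are built, and each is evaluated by stratified
10-fold cross-validation. The CV AUC is computed on the pooled out-of-fold
scores rather than averaged per fold — with ~12 positives per fold a
per-fold AUC would be extremely noisy, while the pooled estimate is always
well defined. The final model is refit on the full benchmark with the
highest CV AUC; exact ties break to the lowest benchmark index with a
warning.

The fit is a binary logistic regression with an L2 ridge of 10⁻⁸ — small
enough to leave coefficients at their maximum-likelihood values on
non-separable data, but sufficient to keep separable toy data finite. The
solver is exact Newton (`newton-cholesky`): with a near-zero ridge the
objective is extremely ill-conditioned along directions collinear with the
intercept, where quasi-Newton methods stall at a non-optimal point of the
flat manifold; exact Newton reaches the penalized optimum (verified by the
closed-form intercept-only fit, ln(n₊/n₋), to 10⁻⁵).

AUC is computed by the rank statistic, AUC = P(s₊ > s₋) + ½P(tie), and is
checked against O(n²) pairwise counting. The 95% CI of the selected
model's CV AUC uses a stratified (within-class) percentile bootstrap,
default 10,000 replicates; stratification preserves class counts so every
replicate's AUC is defined.

Raw scores are mapped to [0, 1] with fences at Q₁ − 3·IQ and Q₃ + 3·IQ:
scores beyond a fence clip to 0/1, in-fence scores rescale linearly
between the extreme in-fence scores S_min and S_max. The 3·IQ fence keeps
a handful of extreme scores from compressing the informative range of the
map. If all in-fence scores are equal the map returns 0.5 with a warning.

Prioritization takes the smallest set of at least ⌈fraction·n⌉ sites such
that no excluded site outscores an included one; ties at the cutoff are
all included (logged). The terminal artifact is the intersection of this
top-scoring set with the regulated sites, with direction and normalized
score attached.

## Enrichment statistics

Kinase and pathway enrichment use the one-sided hypergeometric tail
p = Σ_{m'=m}^{min(n,M)} C(M,m')·C(N−M,n−m')/C(N,n) together with
E-ratio = (m/M)/(n/N); a unit is flagged when p < α and E-ratio > 1. The
tail's upper limit is min(n, M) — terms beyond M are zero, so this is
numerically identical to summing to n while avoiding invalid binomials.
The computation runs in log space (scipy's hypergeometric survival
function) and is verified against exhaustive draw enumeration for N ≤ 12.
No multiple-testing correction is applied by default, since the flagging
rule is a per-unit screen; a Benjamini–Hochberg option exists behind a
flag. The kinase background is all identified phosphosites (configurable),
and each direction of regulation is tested separately.

Score-set enrichment (e.g. per-gene tissue-expression scores) uses a
two-tailed Z-test of a category's mean against the population mean and
standard deviation of all scored items (members included); with small
categories this is a deliberate large-population approximation, not a
t-test.

## Synthetic data

Generators are pure functions of (config, seed) built on numpy's
`default_rng`; identical inputs give identical outputs, and the pipeline's
manifest hashes are byte-stable across runs.

* **Ratios** — log-normal multiplicative noise (natural-log sd default
  0.1) around 1, with regulated isoforms' test-genotype location
  multiplied or divided by the planted fold (default 2.0, half hyper/half
  hypo, default 10% of 500 isoforms, 4 replicates per genotype). A fold of
  1 plants nothing, so the truth table is all-"none" by construction.
* **Benchmarks** — the default generative model is logistic (iid standard
  normal features, labels Bernoulli with known coefficients) so
  coefficient recovery is well posed; a Gaussian-shift mode (positives
  N(d,1) vs negatives N(0,1)) provides the analytic AUC Φ(d/√2) for
  calibration checks.
* **Trees/MSAs** — random binary topologies by sequential pair-joining
  with uniform branch lengths; alignments realize a prescribed
  conserved-species pattern exactly (phosphoacceptor where conserved,
  alanine where not), so conservation scores can be hand-computed from
  the pattern.
* **Annotations** — each kinase receives a fixed number of site edges;
  one planted kinase draws edges from the regulated set with probability
  target-E-ratio × M/N, giving it the configured expected enrichment
  while all other kinases stay null.
* **Full fixture** — 200 sites on 40 random proteins by default, with 30
  designated functional sites whose annotations come from moderately
  shifted distributions (kinase-edge rate 2.0 vs 0.8, conserved fraction
  0.55 vs 0.30, acetylation co-occurrence 0.35 vs 0.15, RSA Beta(3,3) vs
  Beta(2,4), mildly helix-shifted SS). The shifts were set once to produce
  a benchmark that is separable but not trivially so (cross-validated AUC
  typically 0.80–0.93 across seeds), which is the regime where model
  selection and normalization actually do work. Half of the planted
  regulated isoforms are drawn from the functional sites so that the
  prioritized and regulated sets genuinely overlap; the planted kinase
  concentrates on hypo-regulated sites, and its edge count is scaled to a
  quarter of the fixture (the enrichment-power defaults of the standalone
  generator — 200 edges against a 2,000-site background — would span the
  whole fixture and pin the E-ratio to 1).

What the generator does **not** emulate: real amino-acid composition or
motif structure, real kinome topology or edge sparsity, peptide-level
missingness patterns, batch effects beyond the per-replicate median
offset, and correlated features (all feature channels are conditionally
independent given the class). Passing tests therefore demonstrate that the
statistics are implemented correctly and have their nominal operating
characteristics under the stated generative models — not that the scorer's
field performance on real proteomes matches any particular number.

## Numerical conventions and degenerate inputs

* Coordinates 1-based inclusive everywhere; conversion to 0-based only at
  array boundaries (alignment columns are documented as 0-based).
* Quantiles: linear interpolation; affects Q₁/Q₃ at small n.
* Sorting before sampling keeps negative-pool draws independent of input
  row order; stable mergesort is used wherever ranked output is written.
* Exact Wilcoxon threshold: pooled n ≤ 20 and tie-free; ties always force
  the corrected normal approximation.
* Empty regulated sets propagate as empty (not failing) tables through
  prioritization and enrichment.
* Floating-point ties in MBL are grouped within 10⁻¹².

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline on 200-site
fixtures, the Gaussian-benchmark calibration at 5,000 per class,
coefficient recovery at 20,000 samples, caller power/size at 500 isoforms,
enrichment power at a 2,000-site background with 100–200 replicates, and
bootstrap coverage with 2,000 resamples — sizes at which every estimate's
Monte-Carlo error is comfortably inside the asserted tolerance.

## Known limitations

* The kinase→family mapping of edge tables is the caller's responsibility;
  edges arriving at kinase granularity will overcount families unless a
  map is supplied.
* Conservation requires one MSA per protein keyed by accession; sites on
  proteins without an alignment fall under the missing-feature policy.
* The Z-test population includes category members, slightly diluting
  strong categories; excluding members is a possible alternative the
  interface does not currently expose.
* Identifier mapping between annotation releases is out of scope:
  accessions are opaque strings and must match across input tables.
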