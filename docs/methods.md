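# Methods

This note documents the models, numerical choices and known limitations of
`poolscan`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The CMH test and its dialect choices

Each tested site contributes K 2×2 tables (allele × condition), one per
replicate pair; the statistic is the classical Mantel–Haenszel chi-square
with 1 df,

X² = (|Σₖ(aₖ − Eₖ)| − c)² / ΣₖVₖ,  Eₖ = r₁ₖc₁ₖ/nₖ,  Vₖ = r₁ₖr₂ₖc₁ₖc₂ₖ/(nₖ²(nₖ−1)).

Choices worth knowing:

* **Continuity correction** (c = ½) is ON by default, matching the common
  default of the reference R implementation that PoPoolation2 delegates
  to; it is configurable because the original tooling's setting is not
  documented.  When |Σ(aₖ−Eₖ)| < ½ the corrected numerator is clamped at
  zero (some implementations square the negative remainder instead; the
  clamp keeps the statistic monotone near the null).
* **Degenerate strata** (a zero row or column margin, or nₖ ≤ 1) carry no
  information and are skipped; if *all* strata are degenerate the site is
  reported at p = 1 with a warning rather than an exception.
* **K = 1** reduces to the 2×2 chi-square up to the exact factor
  (n−1)/n — the Mantel–Haenszel variance uses n−1 where Pearson uses n.
  The unit tests assert this identity rather than approximate agreement.
* p-values are floored at 1e-300 before −log10 so Manhattan output never
  contains infinities.
* Replicate pairing for strata is identity-ordered (replicate i vs.
  replicate i) by default; replicates are exchangeable and an explicit
  pairing can be supplied.

## The empirical drift null

Replicate populations within one regime share a selection environment, so
CMH tests between them (default: the first two replicates of each regime,
pooled as K = 3 strata — one per regime — into a single test per site)
sample the p-value distribution attainable from drift plus sequencing
noise alone.  Significance thresholds for between-regime scans are the
q = 1e-5 and q = 1e-6 lower quantiles of this distribution ("0.001%" and
"0.0001%" percentiles; the two readings "conservative" and "very
conservative").  Quantiles are type-1 order statistics (inverted ECDF), so
a threshold is always an element of the stored vector; a request below the
1/N resolution resolves to the minimum with a warning.  Selection uses a
strict inequality (p < threshold), giving the calibration-by-construction
property that a threshold applied to its own source selects ⌊qN⌋ or ⌈qN⌉
sites (up to ties — CMH p-values on integer tables are discrete).

Two design points were genuinely open:

* whether the three regimes' replicate pairs form strata of **one** pooled
  test or three separate tests whose p-vectors are concatenated — both are
  implemented (`pooled=` flag), pooled is the default;
* whether thresholds are genome-wide or per-chromosome — genome-wide is
  the default (one pooled p-vector), a per-chromosome option exists and is
  rejected at configuration time when combined with the non-pooled null.

**Drift p-values are not uniform, by design of the problem.**  After t
generations at effective size Ne, drift adds variance ≈ p(1−p)·t/(2Ne) per
pool on top of binomial sampling variance p(1−p)/coverage.  At the default
study conditions (Ne = 500, t = 20, coverage 40) these are comparable
(0.020 vs. 0.025 per unit p(1−p)), inflating the chi-square statistic by a
factor ≈ 1.8 and skewing p-values low (Kolmogorov–Smirnov distance from
uniform ≈ 0.09–0.14 at 10,000 sites, depending on the correction).  This
is precisely why an empirical threshold is used instead of a nominal
cutoff, and the package validates its chi-square calibration on the null
the test actually assumes — two pools sequenced from identical
frequencies — where the KS distance is < 0.01.

## The Wright–Fisher generator

Per regime and replicate: deterministic additive (genic) selection update
p′ = p(1+s)/(1+sp) at selected sites, then binomial drift over 2·Ne
gametes, for `generations` rounds; fixation is absorbing.  Pooled
sequencing draws a Poisson(coverage) depth (or fixed depth on request) and
splits reads binomially by the true frequency into the reference ("A") and
alternate ("T") sync slots — an arbitrary but documented fixture
convention; downstream analysis collapses sites to the two most frequent
alleles anyway.

Parameter defaults are the modeled study's conditions where stated — 3
regimes (C, PF, UF) × 3 replicates, 20 generations, coverage 40 — and
field-realistic choices where not:

* **Ne = 500**: the census size is only bounded below (">500 flies"); Ne
  is set to that bound and is configurable.
* **Base spectrum Beta(2, 2)**: strictly polymorphic, symmetric,
  boundary-avoiding; a point-mass and a uniform spectrum exist for exact
  tests.  (A neutral site-frequency spectrum would pile mass near the
  boundaries; that realism is deliberately traded for stable polymorphism
  over 20 generations at small Ne.)
* **Selection s = 0.1 at 5% of sites in UF only**: the real selection
  strengths are unknown; these values give partial, not saturated,
  recovery, which is what parameter-recovery tests need.  These are
  placeholders for recovery experiments, not estimates of the experiment.
* **Proteome**: log-abundance = baseline N(10, 1) + regime effect + noise
  N(0, 0.1); 34 of 1319 proteins respond (effect 0.25 log-units, random
  sign) in the UF regime; detections drop independently at rate 0.18,
  chosen so the closed-form retention probability of the 2-of-3-in-every-
  regime filter reproduces the study's detection scale (~1009 of 1319
  expected retained vs. the reported 1001).

All randomness flows from the single configured seed (replicates get
independent spawned streams), so identical configurations produce
byte-identical fixture files.

What the generator does **not** model — and hence what passing tests do
not show about real data: linkage and hitchhiking (sites are independent;
the real experiment's significant SNPs are explicitly linked), sequencing
error and mapping bias, demographic change during the experiment, indel
artifacts, and regime-specific lab adaptation shared across regimes.

## Downsampling and biallelic reduction

The "fraction" downsampling rescales each sample's six counts to sum
exactly to the target using largest-remainder (Hamilton) rounding —
deterministic and sum-exact; the original Perl tool's rounding is
unspecified, so this is a documented dialect.  Sites with any sample below
the target or above the maximum depth are dropped whole.  Biallelic
collapse keeps the two alleles with the largest counts pooled across all
samples (never N/deletion; ties break alphabetically) and flags sites with
pooled minor count < 2 (configurable) as monomorphic.

## Gene-wise aggregation

SNPs are assigned to every gene interval containing them (interval-tree
query; 1-based inclusive coordinates internally, BED converted on read).
A gene's score is the plain arithmetic mean of its SNPs' raw p-values;
genes qualify with ≥ 20 SNPs by default.  The published description is
ambiguous between "more than 20" and "20 or more"; the inclusive reading
is the default and a strict flag exposes the other.  The gene-level
threshold is the q = 1e-5 lower quantile of drift-comparison gene scores —
the source text and its table caption disagree on this quantile's
definition, so q is a required, logged parameter rather than a constant.

## Δdistance randomization

Distance is 0 inside a gene, else base pairs to the nearer interval edge
(midpoint distance is an option).  Random gene sets are drawn genome-wide,
uniformly without replacement, size-matched to the focal set (a
chromosome-stratified draw is an option; gene length distributions are
*not* matched).  The 95% interval is the 2.5/97.5 empirical percentile of
the Δ vector over `n_random` sets (default 10,000).  SNPs on chromosomes
where a given set has no gene are excluded from that set's mean, with the
genome-wide mean taken over remaining SNPs.

## Proteomics pipeline

Tests run on log abundances (iTRAQ reporter ratios are multiplicative);
fold changes are reported on the linear scale as mean(X)/mean(Y) for a
contrast labeled "X-Y".  The omnibus test is the unbalanced one-way
fixed-effects ANOVA with undetected cells excluded; a protein with fewer
than two observed regimes or no residual df gets a missing p-value, and an
all-constant protein is a null fit (F = 0, p = 1).  The pairwise contrast
is the equal-variance two-group test (identical to the two-level ANOVA;
the unit tests assert F = t²).  Significance is p ≤ 0.05 **inclusive** —
the published table marks boundary values as significant, which fixes a
convention the text leaves open.  No multiple-testing correction is
applied by default, matching the raw-p workflow being modeled; a
Benjamini–Hochberg option is provided and labeled as an extension.

The packaged `data/regime_contrasts.tsv` holds the published per-contrast
fold changes and p-values of the 34 regime-responsive proteins at printed
(2-decimal) precision; applying the inclusive rule reproduces the
published set sizes and intersections exactly, which the acceptance suite
asserts.

## Problem sizes and determinism of the validation experiments

The validation experiments (`poolscan.experiments`) use 10,000 polymorphic
sites, 1,000 random tables for the reference-implementation comparison,
100 fixture repetitions × 300 random sets for the Δdistance coverage, and
500 shuffles × 30 bins for the overlap reference — sizes chosen to make
the stochastic tolerances meaningful while keeping a full run in seconds.
Every experiment takes an explicit seed; the pipeline (`run_pipeline`)
writes a configuration hash into every output and produces byte-identical
summaries for identical configurations.

## Known limitations

* Independent sites only; no LD-aware inference or explicit s-estimation.
* Exact (network-algorithm) conditional CMH p-values are out of scope;
  the chi-square approximation is used throughout.
* The proteomics stage consumes an already bias-corrected quantification
  table; peptide-level processing is upstream.
* mpileup parsing and indel-region filtering are upstream of the sync
  stage and not implemented.
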