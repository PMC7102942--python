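# Methods

This note records the models the package implements, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the problem sizes used by the validation experiments.

## Biophysical affinity model

Binding affinity is an occupancy sum: every W-mer placement of a motif,
on both strands, contributes `p_i = R0·e^{−E_i}/(1 + R0·e^{−E_i})` with
mismatch energy `E_i = Σ_j (1/λ)·ln(c_max,j / c_base,j)`. Parameters are
fixed at the model's published defaults, `λ = 0.7` and
`ln R0 = 0.584·W − 5.66`, and are exposed as function arguments.
Pseudocount is deliberately zero because the inputs are frequency (not
count) matrices: a zero frequency is treated as a hard incompatibility
and voids the placement. Non-ACGT characters likewise void every
placement covering them (counted and logged, not an error). Sequences
shorter than the motif score 0. A vectorized implementation
(`trap_affinity`) is verified against a brute-force double loop
(`trap_affinity_naive`) to 1e-9 relative tolerance; the naive version is
kept in the package as the reference oracle.

## Background normalization

Raw occupancy sums are not comparable across motifs, so each value is
converted to the probability `A` of seeing an equal-or-higher affinity
in background sequence. Background sequences are CRMs *not* bound by the
motif's TF, cut centrally or extended symmetrically from reference
flanks to a standard length (40, 100, 200, 250, 300, 400, 500, 800,
1000, 2000, 3000 bp; a CRM is matched to its nearest standard length,
ties toward the smaller). A three-parameter generalized extreme value
law is fitted per motif and length, and `A` is its upper-tail survival
probability.

Three numerical choices matter here and were made once, on calibration
evidence from background-sequence experiments:

1. **Log scale.** The GEV is fitted to natural-log affinities. Raw
   occupancy sums span orders of magnitude with extreme right skew; on
   the raw scale the maximum-likelihood fit misses the upper-tail
   quantiles by several percent, on the log scale it does not.
2. **Tail-censored likelihood.** Observations below the 85% empirical
   quantile enter the likelihood only through their total mass below
   that point. Only the upper tail of the fit is ever consumed
   (`A ≤ 0.1` is the region of interest), and censoring removes the
   influence of bulk lack-of-fit on the tail. With this estimator the
   empirical fraction of background scores with `A < q` is within one
   to two points of `q` for `q ∈ {0.01, 0.05, 0.1}` across motifs and
   lengths (the acceptance suite re-measures this at n = 5000 per
   length). The full-data MLE supplies the starting point. The trade-off
   is a shape estimate with larger sampling error than the uncensored
   MLE; the tail probabilities, which are what the pipeline uses, are
   recovered more accurately.
3. **Shape constrained to −0.5 ≤ c ≤ 0** (scipy's sign convention;
   Gumbel up to moderately Fréchet). An occupancy sum has no finite
   upper bound, yet an unconstrained fit on a few hundred background
   sequences frequently lands in the Weibull domain and places a finite
   endpoint *below* the scores of genuinely strong sites, collapsing
   their `A` to an exact 0 — which the zero-substitution rule (below)
   then converts into a spurious `log FCA = 0`. The opposite extreme, a
   very heavy log-scale tail, is small-sample noise that washes strong
   sites into the bulk. Both are excluded. With this constraint `A` is
   positive for every finite score, and the zero-substitution rule is
   reserved for genuine floating-point underflow.

Each fit requires at least 50 background sequences (the pipeline default
tops the pool up to 300 with peak-free genomic segments when a TF is
bound almost everywhere).

## Log fold change in affinity (log FCA)

For every CRM × TF with at least one motif and `A < 0.1` on the
reference individual's highest-affinity allele, each observed haplotype
receives `log10(A_ALT) − log10(min A_ref)` per motif, median-pooled
across the TF's motifs. Exact zeros in either argument are replaced by
the motif's lowest non-zero `A` across all CRMs, computed in a first
pass over the whole atlas before any log FCA is emitted.

The printed formula gives *positive* values for affinity-reducing
haplotypes, while the downstream classification rule treats reduced
affinity as *negative*. The package resolves this by storing one
canonical signed score, `s = −(printed log FCA)`, so affinity-reducing
haplotypes are negative everywhere downstream; `sign_convention`
switches the atlas back to the printed orientation if needed. Selection
of "variable" CRMs uses `max |s| > 0.3` over haplotypes.

## Association testing

Expression input is a gene × individual matrix of normalized residuals
plus raw counts. Genes with zero counts in strictly more than 50% of
samples are removed; retained residual vectors are rank-transformed to
standard normal (`Φ⁻¹((rank − 0.5)/n)`, average ranks on ties).

**Thresholded approach.** Haplotypes of each affinity variant are
classified around a dynamic threshold `log FCA₀ = 0.8 × P85({s ≤ −0.3})`
(linear-interpolation percentile): low if `s ≤ log FCA₀`; high if
`s > log FCA₀/4` when that bound exceeds −0.3 and `s > −0.3` otherwise;
the remainder unclassified. Variants with no haplotype at or below −0.3
are dropped. Individuals carrying an unclassified haplotype are excluded
from every model containing that variant (complete-case). Dosage is the
number of low-affinity alleles. Per gene, predictor columns in
near-perfect correlation (|Pearson r| > 0.99, read as the only
interpretation under which collapsing prevents collinearity) are merged
into their leftmost-in-genome representative; an OLS model with
intercept is fitted, the gene-level p is the ANOVA F-test against the
intercept-only model, Benjamini–Hochberg FDR is applied across genes
(10%), and per-variant two-sided coefficient t-tests (unadjusted,
p < 0.05) name the driving variants within significant genes.

**Threshold-free approach.** The predictor is the per-individual sum of
canonical log FCA over both haplotypes, for every linked variant with
any non-zero change. The gene-level screen is the same OLS ANOVA + BH
FDR. For significant genes with ≥2 predictors, the per-variant calls
come from the elastic-net path with quadratic penalty weight λ₂ = 0.5,
computed as a lasso path (LARS) on ridge-augmented data (standardized
columns, `√λ₂·I` rows appended, zeros appended to the response). At
each knot where a predictor enters, the covariance statistic

    T = (1 + λ₂) · ( ⟨y_a, X_a β(λ_next)⟩ − ⟨y_a, X_A β̃_A(λ_next)⟩ ) / σ̂²

is computed, with `β̃_A` the path refitted on the previously active set
and interpolated at the next knot, and `σ̂²` the residual variance of
the full OLS fit (n > K + 1 required; a known-variance argument exists
for calibration studies). The `(1 + λ₂)` factor undoes naive
elastic-net shrinkage, making T equal to the lasso's
`λ_k(λ_k − λ_{k+1})` statistic in orthogonal designs and preserving its
Exp(1) null reference, which is asymptotic in the number of predictors
(the calibration experiment uses 50). Predictors entering with
`p = e^{−T} < 0.05` and still active at the end of the path are
reported. Genes with a single predictor fall back to the OLS t-test.

## Target linking

Promoter baits annotated with more than one gene's TSS (or none) are
excluded. Distal links require ≥1 bp overlap between a CRM and the
other-end fragment of an interaction with score ≥ 5 whose bait
survived filtering; proximal links require ≥1 bp overlap with the
half-open window `[m − 9000, m + 9000)` around the bait-fragment
midpoint `m = ⌊(start+end)/2⌋`. All coordinates are 0-based half-open;
touching intervals do not overlap. A (CRM, gene) pair linked both ways
is tested once, labelled proximal.

## Enrichment in accessibility QTLs

For each CRM, every SNP's alternative allele is substituted alone into
the reference best haplotype and the pooled |log FCA| recomputed; the
*driver SNP* is the arg-max (ties to the lower coordinate) across the
CRM's retained TFs. For each effect threshold, the test set (driver
effect ≥ t, driver MAF ≥ 0.05) is overlapped (≥1 bp) with 100 bp
differential windows, and B control sets of equal size are sampled from
the remaining CRMs matching the test set's driver-MAF histogram in 0.05
bins (without replacement within a draw). The empirical p-value
`(1 + #{control ≥ observed})/(B + 1)` is never zero. The reference
distribution is well calibrated only when the control pool is several
times the test set — direct simulation of the scheme shows the type-I
rate doubling at a 1:3 test:pool ratio — so the validation fixtures keep
the test fraction near 10–25% of CRMs.

## Colocalization

Per SNP and trait, the log approximate Bayes factor is
`½(log(1 − r) + r·z²)` with `z = β/se` and
`r = sd₀²/(sd₀² + se²)`; the prior effect SD is the quantitative-trait
default 0.15 (configurable). Per-SNP log ABFs combine by log-sum-exp
into the likelihoods of the five hypotheses (no association; trait 1
only; trait 2 only; two distinct causal variants; one shared causal
variant) under priors `p1 = p2 = 1e-4`, `p12 = 1e-5`. Secondary signals
are handled by residualizing the trait on the lead variants of the other
signals before recomputing summaries. Simulations with both traits
measured on the same individuals show the shared-variant posterior is
insensitive to residual correlation up to 0.5, supporting use on
proximal/distal expression pairs from one cohort. The decision threshold
for declaring a shared signal is a user parameter; none is endorsed.
The fine-mapping prior on the number of causal variants per region,
Bin(n, 2/n), has expectation exactly 2 for any n ≥ 2; only this identity
is embodied (stochastic-search fine mapping itself is out of scope).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not read-level data:

* motifs: one or two frequency matrices per TF, widths 8–12, about a
  third of columns carrying an exact zero (to exercise the zero
  pseudocount), the rest Dirichlet-drawn at moderate information
  content like curated frequency matrices;
* a random genome seeded with degraded motif copies ("echoes", one per
  1.5 kb, 2–4 mismatches): real genomic background is dense in partial
  motif matches, and without them background affinity tails are so
  light that normalizing a strong site is ill-posed; at least two
  mismatches keep echoes from rivalling true sites;
* CRM regions of 150–260 bp, each bound by 1–3 TFs with an embedded
  consensus instance per bound TF and ChIP peaks covering the region
  (one TF gets two replicate peak sets to exercise replicate merging);
  regions carrying planted effects are compact (150–180 bp) single-TF
  sites so the planted variant's effect on that TF's occupancy sum is
  unambiguous;
* phased biallelic variants with empirical MAF inside the configured
  range (default 0.10–0.45; the panel convention is MAF ≥ 5%),
  including at least one indel; disrupting variants substitute the
  zero-frequency base at a motif's most informative column, and the
  reference individual is kept homozygous reference there;
* a fragment map, single- and multi-TSS baits, interaction scores
  straddling the significance cut-off of 5, and planted links wiring
  each planted (gene, CRM, TF) either through a ≥9 kb-distant
  interacting fragment ("distal") or through the CRM's own fragment
  ("proximal"); null genes are wired to real CRMs so they are tested;
* expression generated by inverting the association model:
  `residual = β · (summed log FCA predictor) + N(0, noise_sd²)`, null
  genes pure noise, counts a monotone transform of residuals with a
  configurable fraction of genes forced to >50% zeros.

Defaults mirror the study conditions where stated (cohort size 359,
MAF ≥ 5%, interaction cut-off 5, 10% FDR); everything is configurable
and a single seed fixes every output byte.

What passing tests on these cohorts does *not* show: robustness to
linkage disequilibrium beyond shared-haplotype co-placement, population
structure, unmodelled confounding in expression (residuals are taken as
already adjusted), read-level noise, or motif libraries whose PWMs
mismatch the true binding preference.

## Validation problem sizes

The acceptance experiments (shared between `tests/test_acceptance.py`
and `scripts/acceptance.py`) use: 100 random (sequence, PWM) pairs for
the oracle check; 5000 background sequences × 2 motifs × lengths
{100, 200, 500} for GEV calibration; 1000 null genes (n = 200, K = 2)
for ANOVA type-I error and six all-null cohorts for the FDR check; 500
global-null elastic-net fits (n = 100, K = 50) for covariance-test
calibration; 20 cohorts of 200 individuals, 40 CRM regions and 6 planted
effects (noise SD 0.5) for recovery; one 220-CRM cohort with 100 null
label seeds (B = 199) and one 10× planted alternative (B = 1000) for
enrichment; 25 replicates of n = 500, 200-SNP regions per colocalization
scenario. These sizes were chosen to give stable pass/fail behaviour at
desk scale; consortium-scale counts (10⁵ CRMs, hundreds of donors,
thousands of genes) are outside what the synthetic conditions emulate.

## Known limitations

* The occupancy model is mononucleotide and additive; cooperativity,
  dinucleotide preferences and learned binding models are out of scope.
* GEV normalization is an approximation to the background score law;
  its calibration is verified only down to q = 0.01.
* The covariance test's Exp(1) reference is asymptotic in the predictor
  count; with very few predictors it is conservative.
* Conditioning-based multi-signal colocalization requires individual
  level data; summary-only conditioning is not implemented.
* The bait map assigns each TSS to the single fragment containing it;
  fragment-spanning promoters are not modelled.
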