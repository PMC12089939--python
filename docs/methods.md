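# Methods

## Overview

`drugrank` implements a genetics-led drug-repurposing analysis in five
stages: (1) per-method gene ranking and rank fusion, (2) Cauchy
aggregation of transcript-level rare-variant burden p-values, (3)
preranked gene-set enrichment against drug-class (ATC) and
mechanism-of-action gene sets, (4) a parallel transcriptomic
(differential-expression) arm through the same engine, and (5) a
rule-of-five clinical-tractability screen. A synthetic-data module
generates all inputs with known planted structure so every stage is
testable end to end.

## Rank fusion

Each gene-based method ranks its own gene universe by ascending
p-value; universes overlap only partially, so the fused summary must
tolerate missingness. For a gene with n non-missing ranks the raw
median is the median of those n ranks (a single available rank is
reported as-is) and the scaled median divides by n. The scaled median
is the primary statistic: it deliberately up-weights genes supported by
several independent lines of evidence, at the cost of being a
rank-value hybrid rather than a pure rank (values below 1 are
possible). The coefficient of variation (sample sd over mean of a
gene's ranks) is reported only for genes with at least five input
ranks — below that it is too noisy to be a useful stability diagnostic.

Ties are average-ranked by default (unbiased; rank sums per method stay
exactly n(n+1)/2, which the tests assert). An ordinal tie rule (ties
broken by gene symbol) is available when an exact permutation is needed
for reproducibility comparisons. Gene symbols are upper-cased and
trimmed before any join; duplicate (gene, method) pairs are rejected
rather than silently merged; genes with no ranks at all are dropped,
not assigned a worst rank.

**Expression re-weighting.** TWAS/SMR associations can reflect linkage
rather than a shared causal variant. Two plug-in schemes derive an
adjusted evidence stream: `coloc_weight` re-orders genes by
−log10(p) × colocalization posterior, and `heidi_demote` moves genes
failing the HEIDI heterogeneity test (p < 0.05 by default) behind all
passing genes, preserving within-group order. These are this package's
own schemes — the general shape (posterior-weighted demotion) follows
standard practice, and callers can supply either. Genes without
evidence values are treated as unadjusted (posterior 1 / HEIDI pass)
and flagged `adjusted=False`, so downstream consumers can distinguish
them. The adjusted ordering is re-encoded as pseudo p-values i/(n+1),
making the stream usable as one more method column in rank fusion.

## Cauchy (ACAT) aggregation

Transcript-level burden p-values within one gene are strongly dependent
(overlapping exons, shared carriers). The Cauchy combination statistic
T = Σ wᵢ tan(π(½ − pᵢ)) / Σ wᵢ is approximately standard Cauchy under
the null for *arbitrary* dependence, so the combined
p = ½ − arctan(T)/π does not inflate under covariance. Weights default
to equal. Inputs are clamped to [1e-15, 1 − 1e-15] to keep the tangent
finite; for T > 1e10 the tail form p ≈ 1/(πT) replaces the arctan
expression, which loses precision to cancellation there. The eight
ranked annotation masks (disruptive / damaging / + non-damaging
missense combinations at MAF < 0.01 and < 0.005) are fixed vocabulary;
synonymous variation is accepted as a diagnostic mask that is
aggregated on request but never ranked.

Calibration (asserted by the acceptance tests): with m = 5 independent
uniform inputs over 10,000 replicates the rejection rate at α = 0.05
stays within the 99% binomial band [0.045, 0.056]; with an
equicorrelated Gaussian copula at ρ = 0.5 it stays ≤ 0.07.

## Preranked enrichment

The engine is a from-scratch implementation of GSEA-preranked. Genes
are sorted by descending score with ties broken stably by gene symbol
(run-to-run byte-identical output). Walking the list, set members
increment the running sum by |score|^p normalized over members (p = 1,
the default weighted statistic) and non-members decrement by
1/(N − |S|); the ES is the deviation of maximum magnitude. When the
positive and negative extrema tie in magnitude exactly (common at
weight 0 on small lists), the extremum reached first along the list is
taken. Leading edge: members at or before the extremum for positive
ES, at or after it for negative ES.

**Orientation.** The scores fed to the engine are median rank values,
so the best genes (rank near 1) sit at the bottom of the descending
list and enrichment among them produces *negative* ES/NES. This is
deliberate and matches how the drug-class results are read: candidate
classes have NES < 0.

**Null and inference.** The permutation null draws uniformly random
gene subsets of each set's size (the appropriate scheme for preranked
input, where there are no sample labels to permute); sets of equal size
share one null sample for efficiency, and a single seed governs the
whole run. NES divides the ES by the mean same-sign null ES. The
empirical p is the one-sided same-sign exceedance; when no permutation
is as extreme the value 1/(2·n_perm) is reported with a
`p_below_floor` flag — the smallest resolvable nonzero p is 1/n_perm,
and a flagged sub-floor value preserves that convention without
claiming an exact zero. FDR q follows the GSEA ratio method per tail
(share of pooled same-sign null NES at least as extreme over the share
of observed same-sign NES at least as extreme, clipped to [0, 1]).
Two FWER columns are emitted: the permutation-max statistic (primary;
exceedance of the per-permutation most extreme same-sign NES across all
tested sets) and plain Bonferroni on the empirical p. Because the
empirical p is floored, the Bonferroni FWER can occasionally undershoot
the FDR q — a known quirk of this family of statistics. Evidence
tiers use FDR and the permutation-max FWER: strong when both < 0.05,
moderate when exactly one is.

The fast permutation path computes the ES from hit positions alone in
O(k log k) per subset (between hits the running sum decays linearly, so
extrema occur only just before and just after hits); unit tests pin it
against the full O(N) running sum and against an independent
brute-force oracle to 1e-12, and the observed-ES path is additionally
cross-checked against the GSEA reference implementation (gseapy) on a
small instance.

**A property worth knowing.** With p = 1 the hit increments are
proportional to |score|, i.e. to the rank values themselves. A set
whose members are nearly all well-ranked but contains one member with a
very large rank value gives that member most of the set's total hit
weight, which can pull the ES positive even though the rest of the set
sits at the favourable end. This is faithful weighted-GSEA behaviour
(verified against gseapy), not an artifact; it mainly matters when
scores span several orders of magnitude, as median rank values do.

## Transcriptomic arm

Differential-expression tables (gene, log fold change, p-value,
genetic-background label) are ranked per background by ascending
p-value — significance only; the fold change is carried for reporting —
and the rank value is the score, giving the same orientation as the
genetic arm. All enrichment parameters are forwarded unchanged so both
arms are directly comparable.

## Tractability

Molecular weight is computed from the molecular formula with
conventional IUPAC standard atomic weights; the tests allow ±0.05 Da
against database-annotated weights since mass tables differ slightly in
the last digit. Rule-of-five verdicts follow the conventional printed
inequalities — logP ≤ 5, MW strictly < 500 Da, acceptors ≤ 10, donors
≤ 5. logP is never computed (it is predictor-dependent) and must be
annotated. H-bond acceptor counts are annotations too; when absent the
classical N+O proxy is used and flagged approximate, because database
counting conventions differ from the atomic count (vemurafenib: N+O = 6
versus an annotated 4). Missing properties yield absent verdicts that
are excluded from the pass count, and missing BBB probabilities are
reported blank, never zero.

## Synthetic data

The generators emulate the statistical structure of the pipeline's real
inputs at the gene-statistic level; they do not simulate genotypes,
linkage disequilibrium or sequences.

* **Method p-values.** Null genes draw Uniform(0,1); signal genes draw
  Beta(a, 1) — the canonical monotone-density alternative for p-values,
  with a single effect-size knob a (default 0.05). Null entries are
  deleted per method with the missingness probability (default 0.3);
  signal genes are scored by every method by default, emulating
  well-characterized risk genes that all gene-based approaches capture.
  (Setting `signal_fully_observed=False` exposes signal genes to the
  same per-entry missingness; under the default weighted enrichment
  statistic a signal gene left with one or two mediocre ranks can then
  dominate a planted set's hit weight — see the property note above.)
* **Transcript p-values.** Equicorrelated Gaussian copula (shared gene
  factor; default ρ = 0.5, m = 5 transcripts) with uniform null
  margins; signal genes get Beta(a, 1) margins via the quantile
  transform u^(1/a), preserving the copula. Equicorrelation keeps the
  closed-form check tractable: pairwise Spearman is (6/π)·asin(ρ/2).
* **Drug universe.** Random drugs with grammar-valid ATC codes and
  random targets, plus one planted level-4 class (default `L01EC`, 40
  genes) whose targets overlap the signal genes by a configurable
  fraction (default 1.0; at 0.0 the planted class behaves as a null
  set).
* **Differential expression.** Per background, uniform p-values except
  planted perturbed genes in the planted background, which draw
  Beta(a, 1).

Default scale — 15,000 genes, 8 methods, 30% missingness, 100 signal
genes, a 40-gene planted class — mirrors the genome-wide gene-based
setting the pipeline is designed for. Everything is a pure function of
(scenario, fixed stream tag), so the same scenario regenerates
bit-identical outputs.

What passing tests on these data do and do not show: they establish
that the statistics are calibrated under the stated null models, that
planted signal of realistic strength is recovered, and that the
pipeline is deterministic; they do not establish robustness to
real-data features the generators omit — linkage-induced correlation
between neighbouring genes' statistics, non-equicorrelated transcript
dependence, annotation errors in drug-target maps, or selection effects
in which genes each method scores.

## Numerical and design choices

* Rank ties: average by default; ordinal fallback.
* Cauchy clamp ε = 1e-15; tail form beyond T = 1e10.
* ES extremum magnitude ties resolved to the first occurrence along the
  list; sort ties in scores broken by gene symbol.
* Zero-exceedance empirical p reported as 1/(2·n_perm), flagged.
* Null ES samples shared across sets of equal size; all randomness
  derives from one seed (per-stage fixed stream tags in the pipeline).
* Kendall's tau-b (tie-corrected) for NES-vector comparisons, Spearman
  for gene-rank vectors, both via scipy.
* Coefficient of variation uses the sample (n−1) standard deviation.
* Druggable-candidate annotation takes the best ceil(fraction·n) genes
  by scaled median before intersecting with the druggable set.

## Problem sizes used in the test and acceptance runs

Planted-recovery runs use the default scenario (15,000 genes, 8
methods, 1,000 permutations, 20 seeds); calibration checks use 10,000
replicates; the permutation-floor check uses a 2,000-gene list at
10,000 permutations; ES-oracle checks use 200 random instances with
N ≤ 50 and |S| ≤ 10 at weights 0 and 1. These sizes are the package's
own choices for routine verification; all scale linearly if enlarged.

## Known limitations

* The expression re-weighting schemes are documented stand-ins, not a
  reproduction of any published adjustment formula.
* The FWER based on the shared equal-size null is slightly
  anti-conservative when many tested sets have the same size (their
  null columns are identical, shrinking the effective family in the
  per-permutation max); FDR q is unaffected and is the primary
  flagging statistic.
* The weighted ES statistic's sensitivity to single large-score members
  (above) is inherited from the method, not corrected.
* Rule-of-five inputs rely on annotation quality; only molecular weight
  and the N+O proxy are computed from structure-independent data.
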