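# Methods

This note documents the models, numerical choices and known limitations
of methylquad, in the spirit of the methods documentation of packages
like statsmodels or scanpy.

## Differential testing

Features (genes, CpGs or gene-region means) are compared between cases
and controls with either Welch's t or the empirical-Bayes moderated t.
The moderated test pools information across features: per-feature pooled
variances `s²` (residual df `n₁+n₂−2`) are assumed to follow a scaled
inverse-chi-square prior with scale `s0²` and `d0` degrees of freedom;
`(d0, s0²)` are fitted by method of moments on `log s²` (digamma/trigamma
moments, trigamma inverted by Newton iteration), the posterior variance
is the convex combination `(d0·s0² + df·s²)/(d0+df)`, and the statistic is
referred to a t distribution with `d0+df` degrees of freedom. When the
observed spread of log-variances is no larger than expected under a
common variance, `d0 = ∞`: all features share `s0²` and the reference is
normal. Features with zero variance in both groups get `p = 1` when the
means agree and a floor p-value otherwise; p-values are clipped to
`(0, 1]`.

The effect size is `log2FC = log2(mean_case / mean_control)` for every
layer. For beta values this log-ratio convention is one of two defensible
readings of a "fold change of methylation"; the additive difference
Δβ = mean_case − mean_control is always reported alongside so users can
apply Δβ cutoffs instead. Direction calls use *strict* inequalities
(`p < 0.05`, `|log2FC| > 0.3` by default); boundary values are not called.
Raw p-values are used by default; Benjamini-Hochberg adjustment is
available behind a flag.

Calibration: on heteroscedastic normal data the moderated test's null
rejection rate at α = 0.05 is nominal (the acceptance suite measures it).
On bounded data such as uniform or logit-normal betas with 8 vs 8 samples
the test is mildly conservative (≈ 0.04), a property of applying
t-reference tests to short-tailed data, not of the implementation.

## Region aggregation and DMG calling

A CpG annotated to several (gene, region) pairs contributes to each of
them, matching 450K manifest semantics. The region-level methylation of a
(gene, region, sample) triple is the arithmetic mean beta of its CpGs;
regions are tested directly on these means (rather than combining per-CpG
statistics), because the region mean is the quantity of interest.
Single-CpG regions are eligible DMRs by default; a `min_cpgs` floor is
exposed. A gene is a DMG only if all of its DMRs share a direction;
mixed-direction genes are marked conflicted and excluded from DMG lists
and from the quadrant intersection.

## Quadrant integration

DEMGs = DEG ∩ DMG, partitioned by (DEG direction) × (DMG direction) into
up-hyper, up-hypo, down-hyper, down-hypo. The partition is exact: the
four counts always sum to the DEMG total, and swapping case/control maps
up-hyper↔down-hypo and up-hypo↔down-hyper. Overlap summaries report
percentages under three denominators (union, |A|, |B|) because the right
denominator is a presentation choice.

## Centromeric density

The "centromere" of a chromosome is the union of its p11.1 and q11.1
cytogenetic subbands; cytobands use the UCSC 0-based half-open dialect
and 1-based probe positions are converted at this boundary, so a DMC
exactly on a band start belongs to that band. Densities are counts per
megabase; display values are rounded half-up to two decimals while full
precision is retained. The pooled difference test is a reconstruction
(no canonical test exists for this table shape): under the null, DMCs
fall into the two compartments in proportion to pooled lengths; an exact
binomial test is used up to 500 total DMCs and a chi-square
goodness-of-fit test beyond.

## Module detection and hub scores

MCODE reimplementation: vertex weight = core number × density of the
highest k-core of the closed neighborhood; complexes grow outward from
the highest-weighted unassigned seed, admitting neighbors whose weight
exceeds `seed_weight × (1 − cutoff)` with cutoff 0.2; post-processing
keeps the 2-core (haircut); module score = density × node count, and
significant modules require score > 3 and ≥ 5 nodes. Top modules are
ordered by score, then size, then seed symbol.

The twelve hub scores follow the published cytoHubba definitions as a
documented reconstruction, computed on unweighted topology (edge weights
only gate loading): MCC sums `(|C|−1)!` over maximal cliques containing
the node (clique enumeration falls back to degree above a budget, with a
warning); MNC/DMNC use the largest connected component of the open
neighborhood (`DMNC = E/V^1.7`); EPC is the mean percolated-component
size over seeded random edge-retention rounds (default 1000 rounds at
retention 0.5); Closeness is the harmonic form (well defined on
disconnected graphs); EcCentricity is the reciprocal eccentricity within
the component; Radiality uses the component diameter; Betweenness and
Stress are standard shortest-path counts; BottleNeck counts
shortest-path trees in which the node's subtree exceeds a quarter of the
reachable nodes, with the tree parent chosen as the lexicographically
smallest shortest-path predecessor. That deterministic tie-break makes
BottleNeck reproducible but label-dependent when predecessors tie; the
other deterministic scores are exactly invariant under relabeling.

Aggregation: each algorithm's scores are ranked descending with average
ranks on ties; the comprehensive standard is the rank sum (scale-free
across heterogeneous score ranges), ascending, with ties broken by degree
then symbol. A score-sum alternative exists behind a flag.

## Over-representation analysis

Hypergeometric upper tail `P(X ≥ k)` for k list∩term genes with the term
intersected against the universe first. The default universe is the set
of genes on the expression array after probe collapsing; it is
config-exposed because ORA results are sensitive to it. Raw p < 0.05
filtering by default, BH optional.

## Validation statistics

Replicate Cq runs are averaged (discordance > 1 cycle is flagged).
Methylation fractions from enzyme-digestion qPCR are clamped to [0, 1]
with a logged warning when noise pushes the raw formula outside.
Digestion QC operationalizes "positive control near 1, negative near 0"
as ≥ 0.9 / ≤ 0.1 (configurable). Group comparison routes by Shapiro-Wilk
normality (α = 0.05) to Student's t or Mann-Whitney U; categorical tables
use chi-square, or Fisher's exact for 2×2 tables with an expected cell
below 5. Correlation routes the same way to Pearson or Spearman.
Stepwise regression is classic forward-backward OLS (entry p ≤ 0.05,
removal p ≥ 0.10) on z-scored variables, so coefficients are standardized
betas; collinear candidates are skipped via a condition-number guard, and
selection stops once the fit is essentially exact. ROC analysis reports
the empirical AUC (equal to the concordant-pair fraction), a DeLong
variance-based 95% CI and z-test against AUC = 0.5, and the
Youden-optimal cutoff (ties resolved to the lowest cutoff; score ≥ cutoff
predicts case). The combined predictor is the in-sample predicted
probability of an unpenalized two-covariate logistic model — no
cross-validation, mirroring how combined biomarker panels are typically
reported; in-sample the combined AUC cannot fall materially below the
better single predictor.

## Synthetic data

The generator mirrors the emulated study scale: 13 vs 11 expression
samples, 8 vs 8 methylation samples, 1000 genes across 22 autosomes,
each gene with 1–3 CpGs per region class, plus intergenic probes and a
toy cytoband table with 5 Mb pericentromeric blocks. Expression is
log-normal (baseline `N(8, 1)` on log2 scale, noise sd 0.5); betas are
logit-normal (sd 0.3 on the logit scale) around per-probe baselines so
that the planted case shift is additive on the beta scale — a choice that
matches how beta differences are thresholded. Planted genes (default 10
per quadrant, Δβ = 0.2, |log2FC| = 1; the recovery experiments use the
stronger Δβ = 0.25, |log2FC| = 1.2) shift both layers in all four
direction combinations on configurable regions (default TSS200 and
5′UTR); baselines of planted probes are drawn away from the boundaries so
baseline + Δβ always lies in (0, 1), otherwise configuration is rejected.
Cq tables are generated from the closed-form digestion models plus
Gaussian cycle noise (sd 0.05), in duplicate, capped at cycle 40.

All randomness flows through numpy PCG64 generators keyed off the
configured seed (separate streams per stage), so identical seeds give
bit-identical outputs on any platform.

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: probe cross-hybridization, batch and
chip effects, cell-composition confounding in whole-blood methylation,
correlated CpGs within a region, annotation errors, and realistic
PPI degree distributions (the planted module sits in sparse Erdős–Rényi
background noise).

## Problem sizes in the test and acceptance runs

The acceptance suite uses 200 random graphs of ≤ 8 nodes for the
brute-force score comparison, exact edge-subset enumeration (≤ 12 edges)
for the EPC expectation, 100 seeds for MCODE clique recovery, 20 seeds at
the full default simulation scale for quadrant recovery, 10 × 1000 null
features for type-I calibration, 1000 replicates for the two-group null,
100 seeds for the null AUC band, and every hypergeometric configuration
with a universe of ≤ 12 genes. These sizes give stable rates while
keeping the whole suite fast on a single core.

## Known limitations

- DMR calling is region-class-based, not a sliding-window/bump-hunting
  detector; it cannot find differential stretches that straddle region
  boundaries.
- The centromere-density test treats DMCs as independent points; spatial
  correlation of CpGs would make the p-value anti-conservative on real
  arrays.
- The hub-score definitions are reconstructions of the published
  descriptions; other implementations may differ in tie handling and in
  the treatment of disconnected graphs.
- Stepwise selection inherits the usual caveats (post-selection p-values
  are optimistic); it is provided for parity with common clinical
  workflows, not as a recommended inference procedure.
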