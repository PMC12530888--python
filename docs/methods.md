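# Methods

## Overview

`sfactivity` infers splicing-factor (SF) activity by asking how strongly a
factor's regulon — the set of exons or genes that respond to its
perturbation — is enriched at the extremes of a molecular signature. The
package covers the full workflow: signature construction, regulon inference,
rank-based enrichment, multi-network integration, linear calibration between
activity spaces, cross-cohort program classification, cross-regulation and
network-distance statistics, gene-set machinery, and a leave-one-out
benchmark. Every stage can be exercised on synthetic data with planted
ground truth.

## Signatures

Signatures are differences against a reference on the scale native to each
data type:

* **ΔPSI** (percent-spliced-in units, 0–100): case minus reference exon
  inclusion. Replicates are averaged on the raw PSI scale.
* **log₂FC**: expression is transformed to log₂(x+1) (TPM or CPM) *before*
  replicate averaging and subtraction.
* **Pseudo-bulk**: single-cell counts are summed per perturbation label,
  scaled to counts per million over all genes in the matrix (no gene
  filtering), and log₂(x+1)-transformed.

The reference aggregate is a per-feature median or mean; both per-sample
signatures (each case sample vs the aggregate) and per-condition signatures
(averaged case replicates vs the aggregate) are supported, because cohort
analyses use the former and perturbation time courses the latter. A
signature entry exists only when both sides have at least one observed
value; this mirrors the NA semantics of tidy PSI tables, where coverage
gaps are frequent.

## Regulon inference

A target enters a regulon iff its signature value is observed and
|value| ≥ threshold, with the threshold **inclusive** ("at least"):
15 ΔPSI units for exon networks, 1 log₂FC unit for gene networks. mor =
sign(value) ∈ {−1, +1}; likelihood = |value|, stored unnormalized
(normalization happens inside the enrichment engine). When several
conditions perturb the same factor within one dataset (e.g. knockdown and
knockout), the per-target entry with the largest likelihood wins — the
strongest observed evidence, and an order-independent rule. Networks from
different datasets are never merged; they are kept as named collections and
integrated at the activity level.

## Enrichment engine

The two-component rank-quantile formulation is given in the README. Choices
that matter numerically:

* Ties in ranks are averaged; sgn(0) := +1; regulon targets absent from the
  signature are silently dropped (standard enrichment semantics); a
  regulator with fewer than `min_targets` observed targets is reported
  missing, never zero.
* `min_targets` defaults to 25, the customary regulon-size filter for this
  family of methods; synthetic fixtures use ≥ 30 targets so the filter does
  not interact with tests.
* The magnitude component (q₁) contributes only for |mor| < 1. Sign-based
  regulons never produce fractional mor, so in this pipeline the NES is
  purely directional; the component is retained for generality and covered
  by its own oracle tests.
* Multi-network integration is the unweighted mean of the per-network NES
  available for a regulator; a |NES|-weighted mean is exposed as an option
  (`integration="weighted"`). The unweighted mean is the simplest
  order-independent rule and treats every network as an equally credible
  replicate measurement.
* Under exchangeable signatures the analytic standardization D/√Σw′² makes
  the NES approximately standard normal. The approximation error from rank
  dependence is small: the null-calibration check (1000 standard-normal
  signatures of 2000 features, one 50-target regulon) requires mean within
  ±0.1 and sd within [0.9, 1.1].

### Activity direction for knockdown-derived regulons

All perturbations in scope are silencing (knockdown, knockout, CRISPRi), and
mor is defined as the sign of the *knockdown* response. A consequence worth
stating explicitly: a fresh knockdown signature of the same factor *matches*
its regulon, so the silenced factor attains the top **positive** NES —
equivalently, its activity (−NES under this sign convention) drops the most.
The leave-one-out benchmark therefore ranks candidates by +NES by default;
`perturbation="activation"` flips the score for activation screens. Program
classification is unaffected: "activated" and "inactivated" label the NES
direction consistently across cohorts, whatever the underlying convention.

## Calibration

Two architectures map gene-based activities onto the exon-based reference:
element-wise (scale aᵢ and bias bᵢ per SF — a per-factor linear model) and
dense (one fully connected linear layer W, b). Fixed hyperparameters:
20 epochs, batch size 64, learning rate 0.01, smooth-L1 loss with
transition point β = 1, k = 5 folds. The optimizer is Adam with default
betas, seeded; batch order is reshuffled each epoch from the run seed, and
the same seed reproduces weights bit-identically. Dense weights are
initialized to the identity on matched SFs (zeros elsewhere) with zero
biases, so the unadjusted activity is the starting point; random
initialization is available via config. Missing activities are imputed as 0
(the NES null value) before training and inference. Training is on raw NES;
an optional z-scoring flag exists but is off by default, since the NES scale
is already approximately standardized. Each fold's replicate is scored by
pooled Pearson correlation (all SF × sample entries) on its training and
held-out samples; inference averages the k replicate outputs.

## Programs

Differential activity per cohort uses two-sided Mann–Whitney U tests
(asymptotic normal approximation with tie and continuity correction, the
behaviour of the standard scipy implementation at cohort-scale samples) with
Benjamini–Hochberg adjustment *within* the cohort; significance at q < 0.05.
Direction is the sign of median(tumor) − median(normal). A factor is
oncogenic-like if significantly activated in ≥ 5 cohorts (inclusive) and in
strictly more cohorts than inactivated; tumor-suppressor-like symmetrically;
ties are conservatively non-driver-like. Program-level activity is the
median over member SFs with observed activity; the reporter is
median(oncogenic-like) − median(tumor-suppressor-like), positive in the
tumorigenic-like state.

Cross-regulation uses either regulon targets mapped to genes (SF a regulates
SF b iff a target exon of a lies in gene b) or adjacency in an interaction
graph filtered at combined score strictly above 900; self-interactions are
excluded from class-to-class fractions. Shortest paths are unweighted
breadth-first distances; infinite distances are treated as missing when
correlated against other quantities.

## Pathways

Preranked GSEA uses the weighted running-sum statistic with
weight exponent 1 and a gene-label permutation null (n_perm = 1000 by
default, seeded). NES divides ES by the mean |null ES| of matching sign;
the nominal p is the matching-sign tail with the add-one correction
(1+b)/(1+m), so finite permutation counts never produce p = 0; BH across
sets. Sets smaller than 5 genes after intersection with the observed
universe are dropped. ORA is the upper-tail hypergeometric test.
Prioritization: stage 1 keeps pathways whose NES–program-difference Pearson
correlation has the same sign in *all* carcinogenesis datasets and
shortlists the top-5 positive and top-5 negative by unweighted mean
correlation; stage 2 re-correlates the shortlist against per-perturbation
program differences and ranks by descending stage-2 correlation.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structural* assumptions the methods rely on,
at desk scale (defaults: 40 SFs — 15 oncogenic-like, 15 tumor-suppressor-
like, 10 non-driver-like — 2000 exons, 2000 genes, 50 targets per SF,
3 screens, 8 cohorts of 20+20 samples, 800 panel samples; SFs occupy the
head of the gene list so regulon targets can land in SF genes):

* **Screens**: ΔPSI = mor·effect (default 20 PSI units) on planted targets
  plus Gaussian noise (sd 1), clipped so baseline+signature stays in
  [0, 100].
* **Panel**: latent activity Z ~ N(0,1); exon-based Y = Z + ε and gene-based
  X = MZ + ε′ with noise sd 0.2. The mixing M is the identity plus
  off-diagonal Gaussian entries of sd 0.12 — strong enough that per-factor
  scaling demonstrably underfits relative to the dense map, while a
  20-epoch fit still recovers the inverse mixing within 20% relative error
  at the stated noise; chosen once and not tuned per experiment.
* **Cohorts**: tumor samples shift oncogenic-like factors by +2 and
  tumor-suppressor-like by −2 NES units over a shared per-cohort baseline,
  noise sd 1.
* **Perturb-seq**: log-normal baseline expression, planted knockdown log₂FC
  of 1–2 on target genes, negative-binomial counts (variance μ + 0.3μ²,
  depth 20 000 expected counts per cell).

Not emulated: real marginal distributions of PSI/TPM, coverage-dependent
missingness, correlated targets between factors, batch effects, and the
biological coupling between exon- and gene-level responses of the same
factor. Passing tests therefore demonstrate correctness of the machinery
and recoverability under the stated statistical structure — not performance
on any particular real dataset.

## Numerical and degenerate-input conventions

* Missing values are NaN internally and the literal `NA` on disk; matrix
  round trips are bit-exact (floats parsed with round-trip precision).
* GSEA ranking breaks value ties deterministically by gene id; all
  randomized operations take explicit integer seeds.
* Correlations require ≥ 3 complete pairs and report missing (with a
  warning) at zero variance; degenerate AUC units (single class) are
  excluded and counted.
* The recovery AUC is the rank/U statistic with half credit for ties.

## Known limitations

* Pleiotropy and shadow corrections found in some enrichment tools are not
  implemented; nothing in this pipeline enables them by default.
* No empirical permutation p-values for regulon NES (downstream analyses
  use NES magnitudes and cohort-level tests instead).
* Gene-set machinery asserts sign and rank behaviour, not numeric equality
  with any specific external GSEA implementation.
* The calibration hypothesis class is deliberately linear; nonlinear
  architectures are out of scope.
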