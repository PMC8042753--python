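# Methods

## The model

A duplicate pair is described by two features: the
nonsynonymous/synonymous substitution-rate ratio of its coding
sequences (KA/KS) and its age-normalised expression similarity (Re/KS,
the Spearman correlation of the two expression profiles divided by
KS). The degree of functional divergence is the probability of the
"high diversified" class under a binomial GLM with logit link,

    logit(DFD) = b0 + b1 * KA/KS + b2 * Re/KS,    high = 1.

The outcome coding deserves a note: descriptions of this model family
sometimes code 1 = low diversified, but a positive KA/KS coefficient
together with "DFD near 1 means strong divergence" is only coherent
with high = 1, which is what this package uses throughout. DFD is then
directly interpretable as P(high diversified).

Fitting is maximum likelihood by iteratively reweighted least squares,
converged when the largest coefficient update falls below 1e-8 (at most
100 iterations). Under perfect separation (or a collinear design) the
working weights collapse; the fit is then redone with an L2 penalty of
lambda = 1e-6 on the non-intercept coefficients and flagged `ridge` in
the model metadata, or raises `SeparationError` if the fallback is
disabled. The statsmodels GLM implementation serves as an independent
cross-check in the test suite, never as the implementation.

### Threshold calibration

Both call types are limited to a 5% false-positive rate on the
training data: `thr_low` is the 5% quantile (linear interpolation) of
DFD among true-high pairs, `thr_high` the 95% quantile among true-low
pairs. Calls use strict inequalities; a score exactly at a threshold
stays unclassified. When the classes separate so strongly that
`thr_low > thr_high` the thresholds are returned as-is with a
`non_separating` flag — every pair would then receive a call, and the
flag warns that the two 5% guarantees no longer delimit a middle
region. Cross-validation (100 stratified random 80/20 splits by
default, seed-controlled) verifies that the held-out FPR of each call
type stays near the nominal 5%.

ROC AUC is computed through the Mann–Whitney U identity with average
ranks for ties; PR AUC by step-wise interpolation over descending score
thresholds (equivalent to average precision). Variable importance is
the drop in model deviance when a variable is removed from the full
model — a proxy chosen because it is exactly defined and nested-model
comparable; ties break alphabetically.

## KA/KS estimation

The estimator is Nei–Gojobori (1986) counting on a codon alignment
obtained by back-translating a BLOSUM62 global protein alignment
(affine gaps, open -10, extend -0.5; biopython's `PairwiseAligner`,
whose fixed traceback order makes results deterministic; pre-aligned
rows can be imported verbatim instead, e.g. from MAFFT):

* synonymous sites per codon: per position, the fraction of the three
  possible point changes that preserve the amino acid, with changes to
  stop codons counted as nonsynonymous; the two sequences' totals are
  averaged;
* differences per codon pair: averaged over all minimal substitution
  paths, excluding paths through stop codons (if every path is blocked,
  all are used — a vanishingly rare case);
* Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3) applied separately to
  the synonymous and nonsynonymous difference proportions; the
  correction diverges at p >= 3/4, and KA/KS is undefined when KS = 0
  (such pairs are excluded from modelling with reason
  `undefined_feature`).

Columns with gaps, ambiguous bases or stop codons are skipped with a
warning (configurable to a hard error). S + N = 3 x (compared codons)
holds exactly by construction and is asserted property-wise; the whole
counting scheme is tested against an exhaustive site/path enumeration
oracle on random short codon pairs.

ML codon models (GY94-style, transition/transversion weighting, codon
frequencies) are deliberately out of scope: NG86 is fully specifiable
and testable, and externally computed KA/KS values can be injected
through the pair table (`ka`/`ks` columns) when estimates from another
program are preferred.

### Filtering

Pairs are kept when identity >= 0.30 AND coverage >= 0.50 AND
KS <= 3 (boundaries kept; rejection reasons reported per pair).
Identity is identical residues over dually-aligned columns; coverage is
dually-aligned columns over the longer unaligned sequence — the
literature often leaves both denominators implicit, so these
definitions are stated here and used consistently.

## Expression features

Re is the Spearman correlation over pairwise-complete conditions
(average ranks for ties; at least 3 complete pairs required).
Broad/specific expression calls use three exposed knobs: a gene counts
as expressed where its value reaches the expressed-threshold (default:
matrix-wide 60th percentile), broad means expressed in >= 95% of
conditions, specific means expressed in <= 5% (but at least one). The
published broad/specific gene counts imply some such rule but not its
constants; these defaults reproduce the qualitative dichotomy and are
reported in the output headers.

## Bias statistics

2x2 chi-square tests default to the Yates continuity correction — the
published p = 5.00e-5 for the specific/broad x high/low table
(180,174 | 5,31) is reproduced only with the correction on (the
uncorrected statistic gives ~2.3e-5); a per-call flag switches it off.
The Wilcoxon rank-sum test uses exact enumeration of all group
assignments when the combined n is at most 12 (handling ties, which
scipy's exact mode refuses) and the tie/continuity-corrected normal
approximation otherwise. Shared-annotation proportions are Jaccard by
default with a min-denominator alternative. GO-term enrichment is a
one-sided hypergeometric test with Benjamini–Hochberg control; absolute
enriched-term counts depend on the annotation release and are not
treated as reproduction targets.

## Ortholog retention and branch selection

Retention is the fraction of duplicates with an ortholog present in a
species, stratified by class and mechanism, compared by 2x2 chi-square.
For triplets with all three sequences (A. thaliana, A. lyrata,
B. rapa), branch-specific KA and KS come from the additive
decomposition of the three pairwise NG86 distances on the unrooted
star tree: b(Al) = (d(At,Al) + d(Al,Br) - d(At,Br))/2 for the
AS1->Al branch and symmetrically for AS2->Br, where AS1 is the (At,Al)
ancestor and AS2 the three-species ancestor. This is equivalent to
midpoint ancestral placement and avoids explicit ancestral sequence
reconstruction — a deliberate methodological substitution for
tree-based ancestral estimation. Negative decompositions (non-additive
noise) truncate to zero and are flagged.

Selection on a branch is called from a two-sided Fisher exact test of
(branch-allocated nonsynonymous, synonymous differences) against the
(nonsynonymous, synonymous) site totals; the branch allocation scales
the pairwise counts of the pair containing the branch (At–Al for
AS1->Al, At–Br for AS2->Br) by the branch-to-pairwise distance ratio,
rounded half-up. Positive: p < 0.05 and branch KA/KS > 1; purifying:
p < 0.05 and KA/KS < 1; otherwise neutral (zero allocated differences
are neutral with p = None). This count-based procedure is far less
powerful than ML branch-site tests — individual calls are noisy, and
only group *proportions* of positive/purifying calls are treated as a
meaningful surface, compared across class x mechanism groups and
supported by bootstrap resampling.

## The synthetic generator

The generator emulates the statistical structure the analyses assume,
not any particular genome:

* **Codon evolution** is an accept/reject scheme, not a full rate
  matrix: point-mutation proposals arrive as a Poisson process with
  intensity 3L·t per branch, proposals creating stops are rejected,
  nonsynonymous proposals are accepted with probability min(1, omega);
  for omega > 1 the intensity is scaled by omega and synonymous
  acceptance by 1/omega, so the expected synonymous divergence per
  synonymous site stays t while the nonsynonymous/synonymous rate ratio
  is omega. This suffices for NG86-recoverable omega (median estimates
  within ~10% at omega <= 1; attenuated ~10-15% at omega = 1.5 because
  rejected stop-codon proposals and multiple hits bite hardest there).
* **Expression profiles** come from a Gaussian copula with Pearson
  r = 2 sin(pi·rho/6), giving population Spearman exactly rho, then
  exponentiated to an intensity-like scale (Spearman is invariant to
  that). Small-sample bias is covered by tolerance-based tests.
* **Class contrasts** (defaults, all configurable): omega lognormal
  with mean 0.8 (high) vs 0.15 (low), sigma_log 0.8; Spearman targets
  0.2 (high) vs 0.7 (low), sd 0.25; 634 conditions; 300-codon genes;
  KS range 0.1–2.5. Annotation plantings: PPI degree Poisson mean 3
  (high) vs 9 (low); core-gene rates 2% vs 14%; tandem fractions 0.67
  vs 0.27; GO-term sharing probability 0.3 vs 0.8.
* **Ortholog triplets**: retention Bernoulli per species (A. lyrata
  0.41 high / 0.67 low; B. rapa 0.26 / 0.38); tree with synonymous
  branch lengths 0.075 (At), 0.075 (Al), 0.175 (AS2->AS1), 0.25 (Br),
  so pairwise KS ≈ 0.15 (At–Al) and 0.5 (At–Br); branch omegas by
  class x mechanism, 1.5 for high-tandem down to 0.2 for low-WGD, 0.4
  for singleton controls.

Everything derives from a single seed and regenerates byte-identically.

What passing on synthetic data does **not** show: the generator has no
microarray noise structure, no probe effects, no gene-family
correlation between pairs, no indels (simulated orthologs are aligned
by construction), and its class-conditional distributions are idealised
lognormals/Gaussians. Results on real data depend on upstream choices
(isoform selection, alignment quality, annotation release) that the
synthetic path cannot probe.

## Problem sizes and numerical choices

Simulation-based checks use 200 replicates for estimator recovery,
n = 5,000 pairs for coefficient recovery, n = 500 per class for
calibration studies (50 seeds), and 30–50 re-simulated datasets for
ordering-support summaries — sizes at which the targeted tolerances
(±15% on median omega, ±0.01 on mean Spearman, 3 SE on coefficients,
two binomial SE on FPR) are well inside the estimators' sampling noise.
Percentiles interpolate linearly; probabilities are clipped nowhere;
IRLS weights are floored at 1e-10; selection-test counts round half-up.
Coordinates are 0-based half-open internally, 1-based in reported
positions and error messages.

## Known limitations

* NG86 without transition/transversion or codon-frequency corrections
  underestimates omega above 1 and saturates near KS ~ 3; the filters
  keep analyses inside the usable range.
* The Fisher selection call has low per-gene power at realistic branch
  lengths (see above); only proportions are interpreted.
* The breadth rule and the enrichment procedure are stated defaults,
  not recovered constants of any published analysis.
* `relative_importance` is a deviance-drop proxy, not a variance
  decomposition; correlated predictors share importance in a
  model-dependent way.
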