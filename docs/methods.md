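# Methods

## Ligand activity and CCI inference

For one cancer, the inputs are a filtered DEG table (records with adjusted
p < 0.05 and |log2FC| > 0.25; positive log2FC = up in tumor) and a
nonnegative ligand × gene regulatory-potential prior. For every ordered
(sender, receiver) cell-type pair, candidate ligands are sender DEGs present
among the prior's ligands — in either direction of change, since a
down-regulated ligand still marks a perturbed interaction. A ligand's
activity is the Pearson correlation, across a background gene universe,
between its prior-weight vector and the 0/1 indicator of receiver-DEG
membership. The top `top_n` ligands (default 20) per pair are linked to
their `top_k` (default 200) highest-weight targets among the receiver DEGs;
both defaults mirror the convention of the external inference tools this
module emulates and are otherwise arbitrary.

**Background choice.** The background defaults to the prior's full gene
universe. A receiver-restricted background built from significant DEG tables
alone would be degenerate (every background gene would be a DEG, making the
indicator constant and the correlation undefined), so the prior universe —
the closest available analogue of an expressed-gene background — is used
and exposed as a parameter. Degenerate backgrounds (indicator all 0 or all
1) raise an explicit error; ligands with constant weights have undefined
activity and are reported as NaN, after all defined activities. Activity is
invariant to positive affine rescaling of a ligand's weights (a Pearson
property), and the whole module is deterministic.

## MCTM and shared-MCTM

A per-cancer MCTM is the directed cell-type graph whose edge sender →
receiver is weighted by the number of *distinct* (ligand, target)
interactions between the pair (duplicate records collapse first). MCTM
genes are the union of URs and DSs.

The consensus model is built in four steps: (1) URs present in every
cancer's CCI set; (2) for each such UR and each cell type where it is a
DEG, tally cancers with positive and with negative log2FC — the cell type
qualifies when the larger tally reaches `min_concordant` (default 4 of 5);
(3) targets linked to any shared-UR are screened with the identical
concordance rule to give shared-DSs; (4) each shared-UR connects to every
downstream cell type holding ≥ 1 of its shared-DSs, weighted by their
count. Numerical conventions: log2FC exactly 0 counts toward neither sign;
an exact positive/negative tie has no majority and never qualifies; a gene
may qualify in several cell types and all qualifying pairs are kept; genes
qualifying as both shared-UR and shared-DS keep both roles and count once
in the gene union (the role overlap is reported explicitly). Shared-DS
candidacy requires linkage to a shared-UR in at least one cancer by
default; a stricter all-cancer quorum is available via `ds_linkage="all"`.
Whether a shared-UR's qualifying cell types should be limited to cell types
where it acts as a sender is genuinely open; it is exposed as
`restrict_ur_cell_types_to_senders` (default off, matching the permissive
reading "one cell type").

Enrichment of model genes against trait gene sets uses the two-sided Fisher
exact test within a stated background (trait genes outside the background
are discarded first), reporting the conditional maximum-likelihood odds
ratio; batches are Benjamini–Hochberg adjusted. Being an exact test, its
null p-values are discrete and conservative — calibrated in the one-sided
sense P(p ≤ x) ≤ x — which is what the test suite checks.

## Signature prioritization

Shared-URs are clustered on their per-downstream-cell-type interaction
counts under Euclidean distance and the dendrogram is cut into two
subclusters. The linkage method is not dictated by the procedure being
emulated; complete linkage is the default, exposed as a parameter, and the
oracle-equivalence tests run per linkage. "The cluster with more
interactions in all cell types" is operationalized as column-wise mean
dominance (≥ everywhere, > somewhere); when neither cluster dominates every
column the larger total count wins, and an exact total tie falls back to
the cluster containing the lexicographically smallest row label. mCAF
marker selection takes the `top_n` = 10 markers by log2FC versus the other
CAF subclusters (rank ties truncated with a symbol tie-break), keeps those
that are also tumor-vs-normal DEGs in the mCAF cluster (the filters apply
in that order — ranking first, DEG filter second), and drops genes already
chosen as top shared-URs. Assembly keeps a gene appearing on both lists
once, with shared-UR provenance and a warning.

## Scoring

The rank-based single-sample score transforms each feature to empirical-CDF
values across samples (midranks under ties), orders each sample's features
by that value (ties broken by symbol), and takes a weighted
Kolmogorov–Smirnov random walk with the signature as the hit set: hit steps
proportional to the ecdf value (weight exponent 1), miss steps −1/(#misses).
The score is the signed sum of the walk's maximum positive and maximum
negative deviations, hence bounded in [−1, 1]. Relative to the external
tool whose default scoring this emulates, the Gaussian-kernel CDF estimate
is replaced by the empirical CDF — removing a bandwidth choice while
preserving rank semantics — and this is the only estimator offered; the
score statistic is the tool's default signed difference of extrema, and the
alternative (largest single deviation) is deliberately not offered. The
score is invariant to strictly increasing per-feature transforms and
equivariant under sample permutation; exact numeric agreement with the
external implementation is a non-goal.

The protein score is the per-sample mean of observed signature-protein NPX
values (missing values excluded pairwise), applied after QC: proteins
missing in strictly more than 20% of samples are removed and remaining gaps
filled by the mean of the 10 nearest samples under Euclidean distance over
mutually observed features; observed values are never modified. Scores
dichotomize at the cohort mean (high iff score > mean), and the cutoff is
stored so levels are reproducible.

Cohort differential abundance uses the two-sided Wilcoxon rank-sum test per
feature with log2FC defined as the difference of group means on the log2
scale (no formula is dictated for it, so the simplest is used). The exact
null distribution is used when the pooled sample has no ties; with ties,
the tie-corrected normal approximation without continuity correction, so
identical group distributions give p = 1 exactly. BH adjustment runs across
the tested features.

## Survival

Follow-up is truncated at 10 years = 3652 days (the horizon's day count is
a package convention; it is configurable). Cox models use lifelines'
partial likelihood with the Efron approximation for ties (the tie method is
likewise a package choice). Hazard ratios are exp(coefficient) with 95% CIs
from the coefficient standard error. Covariates default to sex, age at
diagnosis, cancer type and sampling lag; covariates constant within a
stratum (sex inside a sex subgroup, cancer type inside one cancer) are
dropped automatically. Separation or non-convergence produces a flagged
result rather than an exception; a constant exposure is an error. The
continuous score enters Cox models; the dichotomized level drives
Kaplan–Meier curves and two-sided log-rank tests, optionally crossed with
sex. Per-cancer screens skip cancers with fewer than 20 death events —
reported as skipped, never silently dropped, for auditability — and BH
adjustment runs across the retained set. Because the appropriate family for
FDR in per-cancer testing is ambiguous (across cancers vs across features
within a cancer), `per_cancer_screen` adjusts across cancers and the batch
helpers allow the other family.

## Synthetic data

The generator emulates the *derived* tables of a five-cancer single-cell
study — not raw counts, UMI matrices or cell-level data. Defaults encode
the study design: 5 cancers, 6 cell types (fibroblast sender, five receiver
types), 300 genes of which 30 are ligands, 3 planted shared-URs with 8
targets each, full (5/5) sign concordance for planted structure, |log2FC|
drawn from [effect, 1.5·effect) with effect 1.0 (comfortably above the 0.25
filter; real effect-size distributions are uncalibrated, so the magnitude
is configurable), adjusted p uniform below 0.01, prior background weights
Uniform(0, 0.2) with +1.0 boost on planted pairs.

Decoys are engineered to fail the consensus rules: *missing* decoys absent
from one cancer, *sign-flip* decoys discordant in two; decoy targets and
background noise DEGs appear with any one sign in at most
min_concordant − 1 cancers per cell type, so recovery of exactly the
planted structure is a structural guarantee, not a statistical accident.

Cohorts: each sample carries a latent activity s ~ N(0,1) shared by its
signature genes (expression = gene baseline + s + 1.0 case shift +
N(0, 0.3) gene noise), so rank-based and mean-abundance scores both track
the hazard. Survival times are exponential with hazard h₀·exp(β·s +
0.2·male + 0.02·(age − 60)), h₀ = ln2 / 5 years (baseline median survival
5 years, so roughly two-thirds of patients die within the 10-year window);
β defaults to ln 2. Exponential (rather than Weibull) times keep
proportional hazards exact and closed-form checks simple. Independent
censoring occurs with probability `censor_rate` at a Uniform(0, T) time —
chosen so full censoring yields exactly zero events and the event fraction
is monotone in the rate — plus administrative censoring at 10 years.
Protein matrices carry missing-completely-at-random gaps at `missing_rate`
(nothing characterizes the real missingness mechanism, so MCAR is assumed).
Covariates: sex Bernoulli(½), age N(60, 10) clipped to [30, 85], uniform
cancer-type assignment for cases, sampling lag Uniform(0, 730) days. The
latent activity is stored in the sample table for parameter-recovery
checks. One global seed fans out to per-artifact child seeds via
`SeedSequence(seed, spawn_key=(counter,))` (0 DEG tables, 1 prior,
2 cohort, 3 marker tables), so generating one artifact never perturbs
another.

What passing tests on these data do *not* show: robustness to correlated
gene noise, batch effects, informative censoring, non-proportional hazards,
realistic DEG effect-size distributions, or prior misspecification — none
of which the generator emulates.

## Problem sizes

Simulation-backed checks use sizes chosen to make the statistics
informative while keeping the suite quick: 200 random instances for
consensus-oracle equivalence, 20 seeds for planted recovery, 100 replicates
at n = 1000 for Cox parameter recovery (±15% on the mean log-HR, ≥ 90% CI
coverage), 500 replicates at n = 100 for null calibration (KS at α = 0.01),
and exhaustive Fisher enumeration over all 2×2 tables with total ≤ 30.

## Known limitations

- The ligand-activity statistic is a deliberate simplification of the
  external tool it emulates (correlation against set membership with the
  tool's default semantics); regression-based variants and
  receptor-expression filtering are out of scope.
- Sender/receiver cell-count filtering before CCI inference is not
  implemented (nothing specifies it); empty or degenerate pairs are skipped
  with warnings.
- Competing risks, time-varying covariates and formal proportionality
  diagnostics are out of scope; non-convergence is surfaced, not repaired.
- The generator's planted-recovery guarantee assumes the default rule
  parameters; loosening `min_concordant` below 4 can admit engineered
  decoy targets by design.
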