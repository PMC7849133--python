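# Methods

## Model

`driversvm` frames patient-level driver detection as novelty detection.
Canonical driver genes are a reliable positive class, but no trustworthy
negative class exists — published "false positive" gene lists are genes
that fool recurrence-based methods, not true non-cancer genes, so training
a two-class model on them would import their biases. One-class SVMs are
therefore fitted on the positives alone, and every other damaged gene is
scored by its resemblance to them.

Four kernels (linear, radial, sigmoid, polynomial) are trained
independently and combined. The combined score of a prediction-set entry is
the sensitivity-weighted sum of the four standardised kernel decision
values: each kernel's continuous decision function is z-scored across the
whole prediction table (making otherwise incommensurable kernel outputs
comparable, and making the combined score invariant under affine rescaling
of any kernel's raw output), multiplied by the kernel's weight
w_k = s_k / Σ s_j, where s_k is the kernel's converged cross-validated
sensitivity, and summed. Genes are ranked within each sample by descending
combined score, ties broken by gene symbol. This closed form honours the
stated principle — kernels weighted by their sensitivity — and is
deliberately simple; the exact aggregation is a design choice of this
package and can be swapped by scoring kernels separately from
`TrainedModel.estimators`.

### Features

Each damaged (sample, gene) pair carries 7 molecular and 19 systems-level
features (26 total). "Damaged" means at least one truncating
(stop gain/loss, frameshift, splice site), non-truncating damaging
(missense / in-frame indel flagged damaging by upstream annotation) or
hotspot mutation, an amplification, or a deletion. Thresholds:
amplification = copy number ≥ 2 × sample ploidy, deletion = copy number
< 1. These follow common practice in absolute copy-number calling and are
overridable (`amplification_multiple`, `deletion_threshold`). A hotspot
missense that is also predicted damaging counts in both the hotspot and
non-truncating damaging tallies. Mutational load counts all non-synonymous
records. Genes without a copy-number call sit at the sample's ploidy
(copy-neutral). Protein length and domain count are excluded from the
feature set: long multi-domain proteins are the hallmark of
recurrence-method false positives, and removing the two features improves
the separation of drivers from false positives.

### Training-set restriction

An oncogene enters training only with gain-of-function alterations
(amplification, hotspot, or non-truncating damaging mutation), a tumour
suppressor only with loss-of-function ones (truncating mutation or
deletion), a dual-role gene with any damaging alteration. Canonical
drivers without a usable mode-of-action role are excluded from training
but remain in the prediction set, where they serve as positives for
assessment.

### Scaling

Feature columns are divided by their training-set sample standard
deviation (ddof = 1) and left un-centred; centring was found to hurt
one-class separation in this setting since the origin acts as the implicit
reference point for the decision function. The divisors are embedded in
the trained model and reused verbatim at prediction time. Constant columns
are divided by 1 and reported with a warning — on small training sets some
binary features are legitimately constant.

### Hyper-parameter selection

Per kernel, a deterministic grid is searched: by default
ν ∈ {0.05, 0.1, 0.2, 0.3}, γ ∈ {2⁻⁷ … 2³} (powers of two, where
applicable), degree ∈ {2, 3, 4}, coef0 ∈ {0, 1} — 400 configurations over
the four kernels. Each selection iteration draws a fresh 3-fold partition
of the training entries (shared across the grid, so configurations are
compared on identical splits), fits each configuration on two folds and
measures the pooled fraction of held-out entries predicted in-class
(sensitivity). The configuration with the highest running-mean sensitivity
is tracked; selection converges when its identity is unchanged for a
window of consecutive iterations (default 100, capped at `max_iterations`
= 2000; an exhausted budget returns the current best flagged unconverged).
Ties prefer lower ν (a tighter training-outlier bound), then grid order.
Fold sensitivities are pooled, not averaged, so unequal fold sizes are
weighted by entry.

`reduced_grid()` (≤ 24 configurations per kernel) spans the low-to-mid
part of the default γ range (2⁻⁷, 2⁻⁴, 2⁻¹) and keeps only the
inhomogeneous polynomial (coef0 = 1): on un-centred unit-SD data, inner
products are large enough that γ ≥ 2⁻³ saturates the sigmoid's tanh and
yields degenerate decision functions. A kernel whose fit fails records
sensitivity 0 and simply receives zero weight; scoring requires at least
one kernel with positive sensitivity.

### Driver calling

The top-up rule: a patient's damaged canonical drivers are drivers by
default; ranked predictions are appended until the list reaches five genes
or the patient's damaged genes are exhausted. Five reflects estimates of
the minimum number of driver events needed for a developed cancer. A
patient with more than five damaged canonical drivers keeps all of them
(the list exceeds the target; predictions are never added in that case). A
gene damaged by both mutation and CNV counts once. Cohorts with fewer than
200 samples (strict inequality) are assigned the pan-cancer setting —
training on a large agnostic cohort — because small cohorts yield unstable
rankings and occasional false positives; at 200 or more, cancer-specific
training is preferred as it can reflect cancer-type biology without losing
stability.

## Cohort simulator

`simulate_cohort` generates new cohorts from a donor cohort by matched
resampling. For each simulated sample, a target damaging mutation burden
and a target ploidy are drawn independently (with replacement) from the
empirical donor values — a bootstrap, chosen over a parametric fit so the
marginal distributions are preserved exactly. Mutation-damaged genes are
then drawn from the multiset of (gene, payload) occurrences across donors
whose burden lies within ±10% (relative) of the target: exactly `target`
distinct genes are taken by walking a random permutation of the
occurrences, so a gene damaged in many eligible donors is proportionally
more likely to be picked and per-gene alteration frequencies carry over to
the simulated cohort. (Sampling uniformly over *unique* pool genes instead
provably flattens the frequency spectrum; this was measurable as a
frequency correlation that degraded as the donor cohort grew.) Alteration
payloads are copied verbatim from the chosen occurrence. CNV-damaged genes
are drawn the same way from donors with ploidy within ±0.1 of the target,
with the per-sample CNV gene count itself resampled from those donors'
counts (the count model is otherwise unconstrained). If a drawn target
admits too small a pool, the target is redrawn (10 attempts) before
rejecting the input.

Burden is defined as the number of genes damaged by mutation in a sample
(one payload of one or more variant records per gene). Under this
definition the simulated burden equals its assigned target exactly, and
simulated ploidy equals its target, making the matching contract
verifiable without tolerance games.

## Synthetic fixture cohorts

`generate_fixture_cohort` fabricates the four pipeline inputs plus ground
truth. Defaults: 2000 genes, 50 planted drivers, 100 samples, 100
candidate genes, 20 false-positive genes. Per sample, the number of
mutation-damaged genes is log-normal with mean 33 (matching a damaged-gene
density of roughly 300 damaged genes per sample per 18,000-gene exome,
scaled to the 2000-gene universe), ploidy is normal (2.7 ± 0.5, clipped to
[1.5, 5]) reflecting widespread aneuploidy, and ~8 genes carry damaging
CNVs. Planted drivers are hit at 8× the background rate — producing driver
alteration frequencies of ~10% per sample, a long-tailed spectrum like
real cohorts — with mode-of-action-consistent alterations (oncogenes:
damaging missense, 30% hotspot rate, amplifications; tumour suppressors:
truncating mutations, deletions). Roles are assigned ~35% OG, ~35% TSG,
~5% dual-role and ~25% no role; the no-role drivers are annotated
canonical but never trained on, mirroring the sizeable minority of real
canonical drivers that cannot be classed as OG or TSG and providing
held-out positives for assessment.

Driver systems-level features are shifted towards the empirical profile of
cancer genes, scaled by `feature_shift` (0 = null, 1 = default): lower
duplicability (45% → 25%), more ohnologs (20% → 45%), higher essentiality
(~5% → ~20% of cell lines), broader gene and protein expression, ~2.5×
higher interaction-network degree with correlated betweenness, more
complex memberships and targeting miRNAs, and older evolutionary origin
(pre-metazoan 25% → 55%). Non-driver baselines are genome-scale
plausibilities (median degree ~7, mostly metazoan/pre-metazoan origin,
low essentiality).

What the fixtures do **not** emulate: mutational signatures and genomic
position, gene–gene co-occurrence and mutual exclusivity, cancer-type
structure, correlated property noise (real systems-level features are
measured, with database-specific artefacts), or realistic false positives
(fixture false positives are random non-drivers, so they are *easier* to
separate than real recurrence-method false positives, which share features
with drivers). A passing recovery test therefore demonstrates that the
pipeline's plumbing, restriction rules, selection and scoring are correct
and that planted signal of realistic effect size is recovered — not that
real-data AUCs of any particular magnitude will be achieved.

## Evaluation statistics

All metrics work on within-sample ranked lists labelled canonical /
candidate / false_positive / rest (precedence in that order).

- **Per-sample AUC** — the Mann–Whitney statistic computed from ranks: the
  fraction of (positive, negative) pairs where the positive outranks the
  negative. Undefined (NaN) when either group is absent; undefined values
  are excluded from cohort medians, never zero-filled.
- **Composition score** — positions i = 1..k (default k = 5) weighted
  (k + 1 − i)/(1 + … + k) (linear decay, weights summing to 1), each
  contributing its weight times +2 (canonical), +1 (candidate), 0 (rest)
  or −2 (false positive). Bounded in [−2, 2]; negative values flag highly
  ranked false positives. The linear-weight/value form is this package's
  reconstruction honouring those stated properties and is swappable via
  `COMPOSITION_VALUES`.
- **O/E ratio** — observed count of a category in the top k over
  k × (category frequency in the sample's pool); undefined when the
  category is absent from the pool.
- **RBO** — rank-biased overlap truncated at the evaluation depth
  (default 5): overlap of the two d-prefixes divided by d, averaged over
  d ≤ depth with geometric weights ∝ p^(d−1) (default p = 0.9) normalised
  to sum to 1. Truncation (rather than the extrapolated variant) matches
  the fixed top-5 lists being compared; identical lists score 1, disjoint
  lists 0.

Correlation-based feature selection (`select_features`) is provided as an
audit tool: all pairwise Pearson correlations, Benjamini–Hochberg
adjustment, pairs with |r| > 0.5 and FDR < 0.05 deemed redundant, and
features removed greedily — most significant pairs first, ties by column
order — until no flagged pair remains. The shipped 26-feature set already
reflects this audit; the default pipeline does not re-select per cohort.

## Numerical and reproducibility choices

- All randomness flows from integer seeds through `numpy` generators;
  sampling uses integer indexing over sorted keys, so outputs are
  byte-identical across platforms and reruns.
- Rank ties are broken by gene symbol; selection ties by lower ν then grid
  order; ranks are dense (1..n).
- A kernel's z-standardisation divides by the prediction-set SD; a
  degenerate (constant) score vector standardises to zeros and contributes
  nothing.
- RBO is clamped to [0, 1] against floating-point overshoot (≤ 2 ulp).
- Models serialise with `joblib` plus a JSON sidecar (configs, weights,
  divisors, roster size, provenance) and a format version; loading rejects
  unknown versions. The pipeline manifest records config, seeds, package
  version and SHA-256 input checksums, sufficient to re-run
  bit-identically.

## Benchmark problem sizes

The packaged experiments (`driversvm.experiments`, also driven by
`scripts/acceptance.py`) use desk-scale sizes chosen to finish in minutes
on one CPU while keeping every qualitative contrast: recovery trains one
model on the default 100-sample fixture with the reduced grid and 50
selection iterations (window 25); stability trains 5 models each on
disjoint 100- and 10-sample cohorts from one 600-sample universe with a
28-configuration grid and 25 iterations, comparing median pairwise top-5
RBO on a common 50-sample evaluation set; simulator fidelity resamples 500
samples from a 100-donor fixture cohort. Production-scale runs with the
full 400-configuration grid and 2000-iteration budget use the same code
paths through the `train` / `run` commands.

## Known limitations

- Gene identity is the upper-cased symbol; no alias resolution.
- Variant-effect prediction and hotspot catalogues are upstream concerns;
  the damaging/hotspot flags are trusted as given.
- Systems-level property curation from source databases is out of scope;
  a prepared property table is required.
- Genes whose systems-level profile departs from the driver norm will be
  missed by construction; the method is designed to complement, not
  replace, recurrence-based callers (hence the top-up design).
- The selection loop refits the grid every iteration; on cohorts with
  thousands of training entries and the full grid this is minutes-to-hours
  of CPU, mitigated by the reduced grid or a smaller iteration budget.
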