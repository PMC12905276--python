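# Methods

This note documents the models implemented in repurposekit, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Disease signatures (`signatures`)

Differential expression between a case and a control group is scored by
a two-sample t statistic with a simple empirical-Bayes-flavoured
variance shrinkage: each gene's pooled variance `s2_g` (residual df
`d_g`) is blended toward the cross-gene mean pooled variance `s2_0`,

    s2_shrunk = (d0·s2_0 + d_g·s2_g) / (d0 + d_g),

with prior weight `d0` (default 4, the order of magnitude a moderated-t
prior typically ends up at for small microarray designs). `d0 = 0`
recovers the ordinary pooled t exactly, and `d0 → ∞` collapses every
gene onto the common variance; both limits are tested. Full estimation
of the prior from the data (marginal-likelihood fitting of `d0` and
`s2_0`) is intentionally out of scope — the blend keeps the estimator
transparent while providing the stabilisation that matters at n ≤ 20
per group. P-values use `d0 + d_g` degrees of freedom and are BH
adjusted (via statsmodels).

A signature keeps genes with adjusted p ≤ alpha (default 0.05, the
conventional FDR level), removes ids matching a control-probe prefix
list (default `AFFX`, the standard array-control prefix), splits by the
sign of the fold change, orders by |t| with a lexicographic gene-id
tiebreak, and truncates to `top_n` per side (default 100 — large enough
to carry signal, small enough that the KS score is not diluted;
`dgem.optimize_parameters` exists precisely because this choice should
be driven by positive-control recovery, not convention).

The KS enrichment score walks the ranking, stepping up by `1/|hits|` on
members (or by |score|^w normalized over hits when `weight_exponent`
w ≠ 0) and down by `1/(N−|hits|)` otherwise; ES is the deviation of
maximal magnitude, clipped to [−1, 1] against cumulative-sum round-off.
Scores on 1–2 genes are degenerate (±1 almost surely), hence the
default minimum overlap of 3.

Sample QC flags samples whose mean inter-sample Pearson correlation
falls below `median − k·MAD` (default k = 3; MAD unscaled). Constant
samples have undefined correlations and are flagged with a warning
rather than raising, so a batch with one dead array still processes.

## Connectivity matching (`dgem`)

The connectivity score is the classic two-sided construction: ES of the
up set and of the down set within a drug's ranking, combined as
`(ES_up − ES_down)/2` when the signs differ and 0 otherwise. −1 is a
perfect inversion; candidate therapeutics are the most negative scores.
The null distribution is built from random signatures of the same
up/down sizes. Because a random gene set scored against a fixed
permutation is distributionally identical to a fixed set against a
random ranking, one null sample (size `n_perm`) is shared across all
drugs of a compendium; p-values are two-sided with +1 smoothing and BH
adjusted across drugs. `n_perm < 100` warns, `< 10` errors.

Positive-control enrichment reports AUROC (probability that a known
therapeutic outranks a non-therapeutic) and fold enrichment at k.
`optimize_parameters` grids over `top_n`/`alpha`/`weight_exponent`,
selects by AUROC, and breaks ties toward smaller signatures.

## Pair-kernel prediction (`prism`)

Compound kernels: Tanimoto over binary fingerprints and Jaccard over
target sets (default weights 0.5/0.5). Disease kernels: Jaccard of
self-inclusive ancestor closures in a rooted ontology, and cosine of
literature co-mention count profiles (default 0.4/0.3/0.3 across
ontology/target/co-occurrence where all three exist; the CLI uses
ontology 0.4 + co-occurrence 0.3 renormalized when disease targets are
absent). Convex combinations are repaired to PSD by clipping negative
eigenvalues at zero and renormalizing the diagonal to 1 — clipping
rather than diagonal shifting keeps the off-diagonal scale of the
similarities.

The pair kernel is the Kronecker product, evaluated lazily per block;
full materialization is capped (default 250k entries) because the pair
space grows as `n_c²·n_d²`.

The classifier is a soft-margin SVM (sklearn, precomputed kernel,
default C = 1) trained on known indication pairs against negatives
sampled uniformly from the unlabeled pairs at `negative_ratio` (default
5) per positive. Two PU-learning realities shape the defaults: sampled
negatives are contaminated with unobserved true pairs, and in highly
structured worlds a contaminated negative can sit at exactly the same
point of kernel space as a genuine positive. Classes are therefore
re-weighted inversely to frequency (`class_weight="balanced"`), the
standard mitigation; without it a single mislabeled duplicate can flip
an entire disease column. Decision scores are raw margins, not
calibrated probabilities — only the ranking is consumed downstream.

The guilt-by-association baseline `score(c,d) = max_(b,a known)
Kc(c,b)·Kd(d,a)` is kept as an independent reference; tests require the
SVM not to fall materially below it.

## Evidence and consensus (`evidence`)

Literature support is pointwise mutual information
`log2[(n_cd+α)N/((n_c+α)(n_d+α))]` with pseudocount α = 0.5 (Jeffreys-
style; α = 0 reproduces textbook PMI and −∞ for unseen pairs).
Propagation takes the best damped similarity-weighted neighbor:
`inferred = max(direct, damping·max Kc·Kd·direct⁺)`, damping default
0.5 — one hop, attenuated, never amplifying.

Consensus normalizes each source's ranks to [0, 1] (1 = best; compounds
missing from a source get 0, that source's worst value, so partial
evidence never drops a candidate silently), averages with configurable
weights (default 0.5/0.5), multiplies by `1 + bonus` (default 0.25)
when literature support is positive, and renormalizes by `1 + bonus`.
Literature is deliberately a confirmation multiplier, not a third
ranked source. Triage applies an approval flag and declarative
`(attribute, comparator, threshold)` rules, recording the first failing
rule per removed compound; it is order-independent and idempotent.

## Synergy (`synergy`)

Monotherapy curves are 4PL fits on fractional inhibition with starting
values bottom = min, top = max, IC50 = geometric-median dose, h = 1,
and h bounded to [0.1, 10]; a failed fit degrades to monotone
interpolation on log-dose (flagged), which still reproduces the
measured margins exactly, and a constant response yields a flat fit
with undefined IC50. AUC is the trapezoid of inhibition over min-max
normalized log10 dose.

The ZIP expectation at a dose pair is `y1 + y2 − y1·y2` from the fitted
margins; δ is the observed-minus-expected difference in percentage
points, reported per cell, as a mean over positive-dose cells, and as
the MSA (maximal mean over contiguous 3×3 windows — window configurable,
3 being the reference convention). This is the margin-fit simplification
of full ZIP: the reference procedure re-fits potency-shifted curves
along every row and column and averages the two directions. For
matrices generated as ZIP-null plus an additive bonus the two coincide;
for real matrices with dose-dependent interaction structure the full
procedure would differ, and this is a known limitation. Efficacy volume
is the mean percent inhibition over positive-dose cells.

## Synthetic worlds (`simulate`)

The generators produce every pipeline input with planted truth, all
randomness through one seeded `numpy.random.Generator`.

* **Expression**: Gaussian on the log2 scale around gene-specific
  baselines (N(7, 1)), default 2000 genes, 20 samples per group, 100 DE
  genes at ±2 log2 units with noise SD 1.0 — the effect/noise regime of
  a well-powered microarray contrast. Planted group-mean differences
  are forced exactly, so zero-noise recovery is exact by construction.
  Not emulated: probe-level artifacts, batch effects, normalization
  residue, count distributions.
* **Compendium**: latent per-drug scores; decoys are N(0,1) everywhere,
  inverse drugs place signature up-genes in a band below the background
  (uniform(−3,−2) vs. background uniform(−1,1)) and down-genes above
  it, mimics mirrored, everything perturbed by Gaussian noise (default
  SD 1.0). At zero noise an inverse drug's ranking is exactly extreme.
  Rankings are argsort-descending with index tiebreak.
* **Similarity world**: compounds and diseases partitioned round-robin
  into blocks; fingerprints are block prototypes with per-bit flip
  probability 0.1; targets drawn from block pools; the ontology is a
  rooted tree (per-block chains of the stated depth with two leaves) —
  a DAG would be a straightforward extension but the tree already
  supports ancestor-set similarity; disease co-mention counts are
  Poisson (within-block rate 30, between 3). The world's premise is
  that similar compounds treat similar diseases, so by default *all*
  matched-block pairs are true (a sparser truth is available via
  `n_true_per_block`); the holdout is stratified by block so every
  block keeps at least one training pair — an unstratified holdout can
  make a whole block's held-out pairs unrecoverable in principle.
  Compound–disease co-occurrence is Poisson at rate 20 for true pairs
  vs. 2 otherwise.
* **Dose–response**: 4PL margins, ZIP interior plus additive bonus plus
  noise, clipped to [0, 1], returned as percent viability. Exact
  recovery of a planted bonus requires cells below the clipping
  ceiling, so sub-saturating grids are used for exactness checks, while
  noise-calibration runs use a screen-style grid spanning 0.25×–4× the
  IC50 (grids capped at the IC50 leave all cells far from saturation
  and inflate margin-fit error propagation into the mean δ).
* **Pipeline world**: one coherent bundle in which the compendium's
  drug ids coincide with the similarity world's compounds, the planted
  inverse drugs sit in the block matched to the focal disease with
  their focal pairs held out of training, and those pairs carry
  elevated literature co-occurrence.

Passing tests on these worlds demonstrates internal consistency —
estimators invert their generators, nulls calibrate, planted truth is
recovered under the stated noise — not performance on real expression
compendia, real chemical similarity, or real literature, all of which
are dirtier in ways the generators deliberately do not model.

## Problem sizes

Simulation-backed checks use 10–20 seeds with 200-drug compendia
(2000-gene universes), 40×16 similarity worlds, and 200-seed synergy
null calibrations; these sizes give stable means for the reported
statistics while keeping any single check in the seconds-to-a-minute
range.

## Known limitations

* The variance shrinkage uses a fixed prior weight, not an estimated
  one; p-values are correspondingly approximate away from the `d0 = 0`
  limit.
* The consensus treats sources as exchangeable rankings; no attempt is
  made to calibrate DGEM scores against SVM margins.
* ZIP is margin-fit only (above); Loewe/Bliss/HSA references and
  toxicity-adjusted scoring are out of scope.
* The ontology model is a tree; multi-parent terms are accepted by the
  similarity code (ancestor closure over a DAG) but never generated.
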