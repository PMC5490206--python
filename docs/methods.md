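# Methods

## Model

The cohort is modeled as a discrete Bayesian network: a DAG G = (V, A) over
the 14 registry variables with one CPT per node, so that
P(V) = ∏_v p(v | pa(v)). All variables are categorical with fixed
vocabularies; `Unknown`/`Undetermined` are ordinary levels, never missing
values — registries tabulate them, and the heuristic can (and does) select
them. Exactly one variable carries the treatment role (T, levels BCS/BCSR).

## Structure learning

Hill climbing from the empty graph: at each step every legal arc addition,
deletion and reversal is scored, and the single move with the largest
improvement is applied; the search stops when no move improves the score.

* **Score.** BIC with natural logs: per family, the maximized multinomial
  log-likelihood minus (ln n / 2) · (r − 1) · q free parameters, where r is
  the child's cardinality and q the product of the parent cardinalities
  (schema cardinalities, not observed ones). BDeu with equivalent sample
  size 1 is available as an alternative. Both are decomposable, so moves are
  scored by re-evaluating only the affected family, with per-family caching.
* **Determinism.** Ties in score improvement are broken lexicographically by
  (move type: add < delete < reverse, parent name, child name). Given the
  data, the search is fully deterministic; the `seed` argument only feeds
  the bootstrap resampling.
* **Model averaging.** Nonparametric bootstrap: resample n records with
  replacement, re-run the search, record arcs. An undirected pair is kept
  when its replicate frequency reaches the strength threshold (default
  0.25, the conventional value for this workflow; default 1000 replicates),
  oriented by majority direction. If majority orientation creates a cycle,
  the weakest retained arc is dropped repeatedly until the graph is acyclic
  (the averaging literature leaves cyclicity handling open; this is the
  simplest monotone repair).
* **Known limitation.** Greedy ascent cannot enter a pure-XOR collider
  (both parents marginally independent of the child): no single arc
  improves the score, so the search stays at the empty graph even though
  the collider scores far higher. The test suite documents this blind spot
  explicitly; it is a property of single-move hill climbing, not of the
  implementation.

## CPT estimation

Each CPT row is (count + c) / (row total + c·k) with pseudo-count c
(default 1, Laplace). The default is deliberate: several strata in the
registry table have single-digit counts (age `Unknown` has one patient), and
unsmoothed rows would make conditioning on them impossible and corrupt the
heuristic's differences. c = 0 gives maximum-likelihood fitting; unseen
parent configurations then fall back to uniform rows so CPTs remain
distributions.

## Inference

Exact variable elimination with a greedy smallest-intermediate-factor order.
The 14-node networks here have small treewidth, so exact inference is cheap;
no approximate scheme is provided. Evidence with zero probability raises an
error rather than returning a uniform fallback — a silent fallback would
corrupt the heuristic's signed differences. Treatment prediction conditions
on all 13 non-treatment variables by default and breaks exact posterior ties
toward BCSR; an exclusion option exists because willingness (W) is nearly
deterministic given the treatment (every `Declined` patient received BCS)
and effectively leaks the label.

## The zoom-in heuristic

The conditioning set v* grows one (variable, category) per iteration. The
decision statistic is the **signed** difference
P(C = c | S = s, T = target, v*) − P(C = c | S = s, T = other, v*),
required to exceed the tolerance (default 0.04) in every stage of the stage
set; candidates are ranked by the minimum difference across stages, with
lexicographic (variable, category) tie-breaks. The signed rule is a
deliberate reading: an absolute rule would select categories that
characterize the *other* treatment's group (stage-0 grades II and III
differ by more than 0.04 in absolute value but favor BCSR), contradicting
the published selections the stubs reproduce; the signed rule reproduces
all of them. The first iteration scans clinical variables only — they
should be the leading determinants of treatment — later iterations scan
clinical and non-clinical variables alike. The stage and treatment
variables are never scan candidates, and a selected variable is never
rescanned, so a run terminates after at most 12 iterations.

Branching keeps the first k selections, substitutes a manually chosen
condition, and resumes; a resumed iteration always scans all variables
(the clinical-only restriction applies only to a run's very first scan).
Stage-controlled runs filter the cohort to one stage, drop the now-constant
stage variable from the schema, refit structure and CPTs on the subset, and
run the heuristic with no stage conditioning in the queries.

An inference backend abstraction makes fitted networks and fixed tables of
published conditional probabilities interchangeable. The table backend
answers only the queries its tables cover and returns nothing for the rest,
so the heuristic silently skips uncovered variables — matching how a
published subset of query results behaves. Printed values of `<0.001` are
encoded as 0.0005; they never decide a selection.

## Evaluation

Accuracy, sensitivity and specificity from a standard 2×2 confusion matrix;
the positive class defaults to BCSR (the recommended majority treatment —
the original analyses do not state their positive class). Zero-denominator
metrics are NaN and flagged, never reported as 0. The logistic baseline is
unpenalized maximum likelihood on indicator-coded categories against a
reference level (first category unless specified); aliased columns are
dropped with a warning, and non-convergence (the symptom of perfect
separation) is recorded on the model. Train/test splits are simple random
without stratification, train size = floor(fraction · n), with a mandatory
seed. Note the registry study reports split sizes (8217/3519 of 11736) that
match neither floor nor round of 0.7 · n; the floor rule is this package's
own documented convention rather than a silent match. No significance test
between paired metrics is implemented; the models are compared as point
estimates.

## Synthetic cohorts

The reference network is the published 23-arc Detroit DAG with CPTs built in
three steps:

1. every CPT row starts at the child's registry-table marginal;
2. each parent contributes a multiplicative kernel: where the registry
   table pins the conditional (any variable tabulated against treatment),
   the kernel is the real likelihood ratio P(cat | t)/P(cat) (for the
   treatment node itself this uses P(t | parent)/P(t), equal by Bayes);
   for pairs the table says nothing about, a fixed seeded log-linear
   perturbation with s.d. 0.5 — odds-ratio magnitudes around 1.5–2.5,
   typical of registry covariates — makes every arc detectable at cohort
   scale;
3. iterative proportional adjustment of CPT columns until every
   single-variable marginal is within 0.02 of the registry table (this
   preserves the log-linear interactions while pinning margins; the overall
   BCS rate lands at ≈ 0.211).

The generator emulates the published marginals, the published dependence
*structure*, and realistic dependence *strengths*; it does not emulate the
true joint distribution of the SEER cohort (unpublished), survival
outcomes, or dates. Passing tests therefore demonstrate that the machinery
recovers known structure and planted effects under registry-like
conditions, not that it reproduces region-specific findings from real
microdata.

Planted divergences rescale the CPT of the chosen variable — mass toward
the category on treatment-target rows, away on the others, renormalizing
proportionally — until the exact-query difference reaches delta − 0.02 in
every requested stage; other single-variable marginals move by < 0.05 (in
practice < 0.01). If the treatment is not yet a parent of the variable, the
arc T → child is added first; planting on T or S is an error. A
treatment-null variant of the reference network (T made independent by
replacing its CPT with the marginal and averaging its children's CPTs over
T) provides the background for planted-effect validation, so any divergence
found afterwards is attributable to the plant alone.

## Problem sizes and numerical choices

Validation uses cohorts of 12000–50000 records, 100 bootstrap replicates
for skeleton-recovery checks, 50 random networks (≤ 6 nodes, ≤ 4
categories) for the inference-vs-enumeration oracle at 1e-9, and 100 random
3-variable datasets (n = 2000) for hill-climb optimality against exhaustive
25-DAG enumeration — sizes at which the stochastic checks are stable across
seeds while the whole suite stays fast. CPT rows must sum to 1 within 1e-9;
score improvements below 1e-9 count as no improvement; percentages are
printed to one decimal, rounding half away from zero, matching registry
convention.
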