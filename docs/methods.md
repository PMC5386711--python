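# Methods

`progressionscope` implements the computational workflow used to find
early-lost tumor-suppressor miRNAs in a staged breast-cancer progression
panel, together with a synthetic-data generator that plants known
structure so every stage can be tested by recovery. This note documents
the models, the defaults and their rationale, the numerical conventions,
and what the synthetic experiments do and do not demonstrate.

## The progression design

The expression containers assume an ordered stage design modelled on the
isogenic MCF10A series: normal-like (P) → hyperplasia (NeoT) → atypical
hyperplasia (AT1) → ductal carcinoma in situ (DCIS) → invasive carcinoma
(Ca1d), with replicate libraries per stage. The stage order is
configurable; all downstream semantics ("first altered transition",
"preneoplastic window") are defined relative to that order. The
*preneoplastic window* defaults to the transitions into NeoT and AT1
(transitions 1 and 2). The boundary of "early" is genuinely a modelling
choice — the normal-to-atypia window is the prevention target — so it is
exposed as a parameter rather than hard-coded.

## Trajectory classification

For each feature and each adjacent stage transition *t* we compute

* the log2 fold change `FC_t = mean(log2 x_later) − mean(log2 x_earlier)`
  over replicates, and
* a two-sided equal-variance (Student, not Welch) two-sample t-test on
  the log2 replicate values.

A transition is called **up** when `FC_t ≥ log2(f)` and `p_t < α` with
defaults `f = 1.5`, `α = 0.05`, **down** symmetrically, otherwise
**flat**. Features are then partitioned into

| group | pattern |
|---|---|
| G1 | up at every transition (early, continuous increase) |
| G2 | down at every transition (early, continuous decrease) |
| G3 | up at transition 1, flat afterwards |
| G4 | down at transition 1, flat afterwards |
| none | anything else |

G1/G2 require per-transition significance at *every* step — the strict
reading of "continuous" — because the alternative (monotone means plus a
single first-vs-last test) admits trajectories that stall in the middle.
No multiple-testing correction is applied at this stage; FDR control
enters once, at the integration step, which mirrors the workflow being
modelled.

Numerical conventions: values are log2-transformed with zeros replaced
by 1 before the transform (a pseudocount applied only to zeros keeps the
statistics exactly invariant under global rescaling of a positive
panel). Zero-pooled-variance tests return p = 1 when the group means
agree and p = 0 when they differ, and are logged. Quantile normalization
(mean-of-sorted-values reference, ties resolved by the mean of the
reference values at the tied ranks) is applied before trajectory calls
in the pipeline; it can be disabled.

## miRNA–mRNA integration

The functional-pair discovery has three filters:

1. **Signature.** Genes whose expression rises more than 1.5-fold with
   p < 0.05 between a chosen pair of stages (default: P → DCIS, the
   span over which a repressed miRNA's targets are de-repressed). The
   signature transition is deliberately *not* restricted to adjacent
   stages.
2. **Target-set enrichment.** For each miRNA with predicted targets,
   the overlap *k* between its target set (size *K* in a universe of
   *N* quantified genes) and the signature (size *n*) is scored with
   the upper tail of the hypergeometric distribution,
   `p = P(X ≥ k), X ~ Hypergeom(N, K, n)` — the one-sided Fisher exact
   test — computed by exact summation of the hypergeometric mass
   (log-gamma arithmetic via `scipy.stats.hypergeom.sf`), never a 2×2
   approximation. Benjamini–Hochberg Q-values are computed across all
   miRNAs tested and gated at Q < 0.25. A miRNA with no in-universe
   targets gets p = 1. The universe is the set of genes quantified in
   the mRNA panel; there is no principled external universe at desk
   scale, and the enrichment is monotone in N, so this conservative
   in-panel choice is declared rather than tuned.
3. **Inverse correlation.** Candidate genes must anticorrelate with the
   miRNA across the progression: Pearson r on the 5 per-stage means
   (matching the stage-level resolution of the design, not replicate
   level), retained when r < 0 and the BH-adjusted correlation p-value
   is below 0.25.

Surviving genes (signature ∩ predicted targets ∩ anticorrelated) are
ranked by the magnitude of the signature-transition fold change, ties
broken lexicographically for determinism. The enrichment gate is applied
first and the anticorrelation set intersected afterwards; the two orders
give the same gene set whenever the miRNA passes the gate, and the
gate-first order avoids computing correlations for miRNAs that can never
report.

Note on BH: adjusted values are `Q_(i) = min_{j≥i} m·p_(j)/j` (capped at
1). BH adjustment is *not* idempotent — re-adjusting the Q-vector
generally inflates tied small values (e.g. (0.01, 0.02, 0.04) →
(0.03, 0.03, 0.04) → (0.04, 0.04, 0.04)) — so Q-values must be computed
from raw p-values exactly once.

## Survival stratification

The cohort is split at the sample median of expression; ties at the
median go to the **low** group (an exact 50/50 split is impossible under
ties, so the rule is declared for determinism). Each group's survival
function is the product-limit estimator
`S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)` (delegated to
`lifelines.KaplanMeierFitter`), with median survival defined as the
smallest t with S(t) ≤ 0.5 and undefined when the curve never reaches
0.5. The two groups are compared with the two-sample log-rank test,
implemented directly so that per-group observed/expected events and the
hypergeometric variance are available: at each distinct event time, with
n at risk (n_A in group A) and d events,
`E_A += d·n_A/n` and `V += d(n_A/n)(n_B/n)(n−d)/(n−1)`;
`χ² = (O_A − E_A)²/V` on 1 df. The implementation is cross-checked
against `lifelines.statistics.logrank_test` in the test suite. No
covariate adjustment is performed anywhere. When no event time has
subjects of both groups at risk, V = 0 and p = 1 with a warning.

## Methylation summaries

The methylation panel holds per-CpG percent methylation (pyrosequencing
scale, 0–100) for a 16-CpG promoter region in two sub-regions, CpG1–7
and CpG8–16. Region means average replicates (passages) per CpG first,
then CpGs, so unequal passage counts cannot bias a region. The 16-CpG
mean is therefore always the 7/16–9/16 weighted mix of the two region
means. The methylation–expression correlation is computed on the 5
stage-level points (the resolution at which the trend is defined);
both the signed r and |r| are reported because "inverse correlation"
reporting conventions differ on the sign. The response to a
demethylating agent is the simple percent change
`100·(treated − vehicle)/vehicle` of the normalized expression level.

## In-vitro quantification

Relative expression uses the classic 2^−ΔΔCt model with amplification
efficiency fixed at 2: per sample ΔCt = Ct(target) − Ct(reference);
ΔΔCt = mean ΔCt(treated) − mean ΔCt(control); fold = 2^−ΔΔCt, control
≡ 1. Significance is a two-sided equal-variance t-test on the replicate
ΔCt values (not on folds, whose distribution is skewed). The package
ships the published 14-gene mimic-response table
(`progressionscope/data/mir29c_mimic_qpcr.tsv`) as input data for the
repression filter: genes with fold < 1 and the significance flag set
(9 of the 14). Ki67 scoring counts a cell proliferative at ≥ 3 nuclear
foci; colony counting requires strictly more than 50 cells ("more than
50" read as a strict inequality); dual-luciferase activity is
firefly/renilla rescaled so the scramble-control condition equals 1.

## The synthetic generator

The generator's defaults are the study conditions, not free dials:

* 5 stages × 3 replicates (a typical sequencing/qPCR design; replicate
  counts are not part of the published design and are declared here),
  200 miRNAs, 2000 mRNAs, base expression lognormally spread around 100.
* **Trajectories**: a planted group multiplies (G1) or divides (G2) the
  stage mean by `effect_size` (default 2) at every transition, or at the
  first transition only (G3/G4). Replicate noise is multiplicative
  lognormal with unit mean and CV `noise_cv` (default 0.1), so log2 fold
  changes are additive and values stay positive.
* **Regulation**: one planted regulator (the miR-29c role) drawn from
  the Group-2 miRNAs; its 35 true-target mRNAs follow the exact inverse
  (continuously rising) trajectory. The prediction table contains every
  true edge plus Bernoulli decoy edges at rate 0.02 per (miRNA, gene)
  pair, never duplicating a true edge.
* **Survival**: an n = 80 cohort with lognormal expression and
  exponential event times; the below-median half's hazard is multiplied
  by the hazard ratio. Defaults — baseline hazard ln 2/95 per month and
  hazard ratio 95/60 — make the planted group medians 60 and 95 months.
  Censoring defaults to none (keeping the closed-form exponential
  median checks exact); an administrative-censoring rate knob exists.
* **Methylation**: per-region per-stage target percents
  (CpG1–7: 15/26/26/56/30; CpG8–16: 70/96/96/96/96 across
  P/NeoT/AT1/DCIS/Ca1d — the pooled "preneoplastic" value assigned to
  both NeoT and AT1), Gaussian noise (sd 2), two passages, clipped to
  [0, 100] with logging. Explicit stage tables are used instead of a
  parametric (e.g. logistic) trend because the non-monotone CpG1–7
  profile cannot be matched exactly by a monotone curve and the
  zero-noise fixture is required to reproduce these summaries exactly.
* **qPCR fixtures**: the treated arm's target Ct is shifted by
  −log2(fold) against a flat reference gene, so the expected 2^−ΔΔCt
  equals the requested fold exactly at zero noise.

One global seed fans out into independent named substreams (expression,
groups, predictions, survival, methylation, qPCR), so regenerating one
component never perturbs another and everything is bit-reproducible.

## What the recovery experiments show — and what they do not

* *Trajectory recovery* (400 features, 60% planted, CV 0.1): the
  classifier recovers planted labels with sensitivity and specificity
  above 0.9, and perfectly at zero noise. This validates the decision
  rules, not their behaviour on real sequencing data, where dispersion
  is feature-dependent, counts are discrete, and trajectories are not
  clean step patterns.
* *Regulator recovery* (200 miRNAs, 2000 genes, 35 true in-signature
  targets, 2% decoys, 20 seeds): the planted regulator attains the
  smallest Q and passes Q < 0.25 in ≥ 95% of runs. Real prediction
  tables have heavy-tailed target-set sizes and correlated decoys; the
  Bernoulli decoy model does not emulate that.
* *Log-rank calibration* (1000 cohorts of n = 80): empirical type-I
  error at α = 0.05 falls in [0.03, 0.07] and power at hazard ratio 2.5
  exceeds 0.8. Exponential times with a sharp two-group hazard are an
  idealisation of patient cohorts.
* The published census counts (e.g. "299 of 561"), the specific 5-miRNA
  and 35-gene lists, the 60/95-month cohort medians with p = 0.037, and
  the r = 0.69 methylation correlation depend on external datasets and
  operational thresholds that are not available here; the pipeline
  reproduces the *procedures* and demonstrates them on planted truth,
  not those exact numbers.

## Problem sizes

The default demo and test configurations (panels up to 2000 × 15, 20
recovery seeds, 1000 Monte-Carlo cohorts, n = 2000 for median recovery)
were chosen as the smallest sizes at which the statistical claims above
are stable across seeds; the whole suite and the acceptance script each
run in well under a minute of compute.

## Known limitations

* Transition tests assume homoscedastic log2 replicates (Student t);
  count overdispersion is not modelled.
* The hypergeometric universe is the quantified panel; enrichment
  p-values shift with a different universe choice.
* With a single-transition design (2 stages), "continuous" and
  "early-then-plateau" patterns coincide; the continuous groups win.
* The correlation filter at 5 stage points has little power; it is a
  direction filter more than a significance filter, faithful to the
  workflow it models.
* The command-line `run` report is byte-reproducible only for identical
  package and dependency versions (floating-point formatting is stable
  but not guaranteed across numpy majors).
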