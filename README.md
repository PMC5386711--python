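# progressionscope

Analysis toolkit for staged tumor-progression expression panels, built
around the question: *which miRNAs are lost early — in the preneoplastic
window — and which genes do they de-repress?*

The package targets the kind of study design used for triple-negative
breast cancer with the isogenic MCF10A series, an ordered panel of cell
lines spanning normal-like (P) → hyperplasia (NeoT) → atypical
hyperplasia (AT1) → ductal carcinoma in situ (DCIS) → invasive carcinoma
(Ca1d), profiled for miRNA and mRNA expression with replicates. It is
aimed at computational biologists who want the full workflow — from raw
expression tables to a ranked candidate-target list — as tested,
reusable library code rather than a one-off analysis script.

## What it computes

**Trajectory classification.** At every adjacent stage transition each
feature gets a log2 fold change and an equal-variance t-test on log2
replicates; a transition is *up* if FC ≥ log2(1.5) and p < 0.05 (*down*
symmetric, else *flat*). Features are partitioned into four progression
groups — continuous increase (G1), continuous decrease (G2), early
increase then plateau (G3), early decrease then plateau (G4) — or
*none*, and a census reports what fraction of altered features first
changed in the preneoplastic window (transitions into NeoT/AT1).

**miRNA–mRNA integration.** A gene signature (e.g. up > 1.5-fold,
p < 0.05 from P to DCIS) is tested per miRNA for over-representation of
predicted targets: with *k* of the miRNA's *K* in-universe targets in a
signature of size *n* drawn from *N* genes,

    p = P(X ≥ k),  X ~ Hypergeometric(N, K, n)

(the one-sided Fisher exact test), with Benjamini–Hochberg Q-values
gated at Q < 0.25. Gated miRNAs are intersected with an
inverse-correlation filter (Pearson r < 0 across the stage means,
BH-adjusted p < 0.25) to yield a fold-change-ranked candidate list.

**Survival stratification.** A cohort is median-split on expression
(ties to the low group), each half gets a Kaplan–Meier curve
`S(t) = Π (1 − d_i/n_i)` with median survival = smallest t with
S(t) ≤ 0.5, and the halves are compared with the two-sample log-rank
test, χ² = (O_A − E_A)²/V on 1 df.

**Methylation trends.** Per-stage means for a 16-CpG promoter panel in
the regions CpG1–7, CpG8–16 and all 16 sites, the Pearson correlation
between stage-level methylation and expression, and the percent change
of expression after a demethylating agent.

**In-vitro quantification.** 2^−ΔΔCt relative expression with t-tests
on replicate ΔCt, the repressed-gene filter (fold < 1 and significant),
the Ki67 proliferation index (≥ 3 foci), colony counts (> 50 cells) and
renilla-normalized dual-luciferase activity.

Every input can be produced by the built-in synthetic generator, which
plants known trajectory groups, a known regulator with anti-monotone
targets, a known survival hazard structure and a known methylation
trend, so each stage is testable by recovery against ground truth.

## Worked example

Generate a small synthetic study (60 miRNAs, 500 genes, one planted
down-regulated regulator) and run the full pipeline:

```python
from progressionscope import SyntheticConfig
SyntheticConfig(n_mirnas=60, n_mrnas=500, seed=7).to_file("demo.yaml")
```

```
$ progressionscope run --config demo.yaml --out demo_out
{
  "n_early": 15,
  "n_altered": 16,
  "preneoplastic_fraction": 0.9375,
  "down_mirnas_group2_4": ["miR-0006", "miR-0018", "miR-0020", "miR-0044", "miR-0047"],
  "planted_regulators": ["miR-0006"],
  "signature_size": 83,
  "top_enriched_mirna": "miR-0006",
  "top_enriched_q": 4.5207740373940763e-20,
  "n_candidate_targets": 30,
  "km_median_low": 45.88478542861894,
  "km_median_high": 53.60475412141685,
  "logrank_chi_square": 0.12824123839262788,
  "logrank_p": 0.7202625982225257,
  "methylation_expression_r": -0.9114906162541709,
  "n_repressed_genes": 9,
  "repressed_genes": ["AKT3", "CDK6", "CREB5", "E2F7", "FOS", "LAMC2", "MAP2K6", "SPRY4", "TGIF2"]
}
```

Reading the report: 15 of the 16 altered miRNAs first changed in the
preneoplastic window; five miRNAs show the down/early-down patterns
(groups G2/G4) of a candidate tumor suppressor, and the target-set
enrichment singles out the planted regulator `miR-0006` (Q ≈ 5·10⁻²⁰ —
the only G2/G4 miRNA passing the Q < 0.25 gate), with 30 of its
candidate targets surviving the signature ∩ prediction ∩
anticorrelation filters. The survival split of this small (n = 80)
cohort is not significant at this hazard ratio (log-rank p = 0.72) —
see the calibration experiments for the test's size and power — while
stage-level methylation of the promoter panel anticorrelates strongly
with the regulator's expression (r = −0.91). The repression filter
applied to the bundled 14-gene mimic-response qPCR table identifies its
9 significantly repressed targets.

Each stage can also be run separately on the written TSVs
(`progressionscope generate|trajectory|integrate|survival|methylation|quantify`),
or from Python via `progressionscope.trajectory`,
`progressionscope.integration`, `progressionscope.survival`,
`progressionscope.methylation` and `progressionscope.quant`.

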