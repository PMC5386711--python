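"""End-to-end orchestration: generate → normalize → classify → integrate →
survive → methylate → quantify, with a machine-readable run report.

The pipeline consumes one :class:`~progressionscope.config.SyntheticConfig`
(from YAML/JSON or in memory), writes every stage output as TSV under an
output directory, and returns a self-contained JSON-serialisable report
with the headline numbers: the preneoplastic census, the down-regulated
(Group 2/4) miRNAs, the top enriched miRNA and its candidate target list,
the survival stratification, the methylation–expression correlation and
the repressed-gene count of the published mimic experiment.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from . import integration, methylation, quant, survival, synthetic, trajectory
from .config import SyntheticConfig

logger = logging.getLogger(__name__)

SIGNATURE_FROM_STAGE_INDEX = 0  # normal-like baseline
SIGNATURE_TO_STAGE_INDEX = 3  # DCIS in the default design


def run_pipeline(
    config: SyntheticConfig | str | Path,
    out_dir: str | Path,
    q_threshold: float = integration.DEFAULT_Q_THRESHOLD,
    signature_fc: float = trajectory.DEFAULT_FC_THRESHOLD,
    signature_p: float = trajectory.DEFAULT_P_THRESHOLD,
    normalize: bool = True,
) -> dict:
    """Run every stage on one generated study and write outputs + report."""
    if not isinstance(config, SyntheticConfig):
        config = SyntheticConfig.from_file(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "outputs": {}, "headline": {}}

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    def _done(name, t0):
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    def _write(name, obj, fname):
        path = out / fname
        obj.to_tsv(path)
        report["outputs"][name] = fname

    # -- generate ----------------------------------------------------------
    t0 = _stage("generate")
    mirna_panel, mrna_panel, truth = synthetic.gen_progression_expression(config)
    predictions = synthetic.gen_target_predictions(truth, config)
    cohort = synthetic.gen_survival_cohort(config)
    methyl_panel = synthetic.gen_methylation_panel(config)
    _write("mirna_panel", mirna_panel, "mirna_panel.tsv")
    _write("mrna_panel", mrna_panel, "mrna_panel.tsv")
    _write("predictions", predictions, "predictions.tsv")
    _write("survival_cohort", cohort, "survival_cohort.tsv")
    _write("methylation_panel", methyl_panel, "methylation_panel.tsv")
    truth.to_json(out / "ground_truth.json")
    report["outputs"]["ground_truth"] = "ground_truth.json"
    _done("generate", t0)

    # -- normalize + trajectories -----------------------------------------
    t0 = _stage("trajectory")
    if normalize:
        mirna_panel = trajectory.quantile_normalize(mirna_panel)
        mrna_panel = trajectory.quantile_normalize(mrna_panel)
    mirna_stats = trajectory.transition_stats(mirna_panel, signature_fc, signature_p)
    mirna_calls = trajectory.classify_trajectory(mirna_stats)
    _write("mirna_transition_stats", mirna_stats, "mirna_transition_stats.tsv")
    _write("mirna_trajectory_calls", mirna_calls, "mirna_trajectory_calls.tsv")
    n_early, n_altered, fraction = trajectory.preneoplastic_census(mirna_calls)
    down_mirnas = mirna_calls.members("G2", "G4")
    _done("trajectory", t0)

    # -- signature + integration ------------------------------------------
    t0 = _stage("integration")
    stages = list(config.stage_labels)
    signature = integration.extract_signature(
        mrna_panel,
        stages[SIGNATURE_FROM_STAGE_INDEX],
        stages[min(SIGNATURE_TO_STAGE_INDEX, len(stages) - 1)],
        fc_threshold=signature_fc,
        p_threshold=signature_p,
        direction="up",
    )
    universe = frozenset(mrna_panel.features)
    enrichment = integration.fisher_enrichment(signature, predictions, universe)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t")
    report["outputs"]["enrichment"] = "enrichment.tsv"
    top_mirna = enrichment["Q"].idxmin() if len(enrichment) else None
    candidates = None
    if top_mirna is not None:
        profile = mirna_panel.stage_means().loc[top_mirna]
        anticorr = integration.anticorrelation_filter(
            profile, mrna_panel, signature.genes, q_threshold
        )
        candidates = integration.candidate_targets(
            top_mirna, signature, predictions, anticorr, enrichment, q_threshold
        )
        candidates.to_csv(out / "candidate_targets.tsv", sep="\t")
        report["outputs"]["candidate_targets"] = "candidate_targets.tsv"
    _done("integration", t0)

    # -- survival ----------------------------------------------------------
    t0 = _stage("survival")
    strat = survival.stratified_km(cohort)
    strat["km_low"].to_tsv(out / "km_low.tsv")
    strat["km_high"].to_tsv(out / "km_high.tsv")
    report["outputs"]["km_low"] = "km_low.tsv"
    report["outputs"]["km_high"] = "km_high.tsv"
    _done("survival", t0)

    # -- methylation -------------------------------------------------------
    t0 = _stage("methylation")
    regions = methylation.region_means(methyl_panel)
    regions.to_csv(out / "methylation_region_means.tsv", sep="\t")
    report["outputs"]["methylation_region_means"] = "methylation_region_means.tsv"
    methyl_corr = None
    if top_mirna is not None:
        methyl_corr = methylation.methylation_expression_correlation(
            regions["CpG1-16"],
            mirna_panel.stage_means().loc[top_mirna, regions.index],
        )
    _done("methylation", t0)

    # -- in-vitro quantification ------------------------------------------
    t0 = _stage("quantify")
    published = quant.load_mimic_response_table()
    n_repressed, repressed_genes = quant.count_repressed(published)
    ct = synthetic.gen_qpcr_fixture(published["treated_fold"].to_dict(), config)
    folds = quant.fold_table(ct, list(published.index))
    folds.to_csv(out / "qpcr_folds.tsv", sep="\t")
    report["outputs"]["qpcr_folds"] = "qpcr_folds.tsv"
    _done("quantify", t0)

    # -- headline numbers --------------------------------------------------
    lr = strat["logrank"]
    report["headline"] = {
        "n_early": n_early,
        "n_altered": n_altered,
        "preneoplastic_fraction": fraction,
        "down_mirnas_group2_4": down_mirnas,
        "planted_regulators": truth.regulators,
        "signature_size": len(signature),
        "top_enriched_mirna": top_mirna,
        "top_enriched_q": float(enrichment.loc[top_mirna, "Q"]) if top_mirna else None,
        "n_candidate_targets": int(len(candidates)) if candidates is not None else 0,
        "km_median_low": strat["km_low"].median,
        "km_median_high": strat["km_high"].median,
        "logrank_chi_square": lr.chi_square,
        "logrank_p": lr.p_value,
        "methylation_expression_r": methyl_corr["r"] if methyl_corr else None,
        "n_repressed_genes": n_repressed,
        "repressed_genes": repressed_genes,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report["outputs"]["report"] = "report.json"
    return report
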