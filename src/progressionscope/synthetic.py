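"""Synthetic study generator with planted ground truth.

Every input of the analysis pipeline can be generated here with the
statistical structure the downstream methods assume:

* staged miRNA and mRNA expression panels with planted trajectory groups
  (multiplicative fold change per altered transition, lognormal replicate
  noise) and planted regulator→target repression (targets follow the
  inverse of their regulator's trajectory);
* a TargetScan-style prediction table containing every true edge plus
  random decoy edges;
* an exponential-hazard survival cohort whose below-median-expression half
  carries an elevated hazard;
* a 16-CpG promoter methylation panel with a per-region stage trend;
* replicate qPCR Ct fixtures whose expected 2^-ddCt equals requested folds.

All generators are deterministic given the config seed; each draws from
its own substream so components can be regenerated independently.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GROUPS, SyntheticConfig
from .integration import PredictionTable
from .methylation import METHYL_REGIONS_SPAN, MethylationPanel
from .panel import ExpressionPanel, make_panel
from .quant import CtTable
from .survival import SurvivalCohort

logger = logging.getLogger(__name__)

#: Trajectory pattern of each group as the inverse pattern of its mirror.
_INVERSE_GROUP = {"G1": "G2", "G2": "G1", "G3": "G4", "G4": "G3", "none": "none"}


@dataclass
class GroundTruth:
    """What was planted, for recovery testing.

    ``mirna_groups`` / ``mrna_groups`` map every feature to its trajectory
    group; ``true_edges`` is the planted regulator→target set;
    ``mirna_trajectories`` / ``mrna_trajectories`` hold noise-free
    per-stage means; ``survival_hazards`` and ``methyl_trend`` record the
    parameters of the cohort and methylation generators.
    """

    mirna_groups: dict[str, str]
    mrna_groups: dict[str, str]
    true_edges: set[tuple[str, str]] = field(default_factory=set)
    regulators: list[str] = field(default_factory=list)
    mirna_trajectories: pd.DataFrame | None = None
    mrna_trajectories: pd.DataFrame | None = None
    survival_hazards: dict[str, float] = field(default_factory=dict)
    methyl_trend: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def targets_of(self, regulator: str) -> set[str]:
        return {g for m, g in self.true_edges if m == regulator}

    def to_json(self, path) -> None:
        payload = {
            "mirna_groups": self.mirna_groups,
            "mrna_groups": self.mrna_groups,
            "true_edges": sorted(map(list, self.true_edges)),
            "regulators": self.regulators,
            "survival_hazards": self.survival_hazards,
            "methyl_trend": {k: list(v) for k, v in self.methyl_trend.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# expression panels
# ---------------------------------------------------------------------------

def _group_multipliers(group: str, n_stages: int, effect: float) -> np.ndarray:
    """Stage-mean multipliers (relative to stage 1) of one trajectory group."""
    t = np.arange(n_stages, dtype=float)
    if group == "G1":
        return effect ** t
    if group == "G2":
        return effect ** -t
    if group == "G3":
        return np.where(t >= 1, effect, 1.0)
    if group == "G4":
        return np.where(t >= 1, 1.0 / effect, 1.0)
    if group == "none":
        return np.ones(n_stages)
    raise ValueError(f"unknown group {group!r}")


def _allocate_groups(n: int, fractions: dict[str, float], rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder counts per group, randomly placed."""
    counts = {}
    remainders = []
    total = 0
    for g in GROUPS:
        exact = fractions[g] * n
        counts[g] = int(math.floor(exact))
        remainders.append((exact - counts[g], g))
        total += counts[g]
    for _, g in sorted(remainders, reverse=True)[: n - total]:
        counts[g] += 1
    labels = np.concatenate([np.full(counts[g], g, dtype=object) for g in GROUPS])
    rng.shuffle(labels)
    return labels


def _replicate_matrix(
    stage_means: np.ndarray, n_rep: int, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Expand features x stages means into features x samples with noise.

    Noise is multiplicative lognormal with unit mean and the requested
    coefficient of variation, so log2 fold changes stay additive and
    values stay positive.
    """
    n_feat, n_stages = stage_means.shape
    tiled = np.repeat(stage_means, n_rep, axis=1)
    if cv == 0:
        return tiled
    sigma2 = math.log(1.0 + cv**2)
    noise = rng.lognormal(
        mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=(n_feat, n_stages * n_rep)
    )
    return tiled * noise


def gen_progression_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionPanel, ExpressionPanel, GroundTruth]:
    """Generate the staged miRNA and mRNA panels plus ground truth.

    miRNAs get trajectory groups by ``group_fractions``; the first
    ``n_regulators`` Group-2 miRNAs become planted regulators whose
    ``n_true_edges_per_regulator`` target mRNAs follow the inverse
    (rising) trajectory.  Remaining mRNAs get groups by the same
    fractions.  Replicates are stage mean x lognormal noise.
    """
    config.validate()
    rng_groups = config.rng("groups")
    rng_expr = config.rng("expression")
    S, R, e = config.n_stages, config.n_replicates_per_stage, config.effect_size

    mirna_ids = [f"miR-{i+1:04d}" for i in range(config.n_mirnas)]
    mrna_ids = [f"GENE{i+1:05d}" for i in range(config.n_mrnas)]

    mirna_labels = _allocate_groups(config.n_mirnas, config.group_fractions, rng_groups)
    g2_idx = [i for i, g in enumerate(mirna_labels) if g == "G2"]
    if len(g2_idx) < config.n_regulators:
        raise ValueError(
            f"need {config.n_regulators} Group-2 miRNAs to act as regulators, "
            f"only {len(g2_idx)} planted; raise the G2 fraction"
        )
    regulators = [mirna_ids[i] for i in g2_idx[: config.n_regulators]]

    n_targets = config.n_regulators * config.n_true_edges_per_regulator
    if n_targets > config.n_mrnas:
        raise ValueError("true-target demand exceeds the mRNA universe")
    target_pos = rng_groups.choice(config.n_mrnas, size=n_targets, replace=False)
    mrna_labels = _allocate_groups(config.n_mrnas, config.group_fractions, rng_groups)
    true_edges: set[tuple[str, str]] = set()
    for r_i, reg in enumerate(regulators):
        block = target_pos[
            r_i * config.n_true_edges_per_regulator : (r_i + 1) * config.n_true_edges_per_regulator
        ]
        for j in block:
            mrna_labels[j] = _INVERSE_GROUP["G2"]  # regulator falls, target rises
            true_edges.add((reg, mrna_ids[j]))

    def build(ids, labels, rng):
        base = config.base_expression * 2.0 ** rng.normal(0.0, 1.0, size=len(ids))
        means = np.stack(
            [base[i] * _group_multipliers(g, S, e) for i, g in enumerate(labels)]
        )
        matrix = _replicate_matrix(means, R, config.noise_cv, rng)
        stage_of_sample = [s for s in config.stage_labels for _ in range(R)]
        panel = make_panel(matrix, ids, stage_of_sample, config.stage_labels)
        trajectories = pd.DataFrame(means, index=ids, columns=list(config.stage_labels))
        return panel, trajectories

    mirna_panel, mirna_traj = build(mirna_ids, mirna_labels, rng_expr)
    mrna_panel, mrna_traj = build(mrna_ids, mrna_labels, rng_expr)

    truth = GroundTruth(
        mirna_groups=dict(zip(mirna_ids, mirna_labels)),
        mrna_groups=dict(zip(mrna_ids, mrna_labels)),
        true_edges=true_edges,
        regulators=regulators,
        mirna_trajectories=mirna_traj,
        mrna_trajectories=mrna_traj,
        survival_hazards={
            "high": config.survival_baseline_hazard,
            "low": config.survival_baseline_hazard * config.survival_hazard_ratio,
        },
        methyl_trend=dict(config.methyl_trend),
    )
    return mirna_panel, mrna_panel, truth


# ---------------------------------------------------------------------------
# prediction table
# ---------------------------------------------------------------------------

def gen_target_predictions(truth: GroundTruth, config: SyntheticConfig) -> PredictionTable:
    """True edges plus Bernoulli decoy edges at ``decoy_edge_rate``.

    Decoys never duplicate a true edge, so the table holds unique pairs by
    construction and equals the true edge set when the decoy rate is 0.
    """
    if not 0 <= config.decoy_edge_rate <= 1:
        raise ValueError("decoy_edge_rate must be in [0, 1]")
    rng = config.rng("predictions")
    mirnas = sorted(truth.mirna_groups)
    genes = sorted(truth.mrna_groups)
    pairs = [(m, g) for m, g in sorted(truth.true_edges)]
    if config.decoy_edge_rate > 0:
        draw = rng.random((len(mirnas), len(genes))) < config.decoy_edge_rate
        true_lookup = truth.true_edges
        for i, m in enumerate(mirnas):
            for j in np.nonzero(draw[i])[0]:
                edge = (m, genes[j])
                if edge not in true_lookup:
                    pairs.append(edge)
    return PredictionTable(pairs)


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def gen_survival_cohort(config: SyntheticConfig) -> SurvivalCohort:
    """Exponential-hazard cohort tied to a continuous expression marker.

    Expression is lognormal; the below-median half of the cohort has its
    hazard multiplied by ``survival_hazard_ratio`` (so low expression of a
    tumor suppressor shortens survival).  With ``survival_censor_rate`` > 0
    the longest-followed fraction is administratively censored at the
    empirical (1 - rate) quantile of the drawn times.
    """
    if config.survival_n < 4:
        raise ValueError("survival_n must be >= 4")
    if config.survival_hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    rng = config.rng("survival")
    n = config.survival_n
    expression = rng.lognormal(mean=3.0, sigma=0.8, size=n)
    med = np.median(expression)
    low = expression <= med
    hazard = np.where(
        low,
        config.survival_baseline_hazard * config.survival_hazard_ratio,
        config.survival_baseline_hazard,
    )
    times = rng.exponential(1.0 / hazard)
    events = np.ones(n, dtype=int)
    if config.survival_censor_rate > 0:
        cutoff = np.quantile(times, 1.0 - config.survival_censor_rate)
        censored = times > cutoff
        times = np.minimum(times, cutoff)
        events[censored] = 0
    data = pd.DataFrame(
        {
            "sample_id": [f"S{i+1:04d}" for i in range(n)],
            "time_months": times,
            "event": events,
            "expression": expression,
        }
    )
    return SurvivalCohort(data)


# ---------------------------------------------------------------------------
# methylation panel
# ---------------------------------------------------------------------------

def gen_methylation_panel(config: SyntheticConfig) -> MethylationPanel:
    """16-CpG promoter panel following the per-region stage trends.

    Each CpG of a region tracks its region's per-stage target percent plus
    Gaussian noise (sd ``methyl_noise_sd``), measured over
    ``methyl_n_passages`` passages, clipped to [0, 100] (clipping is
    logged).
    """
    rng = config.rng("methylation")
    rows = []
    clipped = 0
    for region, trend in config.methyl_trend.items():
        lo, hi = METHYL_REGIONS_SPAN[region]
        for s_i, stage in enumerate(config.stage_labels):
            for cpg in range(lo, hi + 1):
                for rep in range(1, config.methyl_n_passages + 1):
                    value = trend[s_i]
                    if config.methyl_noise_sd > 0:
                        value += rng.normal(0.0, config.methyl_noise_sd)
                    if not 0.0 <= value <= 100.0:
                        clipped += 1
                        value = min(max(value, 0.0), 100.0)
                    rows.append((stage, cpg, rep, value))
    if clipped:
        logger.warning("clipped %d methylation values into [0, 100]", clipped)
    data = pd.DataFrame(rows, columns=["stage", "cpg_index", "replicate", "percent"])
    return MethylationPanel(data=data, stage_order=config.stage_labels)


# ---------------------------------------------------------------------------
# qPCR fixtures
# ---------------------------------------------------------------------------

def gen_qpcr_fixture(
    effects: dict[str, float], config: SyntheticConfig, reference_gene: str = "RNU44"
) -> CtTable:
    """Replicate Ct values whose expected 2^-ddCt equals the requested folds.

    The treated arm's target Ct is shifted by ``-log2(fold)`` relative to
    control (repression raises the Ct); the reference gene is flat across
    arms.  Gaussian Ct noise with sd ``qpcr_noise_sd`` is added per well.
    """
    for gene, fold in effects.items():
        if fold <= 0:
            raise ValueError(f"fold for {gene!r} must be positive")
    rng = config.rng("qpcr")
    rows = []
    for arm in ("control", "treated"):
        for rep in range(1, config.qpcr_n_replicates + 1):
            sample = f"{arm}_rep{rep}"
            rows.append((sample, arm, reference_gene, config.qpcr_reference_ct))
            for gene, fold in sorted(effects.items()):
                ct = config.qpcr_target_ct
                if arm == "treated":
                    ct -= math.log2(fold)
                rows.append((sample, arm, gene, ct))
    data = pd.DataFrame(rows, columns=["sample_id", "arm", "gene_id", "ct"])
    if config.qpcr_noise_sd > 0:
        data["ct"] = data["ct"] + rng.normal(0.0, config.qpcr_noise_sd, size=len(data))
    return CtTable(data=data, reference_gene=reference_gene)
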