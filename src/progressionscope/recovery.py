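"""Recovery experiments against planted ground truth.

These are the package's calibration harnesses: they generate synthetic
studies with known structure and measure how well each analysis stage
recovers what was planted — trajectory-group sensitivity/specificity,
the enrichment rank of the planted regulator, and the size/power of the
log-rank test under null and alternative hazards.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import integration, survival, synthetic, trajectory
from .config import SyntheticConfig


@dataclass
class TrajectoryRecovery:
    sensitivity: float  # planted G1-G4 features called with their planted label
    specificity: float  # planted flat features called "none"
    n_planted: int
    n_flat: int


def trajectory_recovery(config: SyntheticConfig) -> TrajectoryRecovery:
    """Classify a generated miRNA panel and score recovery of planted labels."""
    mirna_panel, _, truth = synthetic.gen_progression_expression(config)
    stats = trajectory.transition_stats(mirna_panel)
    calls = trajectory.classify_trajectory(stats).calls["group"]
    planted = truth.mirna_groups
    grouped = [f for f, g in planted.items() if g != "none"]
    flat = [f for f, g in planted.items() if g == "none"]
    if not grouped or not flat:
        raise ValueError("config must plant both grouped and flat features")
    sens = float(np.mean([calls[f] == planted[f] for f in grouped]))
    spec = float(np.mean([calls[f] == "none" for f in flat]))
    return TrajectoryRecovery(sens, spec, len(grouped), len(flat))


RECOVERY_GROUP_FRACTIONS = {"G1": 0.15, "G2": 0.15, "G3": 0.15, "G4": 0.15, "none": 0.40}


def trajectory_recovery_config(seed: int, noise_cv: float = 0.1) -> SyntheticConfig:
    """Study conditions of the trajectory-recovery experiment.

    Two-fold change per altered transition, triplicates, 10% replicate CV,
    400 features with 60% planted into the four groups.
    """
    return SyntheticConfig(
        n_mirnas=400,
        n_mrnas=50,
        n_true_edges_per_regulator=5,
        group_fractions=dict(RECOVERY_GROUP_FRACTIONS),
        effect_size=2.0,
        noise_cv=noise_cv,
        seed=seed,
    )


@dataclass
class IntegrationRecovery:
    planted_regulator: str
    planted_q: float
    planted_is_top: bool
    n_signature: int
    n_mirnas_tested: int


def integration_recovery_config(seed: int) -> SyntheticConfig:
    """Study conditions of the regulator-recovery experiment.

    200 miRNAs, a 2000-gene universe, one planted regulator with 35
    rising true targets, decoy prediction edges at rate 0.02.
    """
    return SyntheticConfig(
        n_mirnas=200,
        n_mrnas=2000,
        n_regulators=1,
        n_true_edges_per_regulator=35,
        decoy_edge_rate=0.02,
        noise_cv=0.1,
        seed=seed,
    )


def integration_recovery(config: SyntheticConfig) -> IntegrationRecovery:
    """Signature extraction + enrichment; does the planted regulator win?

    The signature is the up-regulated gene set over the normal-like → DCIS
    transition; the planted regulator "wins" when it attains the smallest
    Q-value of all miRNAs tested.
    """
    _, mrna_panel, truth = synthetic.gen_progression_expression(config)
    predictions = synthetic.gen_target_predictions(truth, config)
    stages = list(config.stage_labels)
    signature = integration.extract_signature(mrna_panel, stages[0], stages[3])
    enrichment = integration.fisher_enrichment(
        signature, predictions, frozenset(mrna_panel.features)
    )
    reg = truth.regulators[0]
    return IntegrationRecovery(
        planted_regulator=reg,
        planted_q=float(enrichment.loc[reg, "Q"]),
        planted_is_top=enrichment["Q"].idxmin() == reg,
        n_signature=len(signature),
        n_mirnas_tested=len(enrichment),
    )


def integration_recovery_rate(
    n_runs: int = 20, base_seed: int = 0, q_threshold: float = 0.25
) -> float:
    """Fraction of seeded runs where the planted regulator attains the
    smallest Q and passes the Q-threshold gate."""
    wins = 0
    for i in range(n_runs):
        r = integration_recovery(integration_recovery_config(base_seed + i))
        wins += r.planted_is_top and r.planted_q < q_threshold
    return wins / n_runs


def logrank_rejection_rate(
    hazard_ratio: float,
    n_cohorts: int = 1000,
    cohort_n: int = 80,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the median-split log-rank test.

    ``hazard_ratio = 1`` measures type-I error; larger ratios measure
    power.  Cohorts are regenerated with consecutive seeds.
    """
    template = SyntheticConfig(survival_n=cohort_n, survival_hazard_ratio=max(hazard_ratio, 1e-9))
    rejections = 0
    for i in range(n_cohorts):
        config = dataclasses.replace(template, seed=base_seed + i)
        cohort = synthetic.gen_survival_cohort(config)
        labels = survival.median_split(cohort)
        d = cohort.data.set_index("sample_id")
        low = d.loc[labels.index[labels == "low"]]
        high = d.loc[labels.index[labels == "high"]]
        result = survival.logrank_test(
            low["time_months"], low["event"], high["time_months"], high["event"]
        )
        rejections += result.p_value < alpha
    return rejections / n_cohorts
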