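"""Configuration for the synthetic progression-study generator.

A single :class:`SyntheticConfig` drives every generator: the staged
expression panels, the target-prediction table, the survival cohort, the
promoter CpG methylation panel and the qPCR fixtures.  One global integer
seed fans out into independent per-generator substreams so components can
be regenerated in isolation without perturbing each other.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .panel import DEFAULT_STAGES

#: Trajectory group labels: G1 up at every transition, G2 down at every
#: transition, G3 up then plateau, G4 down then plateau, none = flat.
GROUPS = ("G1", "G2", "G3", "G4", "none")

#: Default per-region, per-stage percent-methylation targets for the 16-CpG
#: promoter panel (regions CpG1-7 and CpG8-16), calibrated so the
#: noise-free region means equal the reported pyrosequencing averages.
DEFAULT_METHYL_TREND: dict[str, tuple[float, ...]] = {
    "region_1_7": (15.0, 26.0, 26.0, 56.0, 30.0),
    "region_8_16": (70.0, 96.0, 96.0, 96.0, 96.0),
}

@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study, with the study-design defaults.

    Defaults emulate the analysed design: a 5-stage isogenic progression
    panel with triplicate libraries, two-fold change per altered
    transition, one planted down-regulated regulator (the miR-29c role)
    with 35 de-repressed targets, an n=80 survival cohort whose planted
    group medians are 60 vs 95 months, and a 16-CpG methylation panel
    measured over 2 passages.
    """

    n_stages: int = 5
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    n_replicates_per_stage: int = 3
    n_mirnas: int = 200
    n_mrnas: int = 2000
    group_fractions: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.05, "G2": 0.05, "G3": 0.05, "G4": 0.05, "none": 0.80}
    )
    effect_size: float = 2.0
    noise_cv: float = 0.1
    base_expression: float = 100.0
    n_regulators: int = 1
    n_true_edges_per_regulator: int = 35
    decoy_edge_rate: float = 0.02
    survival_n: int = 80
    survival_hazard_ratio: float = 95.0 / 60.0
    survival_baseline_hazard: float = math.log(2) / 95.0  # per month, high group
    survival_censor_rate: float = 0.0
    methyl_trend: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_METHYL_TREND.items()}
    )
    methyl_noise_sd: float = 2.0
    methyl_n_passages: int = 2
    qpcr_reference_ct: float = 18.0
    qpcr_target_ct: float = 24.0
    qpcr_noise_sd: float = 0.0
    qpcr_n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_labels = tuple(self.stage_labels)
        self.methyl_trend = {k: tuple(v) for k, v in self.methyl_trend.items()}
        self.validate()

    def validate(self) -> None:
        if self.n_stages != len(self.stage_labels):
            raise ValueError("n_stages must match the number of stage labels")
        for name in (
            "n_stages",
            "n_replicates_per_stage",
            "n_mirnas",
            "n_mrnas",
            "n_regulators",
            "n_true_edges_per_regulator",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if set(self.group_fractions) != set(GROUPS):
            raise ValueError(f"group_fractions must have exactly the keys {GROUPS}")
        total = sum(self.group_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.group_fractions.values()):
            raise ValueError("group fractions must be non-negative")
        if self.effect_size <= 1:
            raise ValueError("effect_size must be > 1 (linear fold per transition)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise_cv > 0 and self.n_replicates_per_stage < 2:
            raise ValueError(
                "need >= 2 replicates per stage when noise_cv > 0; "
                "downstream t-tests are undefined otherwise"
            )
        if not 0 <= self.decoy_edge_rate <= 1:
            raise ValueError("decoy_edge_rate must be in [0, 1]")
        if self.survival_n < 4:
            raise ValueError("survival_n must be >= 4")
        if self.survival_hazard_ratio <= 0:
            raise ValueError("survival_hazard_ratio must be positive")
        if self.survival_baseline_hazard <= 0:
            raise ValueError("survival_baseline_hazard must be positive")
        if not 0 <= self.survival_censor_rate < 1:
            raise ValueError("survival_censor_rate must be in [0, 1)")
        for region, trend in self.methyl_trend.items():
            if len(trend) != self.n_stages:
                raise ValueError(f"methyl_trend[{region!r}] must have one value per stage")
            if any(not 0 <= v <= 100 for v in trend):
                raise ValueError("methylation trend values must lie in [0, 100]")

    # -- seed fan-out ------------------------------------------------------

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream for one generator component."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, _stream_id(stream)]))

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_labels"] = list(self.stage_labels)
        d["methyl_trend"] = {k: list(v) for k, v in self.methyl_trend.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load from YAML or JSON (YAML is a superset, so one parser does)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_STREAMS = (
    "expression",
    "groups",
    "predictions",
    "survival",
    "methylation",
    "qpcr",
)


def _stream_id(stream: str) -> int:
    try:
        return _STREAMS.index(stream)
    except ValueError:
        raise KeyError(f"unknown generator stream {stream!r}") from None
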