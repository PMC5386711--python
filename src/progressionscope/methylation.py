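"""Promoter CpG methylation summaries across progression stages.

A methylation panel holds pyrosequencing percent-methylation values for a
16-CpG promoter region measured at every stage of the progression series
(optionally over several cell passages).  The analysis summarises region
means (CpG1-7, CpG8-16 and all 16 sites), correlates average methylation
with miRNA expression across the stages, and quantifies the expression
response to a demethylating agent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: CpG spans (1-based, inclusive) of the generator's named trend regions.
METHYL_REGIONS_SPAN: dict[str, tuple[int, int]] = {
    "region_1_7": (1, 7),
    "region_8_16": (8, 16),
}

#: Default CpG regions of the promoter panel (1-based inclusive ranges).
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "CpG1-7": (1, 7),
    "CpG8-16": (8, 16),
    "CpG1-16": (1, 16),
}


@dataclass
class MethylationPanel:
    """Long-form per-CpG percent methylation.

    ``data`` columns: ``stage``, ``cpg_index`` (1..16), ``percent``
    (in [0, 100]) and optionally ``replicate`` (cell passage).
    """

    data: pd.DataFrame
    stage_order: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"stage", "cpg_index", "percent"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"methylation table lacks columns {sorted(missing)}")
        pct = self.data["percent"]
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("percent methylation must lie in [0, 100]")
        keys = ["stage", "cpg_index"] + (
            ["replicate"] if "replicate" in self.data.columns else []
        )
        if self.data.duplicated(subset=keys).any():
            raise ValueError("duplicate (stage, CpG, replicate) measurements")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, stage_order) -> "MethylationPanel":
        return cls(pd.read_csv(path, sep="\t"), tuple(stage_order))


def parse_regions(text: str) -> dict[str, tuple[int, int]]:
    """Parse a region spec like ``"1-7,8-16,1-16"`` into named ranges."""
    regions = {}
    for part in text.split(","):
        lo, hi = (int(x) for x in part.strip().split("-"))
        regions[f"CpG{lo}-{hi}"] = (lo, hi)
    return regions


def region_means(
    panel: MethylationPanel,
    regions: dict[str, tuple[int, int]] = DEFAULT_REGIONS,
) -> pd.DataFrame:
    """Per-stage mean percent methylation for each CpG region.

    Replicates (passages) are averaged per CpG first, then CpGs are
    averaged within the region, so every CpG carries equal weight
    regardless of replicate counts.  Rows are stages in progression order,
    columns are regions.
    """
    per_cpg = (
        panel.data.groupby(["stage", "cpg_index"])["percent"].mean().unstack("cpg_index")
    )
    stages = [s for s in panel.stage_order if s in per_cpg.index]
    per_cpg = per_cpg.loc[stages]
    out = {}
    for name, (lo, hi) in regions.items():
        cols = [c for c in per_cpg.columns if lo <= c <= hi]
        if not cols:
            raise ValueError(f"region {name} ({lo}-{hi}) covers no measured CpGs")
        out[name] = per_cpg[cols].mean(axis=1)
    return pd.DataFrame(out)


def methylation_expression_correlation(
    stage_methylation: pd.Series, stage_expression: pd.Series
) -> dict:
    """Pearson correlation of stage-level methylation vs expression.

    Both series must be aligned on the same stage order.  Returns the
    signed r, its magnitude (the reporting convention when a correlation
    is described as "inverse"), and the two-sided p-value.
    """
    if len(stage_methylation) < 3:
        raise ValueError("need >= 3 stages")
    if list(stage_methylation.index) != list(stage_expression.index):
        raise ValueError("stage order of the two profiles must match")
    x = stage_methylation.to_numpy(float)
    y = stage_expression.to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a profile has zero variance")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "abs_r": float(abs(r)), "p_value": float(p), "n_stages": len(x)}


def demethylation_response(vehicle_level: float, treated_level: float) -> float:
    """Percent change of normalized expression after demethylating treatment.

    ``100 * (treated - vehicle) / vehicle``; a de-repressed gene gives a
    positive percentage.
    """
    if vehicle_level <= 0:
        raise ValueError("vehicle level must be positive")
    return 100.0 * (treated_level - vehicle_level) / vehicle_level
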