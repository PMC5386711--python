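"""Feature-by-sample expression panels with an ordered stage design.

The central container is :class:`ExpressionPanel`: a non-negative,
linear-scale expression matrix (rows = features, columns = samples) together
with a mapping of every sample to one stage of an ordered progression
design.  The default stage order follows the MCF10A-based triple-negative
breast-cancer progression series: normal-like (P), hyperplasia (NeoT),
atypical hyperplasia (AT1), ductal carcinoma in situ (DCIS) and invasive
carcinoma (Ca1d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default ordered stage labels of the MCF10A progression panel.
DEFAULT_STAGES: tuple[str, ...] = ("P", "NeoT", "AT1", "DCIS", "Ca1d")


def sample_id(stage: str, replicate: int) -> str:
    """Encode a sample identifier as ``"<stage>_rep<k>"``."""
    return f"{stage}_rep{replicate}"


@dataclass
class ExpressionPanel:
    """Expression matrix plus stage design.

    Parameters
    ----------
    values
        Features (rows) by samples (columns), linear scale, non-negative.
    stages
        Per-sample stage label, indexed by sample ID, in the order the
        samples appear in ``values``.
    stage_order
        Total order of the stages.  Every entry of ``stages`` must appear
        in it.
    """

    values: pd.DataFrame
    stages: pd.Series
    stage_order: tuple[str, ...] = field(default=DEFAULT_STAGES)

    def __post_init__(self) -> None:
        self.stage_order = tuple(self.stage_order)
        if list(self.values.columns) != list(self.stages.index):
            raise ValueError("sample IDs of values and stages disagree")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature IDs")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        unknown = set(self.stages) - set(self.stage_order)
        if unknown:
            raise ValueError(f"samples mapped to unknown stages: {sorted(unknown)}")

    # -- accessors ---------------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def stages_present(self) -> list[str]:
        present = set(self.stages)
        return [s for s in self.stage_order if s in present]

    def samples_of(self, stage: str) -> list[str]:
        return list(self.stages.index[self.stages == stage])

    def stage_values(self, stage: str) -> pd.DataFrame:
        """Replicate columns belonging to one stage."""
        cols = self.samples_of(stage)
        if not cols:
            raise KeyError(f"stage {stage!r} has no samples")
        return self.values[cols]

    def stage_means(self) -> pd.DataFrame:
        """Per-feature mean over replicates, one column per stage present."""
        return pd.DataFrame(
            {s: self.stage_values(s).mean(axis=1) for s in self.stages_present}
        )

    def transitions(self) -> list[tuple[str, str]]:
        """Adjacent stage pairs, in progression order."""
        present = self.stages_present
        return list(zip(present[:-1], present[1:]))

    # -- IO ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, stage_order: tuple[str, ...] = DEFAULT_STAGES) -> "ExpressionPanel":
        """Read a panel written by :meth:`to_tsv`.

        Sample IDs must follow the ``"<stage>_rep<k>"`` encoding so the
        stage design can be recovered from the header alone.
        """
        values = pd.read_csv(path, sep="\t", index_col="feature_id")
        stages = pd.Series(
            [c.rsplit("_rep", 1)[0] for c in values.columns],
            index=values.columns,
            name="stage",
        )
        return cls(values=values, stages=stages, stage_order=stage_order)


def make_panel(
    matrix: np.ndarray | pd.DataFrame,
    feature_ids,
    stage_of_sample: list[str],
    stage_order: tuple[str, ...] = DEFAULT_STAGES,
) -> ExpressionPanel:
    """Build a panel from a raw matrix and a per-column stage list.

    Replicate indices are assigned per stage in column order.
    """
    counters: dict[str, int] = {}
    ids = []
    for s in stage_of_sample:
        counters[s] = counters.get(s, 0) + 1
        ids.append(sample_id(s, counters[s]))
    values = pd.DataFrame(np.asarray(matrix, dtype=float), index=feature_ids, columns=ids)
    stages = pd.Series(stage_of_sample, index=ids, name="stage")
    return ExpressionPanel(values=values, stages=stages, stage_order=stage_order)
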