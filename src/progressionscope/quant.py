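"""In-vitro quantification arithmetic: ddCt folds, Ki67, colonies, luciferase.

Relative expression from qPCR follows the classic 2^-ddCt scheme with an
assumed amplification efficiency of 2: per sample dCt = Ct(target) -
Ct(reference); ddCt = mean dCt(treated) - mean dCt(control); fold =
2^-ddCt, so the control arm is 1.0 by construction.  Significance of a
fold change is an equal-variance two-sided t-test on the replicate dCt
values of the two arms.

The module also scores the simple count-based assays: the Ki67
proliferation index (fraction of cells with at least 3 nuclear foci),
colony counting (colonies of strictly more than 50 cells), and
dual-luciferase reporter normalization (firefly / renilla, rescaled to the
scramble-control condition).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_KI67_THRESHOLD = 3
DEFAULT_COLONY_MIN_CELLS = 50
SIGNIFICANCE_ALPHA = 0.05


@dataclass
class CtTable:
    """Replicate qPCR cycle-threshold records.

    ``data`` columns: ``sample_id``, ``arm`` (treated/control), ``gene_id``
    (targets and the reference gene), ``ct`` (> 0 cycles).
    """

    data: pd.DataFrame
    reference_gene: str = "RNU44"

    def __post_init__(self) -> None:
        required = {"sample_id", "arm", "gene_id", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table lacks columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        bad = set(self.data["arm"]) - {"treated", "control"}
        if bad:
            raise ValueError(f"unknown arms: {sorted(bad)}")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, reference_gene: str = "RNU44") -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference_gene=reference_gene)


@dataclass
class FoldChangeRow:
    """One gene's treated-vs-control relative expression."""

    gene_id: str
    fold: float  # linear scale; control arm == 1.0
    p_value: float | None
    significant: bool


def _delta_ct(ct: CtTable, target: str, reference: str, arm: str) -> np.ndarray:
    d = ct.data[ct.data["arm"] == arm]
    tgt = d[d["gene_id"] == target].set_index("sample_id")["ct"]
    ref = d[d["gene_id"] == reference].set_index("sample_id")["ct"]
    if tgt.empty:
        raise ValueError(f"no Ct values for target {target!r} in arm {arm!r}")
    if not set(tgt.index) <= set(ref.index):
        raise ValueError(f"missing reference-gene Ct for some {arm!r} samples")
    return (tgt - ref.loc[tgt.index]).to_numpy(dtype=float)


def ddct_fold(ct: CtTable, target: str, reference: str | None = None) -> FoldChangeRow:
    """Relative expression (treated vs control) of one target gene.

    With fewer than 2 replicates in either arm the fold is still computed
    but the p-value is undefined (None, flagged non-significant).
    """
    reference = reference or ct.reference_gene
    dct_treated = _delta_ct(ct, target, reference, "treated")
    dct_control = _delta_ct(ct, target, reference, "control")
    ddct = dct_treated.mean() - dct_control.mean()
    fold = float(2.0 ** (-ddct))
    if len(dct_treated) < 2 or len(dct_control) < 2:
        return FoldChangeRow(gene_id=target, fold=fold, p_value=None, significant=False)
    if np.var(dct_treated) == 0 and np.var(dct_control) == 0:
        p = 1.0 if ddct == 0 else 0.0
    else:
        p = float(stats.ttest_ind(dct_treated, dct_control, equal_var=True).pvalue)
    return FoldChangeRow(
        gene_id=target, fold=fold, p_value=p, significant=p < SIGNIFICANCE_ALPHA
    )


def fold_table(ct: CtTable, targets, reference: str | None = None) -> pd.DataFrame:
    """ddCt fold-change rows for many targets, Table-1-style layout."""
    rows = [ddct_fold(ct, t, reference) for t in targets]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "control_fold": 1.0,
            "treated_fold": [r.fold for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
        }
    ).set_index("gene_id")


def count_repressed(rows) -> tuple[int, list[str]]:
    """Significantly repressed genes: fold < 1 with the significance flag set.

    Accepts an iterable of :class:`FoldChangeRow` or a :func:`fold_table`
    frame; returns the count and a lexicographically sorted gene list.
    """
    if isinstance(rows, pd.DataFrame):
        mask = (rows["treated_fold"] < 1.0) & rows["significant"].astype(bool)
        genes = sorted(rows.index[mask])
    else:
        genes = sorted(r.gene_id for r in rows if r.fold < 1.0 and r.significant)
    return len(genes), genes


def load_mimic_response_table() -> pd.DataFrame:
    """The published 14-gene qPCR response to the miR-29c mimic.

    Fold changes of 14 candidate targets in MCF10.AT1 cells 48 h after
    transfection with a miR-29c-3p mimic, relative to a scramble control;
    the ``significant`` column transcribes the published p < 0.05 marks.
    """
    with resources.files("progressionscope.data").joinpath(
        "mir29c_mimic_qpcr.tsv"
    ).open() as fh:
        t = pd.read_csv(fh, sep="\t").set_index("gene_id")
    t["significant"] = t["significant"].astype(bool)
    return t


def ki67_index(foci_counts, positive_threshold: int = DEFAULT_KI67_THRESHOLD) -> float:
    """Fraction of cells scored proliferative (>= threshold nuclear foci)."""
    counts = np.asarray(foci_counts)
    if counts.size == 0:
        raise ValueError("no cells scored")
    if (counts < 0).any():
        raise ValueError("focus counts must be non-negative")
    return float((counts >= positive_threshold).mean())


def colony_count(colony_sizes, min_cells: int = DEFAULT_COLONY_MIN_CELLS) -> int:
    """Number of colonies with strictly more than ``min_cells`` cells."""
    sizes = np.asarray(colony_sizes)
    if (sizes < 0).any():
        raise ValueError("colony sizes must be non-negative")
    return int((sizes > min_cells).sum())


def luciferase_activity(
    firefly, renilla, reference_condition: int | str, conditions=None
) -> pd.Series:
    """Renilla-normalized firefly activity, scaled so the reference is 1.0.

    ``firefly`` and ``renilla`` are aligned per-well signal vectors;
    ``conditions`` labels each well (defaults to positional labels).  The
    mean normalized ratio of ``reference_condition`` defines 1.0.
    """
    ff = np.asarray(firefly, dtype=float)
    rn = np.asarray(renilla, dtype=float)
    if ff.shape != rn.shape:
        raise ValueError("firefly and renilla vectors must align")
    if (rn <= 0).any():
        raise ValueError("renilla signal must be positive")
    if (ff <= 0).any():
        raise ValueError("firefly signal must be positive")
    if conditions is None:
        conditions = list(range(len(ff)))
    ratio = pd.Series(ff / rn, index=pd.Index(conditions, name="condition"))
    per_condition = ratio.groupby(level=0).mean()
    if reference_condition not in per_condition.index:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    return per_condition / per_condition.loc[reference_condition]
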