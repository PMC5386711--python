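"""Stage-transition statistics and progression-group classification.

Given an expression panel over an ordered stage design, each feature is
tested at every adjacent stage transition (equal-variance two-sample t-test
on log2 values, log2 fold change of stage means) and then classified into
one of four progression groups:

* **G1** — significant increase at every transition (early, continuous up)
* **G2** — significant decrease at every transition (early, continuous down)
* **G3** — significant increase at the first transition, flat afterwards
* **G4** — significant decrease at the first transition, flat afterwards
* **none** — any other pattern

A transition is called ``up`` when the log2 fold change reaches
``log2(fc_threshold)`` *and* the t-test p-value is below ``p_threshold``
(``down`` symmetrically); otherwise it is ``flat``.  The census operation
then asks what fraction of all altered features first changed during the
preneoplastic window (by default the transitions into hyperplasia and
atypical hyperplasia).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ExpressionPanel

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_P_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(panel: ExpressionPanel) -> ExpressionPanel:
    """Force every sample onto the common (mean-of-sorted) distribution.

    After normalization each sample's sorted values equal the across-sample
    mean of sorted values; within-sample rank order is preserved.  Tied
    values receive the mean of the reference values at their tied ranks.
    """
    x = panel.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0:
            logger.warning(
                "sample %s is constant; mean-of-tied-ranks rule maps it to the "
                "reference mean", panel.values.columns[j]
            )
        # average rank of each value (1-based); ties share a fractional rank
        ranks = stats.rankdata(col, method="average")
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    values = pd.DataFrame(out, index=panel.values.index, columns=panel.values.columns)
    return ExpressionPanel(values=values, stages=panel.stages, stage_order=panel.stage_order)


# ---------------------------------------------------------------------------
# two-sample statistics on log2 values
# ---------------------------------------------------------------------------

def _log2(values: np.ndarray) -> np.ndarray:
    # pseudocount 1 for zeros only: keeps scale invariance on positive data
    return np.log2(np.where(values > 0, values, 1.0))


def _ttest_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise equal-variance two-sided t-test p-values, b vs a.

    Degenerate rows (zero pooled variance) get p=1 when the means agree and
    p=0 when they differ, by convention.
    """
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per stage for t-tests")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    delta = mb - ma
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    if degenerate.any():
        logger.warning("%d features with zero within-stage variance", int(degenerate.sum()))
        p = np.where(degenerate & (delta == 0), 1.0, p)
        p = np.where(degenerate & (delta != 0), 0.0, p)
    return p


def two_sample_stats(
    earlier: pd.DataFrame, later: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Per-feature (log2 fold change, p-value) of later vs earlier replicates."""
    a = _log2(earlier.to_numpy(dtype=float))
    b = _log2(later.to_numpy(dtype=float))
    fc = pd.Series(b.mean(axis=1) - a.mean(axis=1), index=earlier.index)
    p = pd.Series(_ttest_rows(a, b), index=earlier.index)
    return fc, p


@dataclass
class TransitionStats:
    """Per-feature, per-adjacent-transition differential statistics.

    ``log2_fc``, ``p_value`` and ``direction`` are features x transitions
    frames; transition columns are labelled ``"<from>-><to>"`` in
    progression order.  Directions are ``up`` / ``down`` / ``flat`` per the
    fold-change + significance rule.
    """

    log2_fc: pd.DataFrame
    p_value: pd.DataFrame
    direction: pd.DataFrame
    transitions: list[tuple[str, str]]
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    p_threshold: float = DEFAULT_P_THRESHOLD

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def to_tsv(self, path) -> None:
        rows = []
        for i, (a, b) in enumerate(self.transitions):
            col = self.log2_fc.columns[i]
            rows.append(
                pd.DataFrame(
                    {
                        "feature_id": self.log2_fc.index,
                        "from_stage": a,
                        "to_stage": b,
                        "log2_fc": self.log2_fc[col].to_numpy(),
                        "p_value": self.p_value[col].to_numpy(),
                        "direction": self.direction[col].to_numpy(),
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def _call_direction(fc: np.ndarray, p: np.ndarray, fc_threshold: float, p_threshold: float) -> np.ndarray:
    log_thr = np.log2(fc_threshold)
    sig = p < p_threshold
    out = np.full(fc.shape, "flat", dtype=object)
    out[(fc >= log_thr) & sig] = "up"
    out[(fc <= -log_thr) & sig] = "down"
    return out


def transition_stats(
    panel: ExpressionPanel,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> TransitionStats:
    """Differential statistics at every adjacent stage transition."""
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be a positive linear fold")
    transitions = panel.transitions()
    if not transitions:
        raise ValueError("panel has fewer than 2 stages")
    fcs, ps, dirs = {}, {}, {}
    for a, b in transitions:
        label = f"{a}->{b}"
        fc, p = two_sample_stats(panel.stage_values(a), panel.stage_values(b))
        fcs[label] = fc
        ps[label] = p
        dirs[label] = pd.Series(
            _call_direction(fc.to_numpy(), p.to_numpy(), fc_threshold, p_threshold),
            index=fc.index,
        )
    return TransitionStats(
        log2_fc=pd.DataFrame(fcs),
        p_value=pd.DataFrame(ps),
        direction=pd.DataFrame(dirs),
        transitions=transitions,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
    )


# ---------------------------------------------------------------------------
# trajectory classification
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryCall:
    """Group assignment per feature.

    ``calls`` has columns ``group`` (one of G1/G2/G3/G4/none) and
    ``first_altered_transition`` (1-based index of the first non-flat
    transition; pandas NA when the feature never changes).
    """

    calls: pd.DataFrame
    transitions: list[tuple[str, str]]

    def members(self, *groups: str) -> list[str]:
        mask = self.calls["group"].isin(groups)
        return list(self.calls.index[mask])

    def to_tsv(self, path) -> None:
        out = self.calls.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def classify_trajectory(stats: TransitionStats) -> TrajectoryCall:
    """Assign every feature to exactly one of {G1, G2, G3, G4, none}."""
    d = stats.direction.to_numpy()
    n_feat, n_trans = d.shape
    up = d == "up"
    down = d == "down"
    flat = d == "flat"
    group = np.full(n_feat, "none", dtype=object)
    group[up.all(axis=1)] = "G1"
    group[down.all(axis=1)] = "G2"
    if n_trans >= 2:
        later_flat = flat[:, 1:].all(axis=1)
        group[up[:, 0] & later_flat] = "G3"
        group[down[:, 0] & later_flat] = "G4"
    else:
        # with a single transition, "continuous" and "early then plateau"
        # coincide; the continuous groups win
        pass
    altered = ~flat
    any_altered = altered.any(axis=1)
    first = np.where(any_altered, altered.argmax(axis=1) + 1, -1)
    calls = pd.DataFrame(
        {
            "group": group,
            "first_altered_transition": pd.array(
                [t if t > 0 else None for t in first], dtype="Int64"
            ),
        },
        index=stats.direction.index,
    )
    return TrajectoryCall(calls=calls, transitions=stats.transitions)


def preneoplastic_census(
    calls: TrajectoryCall,
    preneoplastic_transitions: set[int] = frozenset({1, 2}),
) -> tuple[int, int, float]:
    """Count features whose first alteration falls in the preneoplastic window.

    Returns ``(n_early, n_altered, fraction)`` where ``fraction`` is
    ``n_early / n_altered`` (0 when nothing is altered).  The default
    window, transitions 1 and 2, covers the steps into hyperplasia (NeoT)
    and atypical hyperplasia (AT1).
    """
    first = calls.calls["first_altered_transition"]
    altered = first.dropna()
    n_altered = int(len(altered))
    n_early = int(altered.isin(list(preneoplastic_transitions)).sum())
    fraction = n_early / n_altered if n_altered else 0.0
    return n_early, n_altered, fraction
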