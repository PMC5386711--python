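"""miRNA–mRNA functional-pair discovery by target-set enrichment.

The workflow mirrors the SigTerms idea: extract a gene signature from one
progression transition (e.g. genes up more than 1.5-fold, p < 0.05, from
the normal-like stage to DCIS), then ask for every miRNA whether its
predicted targets are over-represented in that signature.  Enrichment is
the upper tail of the hypergeometric distribution (the one-sided Fisher
exact test): drawing ``n`` signature genes from a universe of ``N`` genes
that contains ``K`` predicted targets, the p-value is ``P(X >= k)`` for the
observed overlap ``k``.  Benjamini–Hochberg Q-values across all miRNAs are
gated at Q < 0.25, and surviving miRNAs are intersected with an
inverse-correlation filter to produce a ranked candidate target list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel import ExpressionPanel
from .trajectory import (
    DEFAULT_FC_THRESHOLD,
    DEFAULT_P_THRESHOLD,
    two_sample_stats,
)

logger = logging.getLogger(__name__)

DEFAULT_Q_THRESHOLD = 0.25


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """Gene set that changed over one (not necessarily adjacent) transition.

    ``evidence`` holds the per-gene log2 fold change and p-value used by
    the candidate ranking.
    """

    genes: frozenset[str]
    direction: str  # "up" or "down"
    from_stage: str
    to_stage: str
    fc_threshold: float
    p_threshold: float
    evidence: pd.DataFrame = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.genes)


def extract_signature(
    panel: ExpressionPanel,
    from_stage: str,
    to_stage: str,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    direction: str = "up",
) -> Signature:
    """Genes significantly changed between two stages of the panel.

    A gene enters the ``up`` signature when its to-vs-from log2 fold change
    reaches ``log2(fc_threshold)`` and the equal-variance t-test p-value on
    log2 replicate values is below ``p_threshold`` (``down`` symmetric).
    """
    if from_stage == to_stage:
        raise ValueError("signature transition needs two distinct stages")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    fc, p = two_sample_stats(panel.stage_values(from_stage), panel.stage_values(to_stage))
    log_thr = np.log2(fc_threshold)
    if direction == "up":
        mask = (fc >= log_thr) & (p < p_threshold)
    else:
        mask = (fc <= -log_thr) & (p < p_threshold)
    evidence = pd.DataFrame({"log2_fc": fc[mask], "p_value": p[mask]})
    evidence.index.name = "gene_id"
    return Signature(
        genes=frozenset(evidence.index),
        direction=direction,
        from_stage=from_stage,
        to_stage=to_stage,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# prediction table
# ---------------------------------------------------------------------------

class PredictionTable:
    """Unique (miRNA, gene) predicted-target pairs with per-miRNA access."""

    def __init__(self, pairs: pd.DataFrame | list[tuple[str, str]]):
        if not isinstance(pairs, pd.DataFrame):
            pairs = pd.DataFrame(pairs, columns=["mirna_id", "gene_id"])
        pairs = pairs[["mirna_id", "gene_id"]].astype(str)
        before = len(pairs)
        pairs = pairs.drop_duplicates(ignore_index=True)
        if len(pairs) < before:
            logger.warning("dropped %d duplicate predicted edges", before - len(pairs))
        self.pairs = pairs
        self._by_mirna = {
            m: frozenset(g) for m, g in pairs.groupby("mirna_id")["gene_id"]
        }

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self._by_mirna)

    def targets_of(self, mirna: str) -> frozenset[str]:
        return self._by_mirna.get(mirna, frozenset())

    def add(self, mirna: str, gene: str) -> bool:
        """Insert one edge; duplicates are rejected and leave the table unchanged."""
        if gene in self._by_mirna.get(mirna, frozenset()):
            return False
        self.pairs = pd.concat(
            [self.pairs, pd.DataFrame({"mirna_id": [mirna], "gene_id": [gene]})],
            ignore_index=True,
        )
        self._by_mirna[mirna] = self._by_mirna.get(mirna, frozenset()) | {gene}
        return True

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PredictionTable":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``Q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values, capped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    signature: Signature | frozenset[str],
    predictions: PredictionTable,
    universe: set[str] | frozenset[str],
) -> pd.DataFrame:
    """Per-miRNA hypergeometric target enrichment in the signature.

    Returns a frame indexed by miRNA with columns ``k`` (targets in the
    signature), ``K`` (targets in the universe), ``n`` (signature size),
    ``N`` (universe size), ``p`` (upper-tail hypergeometric, one-sided
    Fisher exact) and ``Q`` (BH across all miRNAs tested).  Target sets are
    intersected with the universe first; a miRNA with no in-universe
    targets gets p = 1.
    """
    genes = signature.genes if isinstance(signature, Signature) else frozenset(signature)
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    if not genes <= universe:
        raise ValueError("signature must be a subset of the universe")
    N, n = len(universe), len(genes)
    rows = []
    for mirna in predictions.mirnas:
        targets = predictions.targets_of(mirna) & universe
        K = len(targets)
        k = len(targets & genes)
        if K == 0:
            p = 1.0
        else:
            # P(X >= k), exact tail of Hypergeometric(N, K, n)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((mirna, k, K, n, N, min(p, 1.0)))
    result = pd.DataFrame(
        rows, columns=["mirna_id", "k", "K", "n", "N", "p"]
    ).set_index("mirna_id")
    result["Q"] = bh_fdr(result["p"].to_numpy()) if len(result) else []
    return result


# ---------------------------------------------------------------------------
# inverse-correlation filter
# ---------------------------------------------------------------------------

def anticorrelation_filter(
    mirna_profile: pd.Series,
    mrna_panel: ExpressionPanel,
    candidates: set[str] | frozenset[str],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> frozenset[str]:
    """Candidate genes whose stage profile inversely correlates with the miRNA.

    Pearson correlation between the miRNA's per-stage means and each
    candidate gene's per-stage means; genes are retained when r < 0 and the
    BH-adjusted two-sided correlation p-value is below ``q_threshold``.
    Zero-variance profiles are skipped with a warning.
    """
    stages = list(mirna_profile.index)
    if len(stages) < 3:
        raise ValueError("need >= 3 stages for a correlation filter")
    means = mrna_panel.stage_means()
    missing = set(candidates) - set(means.index)
    if missing:
        raise ValueError(f"candidates outside the panel universe: {sorted(missing)[:5]}")
    x = mirna_profile.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        logger.warning("miRNA profile has zero variance; nothing retained")
        return frozenset()
    kept_genes, rs, ps = [], [], []
    for gene in sorted(candidates):
        y = means.loc[gene, stages].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            logger.warning("gene %s has a constant stage profile; skipped", gene)
            continue
        r, p = stats.pearsonr(x, y)
        kept_genes.append(gene)
        rs.append(r)
        ps.append(p)
    if not kept_genes:
        return frozenset()
    q = bh_fdr(np.asarray(ps))
    keep = (np.asarray(rs) < 0) & (q < q_threshold)
    return frozenset(np.asarray(kept_genes, dtype=object)[keep])


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------

def candidate_targets(
    mirna: str,
    signature: Signature,
    predictions: PredictionTable,
    anticorr_set: frozenset[str],
    enrichment: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Ranked evidence table for one enriched miRNA.

    Genes in ``signature ∩ predicted targets ∩ anticorr_set``, ranked by
    the magnitude of the signature-transition fold change (descending),
    ties broken lexicographically by gene ID.  The list is empty when the
    miRNA fails the enrichment gate (Q >= ``q_threshold``) or has no
    predictions.
    """
    columns = ["gene_id", "log2_fc", "p_value"]
    empty = pd.DataFrame(columns=columns).set_index("gene_id")
    if mirna not in enrichment.index or not predictions.targets_of(mirna):
        logger.warning("miRNA %s absent from predictions; empty candidate list", mirna)
        return empty
    if enrichment.loc[mirna, "Q"] >= q_threshold:
        return empty
    genes = signature.genes & predictions.targets_of(mirna) & anticorr_set
    if not genes:
        return empty
    ev = signature.evidence.loc[sorted(genes)].copy()
    ev["abs_fc"] = ev["log2_fc"].abs()
    # stable sort over a lexicographically ordered frame = deterministic ties
    ev = ev.sort_values("abs_fc", ascending=False, kind="mergesort")
    return ev.drop(columns="abs_fc")
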