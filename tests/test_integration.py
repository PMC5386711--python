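"""Signature extraction, hypergeometric enrichment, BH FDR and candidates."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from progressionscope import SyntheticConfig, make_panel
from progressionscope.integration import (
    PredictionTable,
    anticorrelation_filter,
    bh_fdr,
    candidate_targets,
    extract_signature,
    fisher_enrichment,
)
from progressionscope.synthetic import gen_progression_expression, gen_target_predictions


def _two_stage_panel(rows, ids):
    return make_panel(np.array(rows, dtype=float), ids, ["P"] * 3 + ["DCIS"] * 3)


class TestExtractSignature:
    def test_toy_threshold_application(self):
        # exactly two of five genes exceed 1.5-fold with p < 0.05
        rows = [
            [10, 10.2, 9.8, 41, 39, 40],      # 4-fold, tight -> in
            [10, 10.2, 9.8, 16.2, 15.8, 16],  # 1.6-fold, tight -> in
            [10, 10.2, 9.8, 12.2, 11.8, 12],  # 1.2-fold -> fails fc
            [10, 20, 40, 16, 32, 64],         # 1.6-fold but huge spread -> fails p
            [40, 41, 39, 10, 10.2, 9.8],      # down -> excluded from "up"
        ]
        ids = [f"g{i}" for i in range(5)]
        sig = extract_signature(_two_stage_panel(rows, ids), "P", "DCIS")
        assert sig.genes == {"g0", "g1"}
        # verify against an independent scipy route
        for i, row in enumerate(rows):
            a, b = np.log2(row[:3]), np.log2(row[3:])
            fc = b.mean() - a.mean()
            p = sps.ttest_ind(b, a, equal_var=True).pvalue
            assert ((fc >= math.log2(1.5)) and (p < 0.05)) == (ids[i] in sig.genes)

    def test_down_direction_symmetric(self):
        rows = [[40, 41, 39, 10, 10.2, 9.8], [10, 10.2, 9.8, 41, 39, 40]]
        sig = extract_signature(
            _two_stage_panel(rows, ["down_g", "up_g"]), "P", "DCIS", direction="down"
        )
        assert sig.genes == {"down_g"}

    def test_identical_stages_rejected(self, two_stage_panel):
        with pytest.raises(ValueError, match="distinct"):
            extract_signature(two_stage_panel, "P", "P")


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_and_constant(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_dominance_and_monotonicity(self, p):
        q = bh_fdr(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_step_up_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 25))
            m = len(p)
            order = np.argsort(p)
            ref = np.empty(m)
            for rank_pos, idx in enumerate(order):
                ref[idx] = min(
                    m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
                )
            np.testing.assert_allclose(bh_fdr(p), np.minimum(ref, 1.0), atol=1e-12)


def _enrichment_p(N, K, n, k):
    """Single-call route through fisher_enrichment."""
    universe = {f"u{i}" for i in range(N)}
    targets = sorted(universe)[:K]
    non_targets = sorted(universe)[K:]
    signature = frozenset(targets[:k] + non_targets[: n - k])
    table = PredictionTable([("miR-x", g) for g in targets])
    res = fisher_enrichment(signature, table, universe)
    return float(res.loc["miR-x", "p"])


class TestFisherEnrichment:
    def test_small_case_closed_form(self):
        # N=10, K=3, n=4, k=2: P(X>=2) = (63 + 7)/210 = 1/3
        assert _enrichment_p(10, 3, 4, 2) == pytest.approx(1 / 3, abs=1e-12)

    def test_signature_equals_universe(self):
        assert _enrichment_p(8, 3, 8, 3) == pytest.approx(1.0)

    def test_zero_overlap(self):
        assert _enrichment_p(10, 3, 4, 0) == pytest.approx(1.0)

    def test_counts_and_q_invariants(self, small_study, small_config):
        _, mrna_panel, truth = small_study
        predictions = gen_target_predictions(truth, small_config)
        sig = extract_signature(mrna_panel, "P", "DCIS")
        res = fisher_enrichment(sig, predictions, frozenset(mrna_panel.features))
        assert (res["k"] <= np.minimum(res["K"], res["n"])).all()
        assert (res["n"] <= res["N"]).all()
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()
        assert (res["Q"] >= res["p"] - 1e-12).all()
        assert (res["Q"] <= 1).all()

    def test_gene_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        universe = [f"u{i}" for i in range(30)]
        targets = list(rng.choice(universe, 8, replace=False))
        signature = frozenset(rng.choice(universe, 10, replace=False))
        table = PredictionTable([("m", g) for g in targets])
        base = fisher_enrichment(signature, table, frozenset(universe))
        relabel = {g: f"x{i:03d}" for i, g in enumerate(rng.permutation(universe))}
        table2 = PredictionTable([("m", relabel[g]) for g in targets])
        res2 = fisher_enrichment(
            frozenset(relabel[g] for g in signature),
            table2,
            frozenset(relabel.values()),
        )
        assert res2.loc["m", "p"] == pytest.approx(base.loc["m", "p"], abs=1e-15)
        assert res2.loc["m", "Q"] == pytest.approx(base.loc["m", "Q"], abs=1e-15)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment(frozenset(), PredictionTable([("m", "g")]), frozenset())


class TestAnticorrelationFilter:
    def _panel_from_stage_means(self, means_by_gene):
        stage_of_sample = ["P", "NeoT", "AT1", "DCIS", "Ca1d"]
        ids = list(means_by_gene)
        matrix = np.array([means_by_gene[g] for g in ids])
        return make_panel(matrix, ids, stage_of_sample)

    def test_perfect_inverse_retained_and_parallel_removed(self):
        mirna = pd.Series([5.0, 4, 3, 2, 1], index=["P", "NeoT", "AT1", "DCIS", "Ca1d"])
        panel = self._panel_from_stage_means(
            {"inv": [1, 2, 3, 4, 5], "par": [10, 8, 6, 4, 2]}
        )
        kept = anticorrelation_filter(mirna, panel, {"inv", "par"})
        assert kept == {"inv"}

    def test_toy_product_moment(self):
        mirna = pd.Series([5.0, 4, 3, 2, 1], index=["P", "NeoT", "AT1", "DCIS", "Ca1d"])
        panel = self._panel_from_stage_means({"g": [1, 2, 2, 4, 5]})
        x, y = np.array([5, 4, 3, 2, 1.0]), np.array([1, 2, 2, 4, 5.0])
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(-10 / np.sqrt(108))
        _, p = sps.pearsonr(x, y)
        kept = anticorrelation_filter(mirna, panel, {"g"}, q_threshold=0.25)
        assert ("g" in kept) == (r < 0 and p < 0.25)

    def test_constant_gene_skipped(self):
        mirna = pd.Series([5.0, 4, 3, 2, 1], index=["P", "NeoT", "AT1", "DCIS", "Ca1d"])
        panel = self._panel_from_stage_means({"flat": [3, 3, 3, 3, 3]})
        assert anticorrelation_filter(mirna, panel, {"flat"}) == frozenset()


class TestCandidateTargets:
    def test_decoy_free_run_recovers_planted_targets(self):
        config = SyntheticConfig(n_mirnas=40, n_mrnas=300, decoy_edge_rate=0.0, seed=21)
        mirna_panel, mrna_panel, truth = gen_progression_expression(config)
        predictions = gen_target_predictions(truth, config)
        sig = extract_signature(mrna_panel, "P", "DCIS")
        enr = fisher_enrichment(sig, predictions, frozenset(mrna_panel.features))
        reg = truth.regulators[0]
        profile = mirna_panel.stage_means().loc[reg]
        anticorr = anticorrelation_filter(profile, mrna_panel, sig.genes)
        ranked = candidate_targets(reg, sig, predictions, anticorr, enr)
        assert set(ranked.index) == truth.targets_of(reg) & sig.genes
        assert len(ranked) > 0

    def test_failing_q_gate_gives_empty_list(self, small_study, small_config):
        _, mrna_panel, truth = small_study
        predictions = gen_target_predictions(truth, small_config)
        sig = extract_signature(mrna_panel, "P", "DCIS")
        enr = fisher_enrichment(sig, predictions, frozenset(mrna_panel.features))
        enr = enr.assign(Q=1.0)  # force the gate shut
        reg = truth.regulators[0]
        ranked = candidate_targets(reg, sig, predictions, frozenset(sig.genes), enr)
        assert ranked.empty

    def test_absent_mirna_gives_empty_list(self, small_study, small_config):
        _, mrna_panel, truth = small_study
        predictions = gen_target_predictions(truth, small_config)
        sig = extract_signature(mrna_panel, "P", "DCIS")
        enr = fisher_enrichment(sig, predictions, frozenset(mrna_panel.features))
        ranked = candidate_targets(
            "miR-not-there", sig, predictions, frozenset(), enr
        )
        assert ranked.empty

    def test_ranking_is_by_fold_magnitude(self):
        config = SyntheticConfig(n_mirnas=40, n_mrnas=300, decoy_edge_rate=0.0, seed=22)
        mirna_panel, mrna_panel, truth = gen_progression_expression(config)
        predictions = gen_target_predictions(truth, config)
        sig = extract_signature(mrna_panel, "P", "DCIS")
        enr = fisher_enrichment(sig, predictions, frozenset(mrna_panel.features))
        reg = truth.regulators[0]
        ranked = candidate_targets(reg, sig, predictions, frozenset(sig.genes), enr)
        mags = ranked["log2_fc"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()
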