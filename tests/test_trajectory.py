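"""Quantile normalization, transition statistics and group classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from progressionscope import make_panel
from progressionscope.trajectory import (
    TrajectoryCall,
    TransitionStats,
    classify_trajectory,
    preneoplastic_census,
    quantile_normalize,
    transition_stats,
    two_sample_stats,
)


def _panel_from_columns(columns, stage_of_sample):
    matrix = np.column_stack(columns).astype(float)
    return make_panel(matrix, [f"g{i}" for i in range(matrix.shape[0])], stage_of_sample)


class TestQuantileNormalize:
    def test_rank_mean_arithmetic(self):
        panel = _panel_from_columns([[1, 2, 3], [4, 5, 6]], ["P", "NeoT"])
        out = quantile_normalize(panel).values
        np.testing.assert_allclose(out.iloc[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.iloc[:, 1], [2.5, 3.5, 4.5])

    def test_identical_value_multisets_unchanged(self):
        panel = _panel_from_columns([[3, 1, 2], [1, 2, 3]], ["P", "NeoT"])
        out = quantile_normalize(panel).values
        np.testing.assert_allclose(out.iloc[:, 0], [3, 1, 2])
        np.testing.assert_allclose(out.iloc[:, 1], [1, 2, 3])

    def test_column_means_equalized(self, two_stage_panel):
        out = quantile_normalize(two_stage_panel).values
        means = out.mean(axis=0)
        np.testing.assert_allclose(means, means.iloc[0])

    def test_within_sample_order_preserved(self, two_stage_panel):
        before = two_stage_panel.values
        after = quantile_normalize(two_stage_panel).values
        for col in before.columns:
            assert (
                np.argsort(before[col].to_numpy(), kind="stable")
                == np.argsort(after[col].to_numpy(), kind="stable")
            ).all()

    def test_constant_sample_tie_rule(self):
        panel = _panel_from_columns([[1, 2, 3], [5, 5, 5]], ["P", "NeoT"])
        out = quantile_normalize(panel).values
        # sample 2 is constant: every value gets the middle reference value
        assert out.iloc[:, 1].nunique() == 1


class TestTwoSampleStats:
    def test_pooled_t_hand_example(self):
        # log2 values {1,2,3} vs {4,5,6}: FC=3, t = 3/sqrt(2/3), df=4
        earlier = pd.DataFrame([[2.0, 4.0, 8.0]], index=["g"])
        later = pd.DataFrame([[16.0, 32.0, 64.0]], index=["g"])
        fc, p = two_sample_stats(earlier, later)
        assert fc["g"] == pytest.approx(3.0)
        t = 3.0 / np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(3.674, abs=1e-3)
        assert p["g"] == pytest.approx(2 * sps.t.sf(t, 4))
        assert p["g"] == pytest.approx(0.021, abs=1e-3)

    def test_symmetric_null(self):
        x = pd.DataFrame([[2.0, 4.0, 8.0]], index=["g"])
        fc, p = two_sample_stats(x, x.copy())
        assert fc["g"] == 0.0
        assert p["g"] == pytest.approx(1.0)

    def test_matches_scipy_reference_on_random_cases(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            na, nb = rng.integers(2, 6, size=2)
            a = rng.lognormal(3, 0.5, size=(1, na))
            b = rng.lognormal(3, 0.5, size=(1, nb))
            _, p = two_sample_stats(
                pd.DataFrame(a, index=["g"]), pd.DataFrame(b, index=["g"])
            )
            ref = sps.ttest_ind(np.log2(b[0]), np.log2(a[0]), equal_var=True).pvalue
            assert p["g"] == pytest.approx(ref, abs=1e-9)

    def test_degenerate_variance_conventions(self):
        same = pd.DataFrame([[4.0, 4.0]], index=["g"])
        shifted = pd.DataFrame([[8.0, 8.0]], index=["g"])
        _, p_equal = two_sample_stats(same, same.copy())
        _, p_diff = two_sample_stats(same, shifted)
        assert p_equal["g"] == 1.0
        assert p_diff["g"] == 0.0


def _stats_from_directions(direction_rows, transitions=None):
    """Build a TransitionStats carrying only direction calls."""
    n_trans = len(direction_rows[0])
    transitions = transitions or [(f"s{i}", f"s{i+1}") for i in range(n_trans)]
    index = [f"g{i}" for i in range(len(direction_rows))]
    cols = [f"{a}->{b}" for a, b in transitions]
    direction = pd.DataFrame(direction_rows, index=index, columns=cols)
    zeros = pd.DataFrame(0.0, index=index, columns=cols)
    return TransitionStats(
        log2_fc=zeros, p_value=zeros + 1.0, direction=direction, transitions=transitions
    )


class TestClassification:
    @pytest.mark.parametrize(
        "directions,expected_group,expected_first",
        [
            (["up", "up", "up", "up"], "G1", 1),
            (["down", "down", "down", "down"], "G2", 1),
            (["up", "flat", "flat", "flat"], "G3", 1),
            (["down", "flat", "flat", "flat"], "G4", 1),
            (["flat", "flat", "flat", "flat"], "none", None),
            (["up", "flat", "down", "flat"], "none", 1),
            (["flat", "down", "down", "down"], "none", 2),
            (["flat", "up", "flat", "flat"], "none", 2),
        ],
    )
    def test_group_rules(self, directions, expected_group, expected_first):
        calls = classify_trajectory(_stats_from_directions([directions])).calls
        assert calls.loc["g0", "group"] == expected_group
        first = calls.loc["g0", "first_altered_transition"]
        if expected_first is None:
            assert pd.isna(first)
        else:
            assert first == expected_first

    def test_partition_property(self, small_study):
        panel = small_study[0]
        calls = classify_trajectory(transition_stats(panel)).calls
        assert set(calls.index) == set(panel.features)
        assert calls["group"].isin(["G1", "G2", "G3", "G4", "none"]).all()

    def test_direction_thresholds(self):
        # g0: 1.6-fold increase with tight replicates -> up at (1.5, 0.05);
        # g1: no change -> flat
        matrix = np.array(
            [
                [10.0, 10.1, 9.9, 16.1, 15.9, 16.0],
                [10.0, 10.1, 9.9, 10.1, 9.9, 10.0],
            ]
        )
        panel = make_panel(matrix, ["g0", "g1"], ["P"] * 3 + ["NeoT"] * 3)
        stats = transition_stats(panel, fc_threshold=1.5, p_threshold=0.05)
        assert stats.direction.iloc[0, 0] == "up"
        assert stats.p_value.iloc[0, 0] < 0.05
        assert stats.direction.iloc[1, 0] == "flat"


class TestInvariances:
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        matrix = rng.lognormal(4, 0.4, size=(6, 9))
        stage_of_sample = ["P"] * 3 + ["NeoT"] * 3 + ["AT1"] * 3
        base = make_panel(matrix, [f"g{i}" for i in range(6)], stage_of_sample)
        scaled = make_panel(matrix * scale, [f"g{i}" for i in range(6)], stage_of_sample)
        s1, s2 = transition_stats(base), transition_stats(scaled)
        np.testing.assert_allclose(s1.log2_fc, s2.log2_fc, atol=1e-9)
        np.testing.assert_allclose(s1.p_value, s2.p_value, atol=1e-9)
        assert s1.direction.equals(s2.direction)
        assert classify_trajectory(s1).calls.equals(classify_trajectory(s2).calls)

    def test_replicate_permutation_invariance(self, small_study):
        panel = small_study[0]
        shuffled = panel.values.copy()
        for stage in panel.stages_present:
            cols = panel.samples_of(stage)
            shuffled[cols] = panel.values[cols[::-1]].to_numpy()
        permuted = type(panel)(
            values=shuffled, stages=panel.stages, stage_order=panel.stage_order
        )
        s1, s2 = transition_stats(panel), transition_stats(permuted)
        np.testing.assert_allclose(s1.log2_fc, s2.log2_fc, atol=1e-12)
        np.testing.assert_allclose(s1.p_value, s2.p_value, atol=1e-12)


class TestCensus:
    def test_empty_calls(self):
        calls = TrajectoryCall(
            calls=pd.DataFrame(
                {"group": [], "first_altered_transition": pd.array([], dtype="Int64")}
            ),
            transitions=[],
        )
        assert preneoplastic_census(calls) == (0, 0, 0.0)

    def test_hand_counts(self):
        first = pd.array([1, 1, 1, 3, None], dtype="Int64")
        calls = TrajectoryCall(
            calls=pd.DataFrame(
                {"group": ["G3", "G4", "G2", "none", "none"],
                 "first_altered_transition": first},
                index=[f"g{i}" for i in range(5)],
            ),
            transitions=[("P", "NeoT"), ("NeoT", "AT1"), ("AT1", "DCIS")],
        )
        assert preneoplastic_census(calls) == (3, 4, 0.75)

    def test_planted_early_fraction_recovered(self):
        from progressionscope.synthetic import gen_progression_expression
        from progressionscope import SyntheticConfig

        # G2/G4 and G1/G3 all first change at transition 1 by construction,
        # so the planted early fraction is 1.0
        config = SyntheticConfig(n_mirnas=300, n_mrnas=50, seed=3)
        panel, _, truth = gen_progression_expression(config)
        calls = classify_trajectory(transition_stats(panel))
        n_early, n_altered, fraction = preneoplastic_census(calls)
        assert n_altered > 0
        assert fraction == pytest.approx(1.0, abs=0.05)
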