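"""Contrast statistics, DEG screening and the QC views."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats import weightstats

import netpharm as nh
from netpharm.expression import ExpressionMatrix, cut_clusters


def _matrix(values: dict, arms: dict) -> ExpressionMatrix:
    genes = [f"g{i}" for i in range(len(next(iter(values.values()))))]
    df = pd.DataFrame(values, index=genes)
    return ExpressionMatrix(values=df, arm_of=arms)


def two_arm_matrix(case: np.ndarray, ctrl: np.ndarray) -> ExpressionMatrix:
    cols = {}
    arms = {}
    for i in range(case.shape[1]):
        cols[f"c{i}"] = case[:, i]
        arms[f"c{i}"] = "case"
    for i in range(ctrl.shape[1]):
        cols[f"k{i}"] = ctrl[:, i]
        arms[f"k{i}"] = "ctrl"
    genes = [f"g{i:03d}" for i in range(case.shape[0])]
    return ExpressionMatrix(values=pd.DataFrame(cols, index=genes), arm_of=arms)


class TestComputeGeneStats:
    def test_identical_groups_give_zero_log2fc(self, rng):
        vals = rng.normal(8, 1, size=(20, 3))
        expr = two_arm_matrix(vals, vals.copy())
        stats = nh.compute_gene_stats(expr, "case", "ctrl")
        assert np.allclose(stats["log2fc"], 0)

    def test_constant_shift_recovers_effect(self, rng):
        ctrl = np.ones((5, 3)) + rng.normal(0, 1e-9, size=(5, 3))
        case = ctrl + 2.0
        stats = nh.compute_gene_stats(two_arm_matrix(case, ctrl), "case", "ctrl")
        assert np.allclose(stats["log2fc"], 2.0, atol=1e-6)

    def test_pvalues_match_reference_implementation(self, rng):
        """Pooled and Welch p agree with statsmodels to 1e-8."""
        case = rng.normal(0, 1, size=(50, 4))
        ctrl = rng.normal(0.3, 1.5, size=(50, 5))
        expr = two_arm_matrix(case, ctrl)
        for test, usevar in (("student", "pooled"), ("welch", "unequal")):
            ours = nh.compute_gene_stats(expr, "case", "ctrl", test=test)["pvalue"]
            ref = [
                weightstats.ttest_ind(case[i], ctrl[i], usevar=usevar)[1]
                for i in range(50)
            ]
            assert np.allclose(ours, ref, atol=1e-8)

    def test_type_i_error_is_nominal(self):
        """Null data: rejection rate at 0.05 stays near 0.05 (pooled test)."""
        rej = total = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            expr = two_arm_matrix(r.normal(0, 1, (500, 3)), r.normal(0, 1, (500, 3)))
            p = nh.compute_gene_stats(expr, "case", "ctrl")["pvalue"]
            rej += int((p < 0.05).sum())
            total += 500
        assert abs(rej / total - 0.05) < 0.01

    def test_flat_genes(self):
        expr = two_arm_matrix(np.full((2, 3), 5.0), np.array([[5.0] * 3, [3.0] * 3]))
        stats = nh.compute_gene_stats(expr, "case", "ctrl")
        assert stats["pvalue"].iloc[0] == 1.0  # equal constant means
        assert stats["pvalue"].iloc[1] < 1e-6  # different constant means

    def test_errors_name_the_offending_arm(self, rng):
        vals = rng.normal(size=(4, 4))
        expr = _matrix(
            {f"s{i}": vals[:, i] for i in range(4)},
            {"s0": "a", "s1": "a", "s2": "b", "s3": "c"},
        )
        with pytest.raises(ValueError, match="'c'"):
            nh.compute_gene_stats(expr, "c", "a")
        with pytest.raises(ValueError, match="unknown arm"):
            nh.compute_gene_stats(expr, "missing", "a")


class TestScreenDegs:
    @pytest.mark.parametrize(
        "log2fc,pvalue,expected",
        [
            (0.6, 0.01, "up"),
            (-0.6, 0.01, "down"),
            (0.5, 0.01, "ns"),  # boundary: strict inequality
            (-0.5, 0.01, "ns"),
            (0.6, 0.05, "ns"),  # boundary on p
            (2.0, 0.2, "ns"),
        ],
    )
    def test_threshold_rule(self, log2fc, pvalue, expected):
        stats = pd.DataFrame(
            {"log2fc": [log2fc], "pvalue": [pvalue], "direction": "ns"},
            index=["g1"],
        )
        assert nh.screen_degs(stats)["direction"].iloc[0] == expected

    def test_swapping_arms_exchanges_up_and_down(self, rng):
        case = rng.normal(1, 0.2, size=(100, 3))
        ctrl = rng.normal(0, 0.2, size=(100, 3))
        expr = two_arm_matrix(case, ctrl)
        fwd = nh.screen_degs(nh.compute_gene_stats(expr, "case", "ctrl"))
        rev = nh.screen_degs(nh.compute_gene_stats(expr, "ctrl", "case"))
        assert set(fwd.index[fwd.direction == "up"]) == set(
            rev.index[rev.direction == "down"]
        )
        assert set(fwd.index[fwd.direction == "down"]) == set(
            rev.index[rev.direction == "up"]
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        lfc1=st.floats(0.1, 2.0),
        lfc2=st.floats(0.1, 2.0),
        p1=st.floats(0.001, 0.5),
        p2=st.floats(0.001, 0.5),
        seed=st.integers(0, 1000),
    )
    def test_threshold_monotonicity(self, lfc1, lfc2, p1, p2, seed):
        """Looser thresholds never shrink the up/down sets."""
        r = np.random.default_rng(seed)
        stats = pd.DataFrame(
            {
                "log2fc": r.normal(0, 1, 50),
                "pvalue": r.uniform(0, 1, 50),
                "direction": "ns",
            },
            index=[f"g{i}" for i in range(50)],
        )
        lo_lfc, hi_lfc = sorted((lfc1, lfc2))
        lo_p, hi_p = sorted((p1, p2))
        strict = nh.screen_degs(stats, hi_lfc, lo_p)
        loose = nh.screen_degs(stats, lo_lfc, hi_p)
        for d in ("up", "down"):
            assert set(strict.index[strict.direction == d]) <= set(
                loose.index[loose.direction == d]
            )

    def test_up_down_disjoint_and_bounded(self, default_scenario):
        expr, *_ = default_scenario
        screened = nh.screen_degs(nh.compute_gene_stats(expr, "model", "control"))
        counts = nh.deg_counts(screened)
        assert counts["up"] + counts["down"] <= len(screened)
        up = set(screened.index[screened.direction == "up"])
        down = set(screened.index[screened.direction == "down"])
        assert not (up & down)

    def test_invalid_thresholds_rejected(self):
        stats = pd.DataFrame(
            {"log2fc": [1.0], "pvalue": [0.01], "direction": "ns"}, index=["g"]
        )
        for bad in (0, -1, float("nan"), float("inf")):
            with pytest.raises(ValueError):
                nh.screen_degs(stats, lfc_threshold=bad)


class TestClusterSamples:
    def test_duplicated_profiles_merge_at_height_zero(self, rng):
        base = rng.normal(size=6)
        expr = _matrix(
            {"s1": base, "s2": base, "s3": base + 5},
            {"s1": "a", "s2": "a", "s3": "b"},
        )
        order, heights, _ = nh.cluster_samples(expr, set(expr.gene_ids))
        assert heights[0] == 0.0

    def test_equidistant_ties_break_lexicographically(self):
        # three samples at mutual equal distances (simplex geometry)
        expr = _matrix(
            {"b": [1.0, 0.0, 0.0], "c": [0.0, 1.0, 0.0], "a": [0.0, 0.0, 1.0]},
            {"a": "x", "b": "x", "c": "x"},
        )
        _, _, z = nh.cluster_samples(expr, set(expr.gene_ids))
        # first merge joins the lexicographically first pair {a, b} = indices 0, 1
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_arms_separate_in_planted_scenario(self, default_scenario):
        expr, *_ , truth = default_scenario
        degs = nh.screen_degs(nh.compute_gene_stats(expr, "model", "control"))
        sub = nh.dysregulated_genes(degs)
        keep = [s for s in expr.sample_ids if expr.arm_of[s] in ("model", "control")]
        sub_expr = ExpressionMatrix(
            values=expr.values[keep], arm_of=expr.arm_of[keep]
        )
        _, _, z = nh.cluster_samples(sub_expr, sub)
        labels = cut_clusters(z, 2, keep)
        by_arm = {
            arm: {labels[s] for s in keep if sub_expr.arm_of[s] == arm}
            for arm in ("model", "control")
        }
        assert len(by_arm["model"]) == 1 and len(by_arm["control"]) == 1
        assert by_arm["model"] != by_arm["control"]

    def test_empty_subset_rejected(self, default_scenario):
        expr = default_scenario[0]
        with pytest.raises(ValueError):
            nh.cluster_samples(expr, set())


class TestPcaSamples:
    def test_constant_matrix_gives_zero_scores(self):
        expr = _matrix(
            {"s1": [1.0, 1.0], "s2": [1.0, 1.0]}, {"s1": "a", "s2": "a"}
        )
        with pytest.warns(UserWarning):
            scores, fracs = nh.pca_samples(expr)
        assert np.all(scores.to_numpy() == 0) and np.all(fracs == 0)

    def test_variance_fractions_ordered_and_bounded(self, default_scenario):
        expr = default_scenario[0]
        scores, fracs = nh.pca_samples(expr)
        assert np.all(np.diff(fracs) <= 1e-12)
        assert 0 <= fracs.sum() <= 1 + 1e-12

    def test_first_component_separates_arms(self, default_scenario):
        expr, *_ = default_scenario
        degs = nh.screen_degs(nh.compute_gene_stats(expr, "model", "control"))
        sub = nh.dysregulated_genes(degs)
        keep = [s for s in expr.sample_ids if expr.arm_of[s] in ("model", "control")]
        sub_expr = ExpressionMatrix(values=expr.values[keep], arm_of=expr.arm_of[keep])
        scores, _ = nh.pca_samples(sub_expr, sub)
        pc1 = scores["PC1"]
        model = pc1[[s for s in keep if sub_expr.arm_of[s] == "model"]]
        control = pc1[[s for s in keep if sub_expr.arm_of[s] == "control"]]
        assert model.max() < control.min() or control.max() < model.min()
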