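"""Differential statistics: exact-test oracles, BH, aggregation, PCA, scores."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidshift.landscape_stats import (
    GroupDesign,
    bh_adjust,
    class_aggregate_test,
    fatty_acid_pool,
    pathway_zscore,
    pca_group_test,
    rank_sum_test,
    regulation_fractions,
    saturation_grid,
    signed_rank_test,
    species_differential,
)
from lipidshift.quantification import AbundanceMatrix


def enumerate_rank_sum_p(x, y):
    """Brute-force exact two-sided rank-sum p over all C(n+m, n) assignments.

    Uses the symmetry of the tie-free null distribution of the Mann-Whitney
    U statistic around nm/2.
    """
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    count = 0
    total = 0
    for subset in combinations(range(n + m), n):
        u = ranks[list(subset)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            count += 1
    return count / total


def make_matrix(data, classes=None, tiers=None, n_case=None):
    n = len(next(iter(data.values())))
    if n_case is None:
        n_case = n // 2
    samples = [f"c{i}" for i in range(n_case)] + [f"r{i}" for i in range(n - n_case)]
    df = pd.DataFrame(data, index=samples).T  # species x samples
    info = pd.DataFrame(
        {
            "lipid_class": classes or {sp: "PC" for sp in df.index},
            "tier": tiers or {sp: "primary" for sp in df.index},
        }
    )
    return AbundanceMatrix(df, info)


def make_design(n_case, n_ref, case="cap_admission", ref="control"):
    samples = [f"c{i}" for i in range(n_case)] + [f"r{i}" for i in range(n_ref)]
    groups = pd.Series([case] * n_case + [ref] * n_ref, index=samples)
    return samples, GroupDesign(groups=groups)


class TestRankSum:
    def test_maximally_separated_small_groups(self):
        # all C(6,3)=20 assignments; the observed split is maximally extreme
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(2, 7) for m in range(n, 11) if n + m <= 12])
    def test_exact_p_matches_full_enumeration(self, n, m):
        rng = np.random.default_rng(n * 100 + m)
        x, y = rng.normal(0, 1, n), rng.normal(0.8, 1, m)
        assert rank_sum_test(x, y) == pytest.approx(enumerate_rank_sum_p(x, y), abs=1e-12)

    def test_identical_degenerate_input(self):
        assert rank_sum_test([1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_signed_rank_paired(self):
        x = np.arange(1.0, 9.0)
        assert signed_rank_test(x, x) == 1.0
        assert signed_rank_test(x + 1.0, x) < 0.05


class TestBH:
    def test_hand_computed_step_up(self):
        # adj_i = min_{j>=i} p_(j) * m / j
        adjusted = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adjusted, [0.03, 0.03, 0.03])
        adjusted = bh_adjust([0.01, 0.04, 0.9])
        assert np.allclose(adjusted, [0.03, 0.06, 0.9])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, pvals):
        adjusted = bh_adjust(pvals)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-12)
        assert np.all(adjusted <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)


class TestSpeciesDifferential:
    def test_identical_groups_are_unchanged(self):
        values = {f"s{i}": [float(i + 1)] * 8 for i in range(5)}
        matrix = make_matrix(values)
        _, design = make_design(4, 4)
        results = species_differential(matrix, design, "cap_admission", "control")
        assert (results["status"] == "unchanged").all()
        assert np.allclose(results["log2fc"], 0.0)

    def test_planted_shift_detected_with_correct_sign(self):
        rng = np.random.default_rng(7)
        samples, design = make_design(20, 20)
        data = {}
        for i in range(30):
            base = rng.lognormal(0, 0.3, 40)
            if i < 5:
                base[:20] *= 4.0
            data[f"sp{i}"] = base
        matrix = AbundanceMatrix(
            pd.DataFrame(data, index=samples).T,
            pd.DataFrame({"lipid_class": "PC", "tier": "primary"}, index=[f"sp{i}" for i in range(30)]),
        )
        results = species_differential(matrix, design, "cap_admission", "control")
        up = results.index[results["status"] == "up"]
        assert set(up) == {f"sp{i}" for i in range(5)}

    def test_secondary_tier_excluded(self):
        values = {f"s{i}": list(range(1, 9)) for i in range(4)}
        matrix = make_matrix(values, tiers={"s0": "secondary", "s1": "primary", "s2": "primary", "s3": "primary"})
        _, design = make_design(4, 4)
        results = species_differential(matrix, design, "cap_admission", "control")
        assert "s0" not in results.index

    def test_zero_reference_mean_flagged_undefined(self):
        matrix = make_matrix({"s0": [1, 2, 3, 0, 0, 0], "s1": [1, 2, 3, 4, 5, 6]})
        _, design = make_design(3, 3)
        results = species_differential(matrix, design, "cap_admission", "control")
        assert results.loc["s0", "status"] == "undefined"
        assert np.isnan(results.loc["s0", "log2fc"])

    def test_median_fold_change_option(self):
        matrix = make_matrix({"s0": [2, 2, 2, 100, 1, 1, 1, 100]})
        _, design = make_design(4, 4)
        res = species_differential(matrix, design, "cap_admission", "control", fc_stat="median")
        assert res.loc["s0", "log2fc"] == pytest.approx(1.0)


class TestRegulationFractions:
    def frame(self, statuses):
        return pd.DataFrame({"status": statuses})

    def test_all_unchanged(self):
        assert regulation_fractions(self.frame(["unchanged"] * 4)) == {
            "up": 0,
            "down": 0,
            "unchanged": 100,
        }

    def test_quarters(self):
        fractions = regulation_fractions(self.frame(["up", "down", "unchanged", "unchanged"]))
        assert fractions == {"up": 25, "down": 25, "unchanged": 50}

    @given(
        up=st.integers(min_value=0, max_value=40),
        down=st.integers(min_value=0, max_value=40),
        unchanged=st.integers(min_value=1, max_value=400),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_percentages_always_sum_to_100(self, up, down, unchanged):
        statuses = ["up"] * up + ["down"] * down + ["unchanged"] * unchanged
        assert sum(regulation_fractions(self.frame(statuses)).values()) == 100


class TestClassAggregate:
    def test_aggregate_is_species_sum(self):
        matrix = make_matrix(
            {"a": [1.0] * 4, "b": [2.0] * 4},
            classes={"a": "PC", "b": "PC"},
        )
        _, design = make_design(2, 2)
        _, aggregates = class_aggregate_test(matrix, design, "cap_admission", "control")
        assert (aggregates.loc["PC"] == 3.0).all()

    def test_identical_groups_p_one(self):
        matrix = make_matrix({"a": [1, 2, 1, 2], "b": [3, 4, 3, 4]})
        _, design = make_design(2, 2)
        summary, _ = class_aggregate_test(matrix, design, "cap_admission", "control")
        assert (summary["p"] == 1.0).all()

    def test_permutation_invariance_in_species_order(self):
        rng = np.random.default_rng(0)
        values = {f"s{i}": rng.lognormal(0, 0.3, 10) for i in range(6)}
        samples, design = make_design(5, 5)
        classes = {f"s{i}": ("PC" if i % 2 else "PE") for i in range(6)}
        m1 = AbundanceMatrix(
            pd.DataFrame(values, index=samples).T,
            pd.DataFrame({"lipid_class": classes, "tier": "primary"}),
        )
        order = list(reversed(m1.data.index))
        m2 = AbundanceMatrix(m1.data.loc[order], m1.species_info.loc[order])
        s1, a1 = class_aggregate_test(m1, design, "cap_admission", "control")
        s2, a2 = class_aggregate_test(m2, design, "cap_admission", "control")
        assert np.allclose(a1.sort_index(), a2.sort_index())
        assert np.allclose(s1["p"].sort_index(), s2["p"].sort_index())

    def test_secondary_tier_included_at_class_level(self):
        matrix = make_matrix(
            {"a": [2, 2, 1, 1], "b": [2, 2, 1, 1]},
            classes={"a": "FA", "b": "FA"},
            tiers={"a": "secondary", "b": "secondary"},
        )
        _, design = make_design(2, 2)
        summary, _ = class_aggregate_test(matrix, design, "cap_admission", "control")
        assert summary.loc["FA", "n_species"] == 2
        assert summary.loc["FA", "direction"] == "up"

    def test_paired_comparison_uses_subject_matching(self):
        samples = [f"a{i}" for i in range(6)] + [f"r{i}" for i in range(6)]
        groups = pd.Series(["cap_admission"] * 6 + ["cap_recovery"] * 6, index=samples)
        subjects = pd.Series([f"P{i}" for i in range(6)] * 2, index=samples)
        design = GroupDesign(groups=groups, subjects=subjects)
        rng = np.random.default_rng(1)
        admission = rng.lognormal(1.0, 0.2, 6)
        recovery = admission * 0.5
        data = pd.DataFrame({"sp": np.concatenate([admission, recovery])}, index=samples).T
        matrix = AbundanceMatrix(
            data, pd.DataFrame({"lipid_class": {"sp": "PC"}, "tier": {"sp": "primary"}})
        )
        summary, _ = class_aggregate_test(
            matrix, design, "cap_admission", "cap_recovery", paired=True
        )
        assert summary.loc["PC", "p"] < 0.05
        assert summary.loc["PC", "direction"] == "up"


class TestPCA:
    def build(self, seed=0, shift=0.0, n_species=20, n1=10, n2=10):
        rng = np.random.default_rng(seed)
        samples, design = make_design(n1, n2)
        data = rng.lognormal(0, 0.3, (n_species, n1 + n2))
        data[: n_species // 2, :n1] *= np.exp(shift)
        df = pd.DataFrame(data, index=[f"s{i}" for i in range(n_species)], columns=samples)
        info = pd.DataFrame({"lipid_class": "PC", "tier": "primary"}, index=df.index)
        return AbundanceMatrix(df, info), design

    def test_planted_shift_separates_groups(self):
        matrix, design = self.build(seed=2, shift=1.0)
        out = pca_group_test(matrix, design, "cap_admission", "control")
        assert out["p_pc1"] < 0.05
        scores = out["scores"]
        assert scores.loc[scores["group"] == "cap_admission", "PC1"].mean() >= scores.loc[
            scores["group"] == "control", "PC1"
        ].mean()

    def test_species_permutation_leaves_scores_unchanged_up_to_sign(self):
        matrix, design = self.build(seed=3, shift=0.5)
        out1 = pca_group_test(matrix, design, "cap_admission", "control")
        order = list(reversed(matrix.data.index))
        matrix2 = AbundanceMatrix(matrix.data.loc[order], matrix.species_info.loc[order])
        out2 = pca_group_test(matrix2, design, "cap_admission", "control")
        pc1_a = out1["scores"]["PC1"].to_numpy()
        pc1_b = out2["scores"]["PC1"].to_numpy()
        assert np.allclose(pc1_a, pc1_b, atol=1e-8) or np.allclose(pc1_a, -pc1_b, atol=1e-8)
        assert out1["p_pc1"] == pytest.approx(out2["p_pc1"])

    def test_zero_variance_species_dropped(self):
        matrix, design = self.build(seed=4)
        matrix.data.iloc[0, :] = 5.0
        out = pca_group_test(matrix, design, "cap_admission", "control")
        assert len(out["scores"]) == 20


class TestSaturationGrid:
    def results(self, names):
        return pd.DataFrame(
            {"log2fc": 0.5, "p_adj": 0.01}, index=pd.Index(names, name="species")
        )

    def test_categories(self):
        grid, rejects = saturation_grid(self.results(["TG(52:0)", "PC(34:1)", "TG(54:5)", "PE(36:2)"]))
        assert rejects == []
        by_species = grid.set_index("species")
        assert by_species.loc["TG(52:0)", "category"] == "saturated"
        assert by_species.loc["TG(52:0)", "carbons"] == 52
        assert by_species.loc["PC(34:1)", "category"] == "monounsaturated"
        assert by_species.loc["TG(54:5)", "category"] == "polyunsaturated-containing"
        assert by_species.loc["TG(54:5)", "pufa_guaranteed"]
        assert by_species.loc["PE(36:2)", "category"] == "polyunsaturated-containing"

    def test_tg_pufa_rule_boundary(self):
        grid, _ = saturation_grid(self.results(["TG(54:4)", "TG(54:5)"]))
        by_species = grid.set_index("species")
        # more than 4 double bonds forces a polyunsaturated chain in a TG
        assert not by_species.loc["TG(54:4)", "pufa_guaranteed"]
        assert by_species.loc["TG(54:5)", "pufa_guaranteed"]

    def test_unparseable_names_collected(self):
        grid, rejects = saturation_grid(self.results(["PC(34:1)", "garbage"]))
        assert rejects == ["garbage"]
        assert len(grid) == 1


class TestFattyAcidPool:
    def build(self):
        samples, design = make_design(3, 3)
        data = pd.DataFrame(
            {
                "FA(16:0)": [0.5] * 3 + [0.25] * 3,
                "FA(20:4)": [1.5] * 3 + [0.75] * 3,
                "PC(34:1)": [1.0] * 6,
            },
            index=samples,
        ).T
        info = pd.DataFrame(
            {
                "lipid_class": {"FA(16:0)": "FA", "FA(20:4)": "FA", "PC(34:1)": "PC"},
                "tier": {"FA(16:0)": "secondary", "FA(20:4)": "secondary", "PC(34:1)": "primary"},
            }
        )
        return AbundanceMatrix(data, info), design

    def test_pool_is_sum_of_fa_species(self):
        matrix, design = self.build()
        out = fatty_acid_pool(matrix, design, "cap_admission", "control", single_species="FA(20:4)")
        assert out["pool"].iloc[0] == pytest.approx(2.0)
        assert out["pool_direction"] == "up"
        assert out["species_direction"] == "up"

    def test_missing_single_species_raises(self):
        matrix, design = self.build()
        with pytest.raises(KeyError):
            fatty_acid_pool(matrix, design, "cap_admission", "control", single_species="FA(22:6)")

    def test_no_fa_class_raises(self):
        matrix, design = self.build()
        trimmed = AbundanceMatrix(
            matrix.data.loc[["PC(34:1)"]], matrix.species_info.loc[["PC(34:1)"]]
        )
        with pytest.raises(ValueError):
            fatty_acid_pool(trimmed, design, "cap_admission", "control")


class TestPathwayZscore:
    def test_balanced_zscores_average_to_zero(self):
        expr = pd.DataFrame(
            {"p1": [1.0, 3.0], "p2": [2.0, 2.0], "p3": [3.0, 1.0]},
            index=["g1", "g2"],
        )
        scores = pathway_zscore(expr, ["g1", "g2"])
        assert scores["p2"] == pytest.approx(0.0, abs=1e-12)
        assert scores.sum() == pytest.approx(0.0, abs=1e-12)

    def test_single_gene_pathway_equals_gene_zscore(self):
        expr = pd.DataFrame({"p1": [1.0], "p2": [2.0], "p3": [3.0]}, index=["g1"])
        scores = pathway_zscore(expr, ["g1"])
        z = (expr.loc["g1"] - expr.loc["g1"].mean()) / expr.loc["g1"].std(ddof=1)
        assert np.allclose(scores, z)

    def test_missing_and_zero_variance_genes_skipped(self):
        expr = pd.DataFrame(
            {"p1": [1.0, 5.0], "p2": [2.0, 5.0], "p3": [3.0, 5.0]}, index=["g1", "gflat"]
        )
        scores = pathway_zscore(expr, ["g1", "gflat", "gmissing"])
        z = (expr.loc["g1"] - expr.loc["g1"].mean()) / expr.loc["g1"].std(ddof=1)
        assert np.allclose(scores, z)
        with pytest.raises(ValueError):
            pathway_zscore(expr, ["gmissing"])


class TestGroupDesign:
    def test_duplicate_sample_rejected(self):
        groups = pd.Series(["a", "b"], index=["s1", "s1"])
        with pytest.raises(ValueError):
            GroupDesign(groups=groups)

    def test_subject_with_two_samples_in_one_group_rejected(self):
        groups = pd.Series(["a", "a"], index=["s1", "s2"])
        subjects = pd.Series(["P1", "P1"], index=["s1", "s2"])
        with pytest.raises(ValueError):
            GroupDesign(groups=groups, subjects=subjects)
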