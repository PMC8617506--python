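"""Trait heterosis, panel correlations, threshold sets, enrichment and densities."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

import midparent as mp
from midparent.panel import (
    DENSITY_GRID,
    correlation_density_by_group,
    correlation_threshold_set,
    enrichment_hypergeometric,
    expression_heterosis_matrix,
    negative_control_correlation,
    protein_trait_correlation,
    top_fraction,
    trait_heterosis,
)


def _traits(d):
    return mp.TraitTable(pd.DataFrame({"genotype": list(d), "height_cm": list(d.values())}))


def _panel(crosses):
    return mp.CrossPanel(
        pd.DataFrame(
            {"hybrid": [h for h, _, _ in crosses],
             "parent_female": [a for _, a, _ in crosses],
             "parent_male": [b for _, _, b in crosses]}
        )
    )


class TestTraitHeterosis:
    def test_simple_ratio(self):
        traits = _traits({"A": 100.0, "B": 120.0, "AxB": 165.0})
        h = trait_heterosis(traits, _panel([("AxB", "A", "B")]))
        assert h["AxB"] == pytest.approx(1.5)

    def test_hybrid_at_midparent_height(self):
        traits = _traits({"A": 100.0, "B": 120.0, "AxB": 110.0})
        assert trait_heterosis(traits, _panel([("AxB", "A", "B")]))["AxB"] == pytest.approx(1.0)

    def test_five_hybrid_hand_arithmetic(self):
        parents = {"P1": 140.0, "P2": 150.0, "P3": 160.0}
        crosses = [("H1", "P1", "P2"), ("H2", "P1", "P3"), ("H3", "P2", "P3"),
                   ("H4", "P2", "P1"), ("H5", "P3", "P1")]
        hybrid_heights = {"H1": 200.0, "H2": 210.0, "H3": 220.0, "H4": 190.0, "H5": 230.0}
        traits = _traits({**parents, **hybrid_heights})
        h = trait_heterosis(traits, _panel(crosses))
        for name, pf, pm in crosses:
            expected = hybrid_heights[name] / ((parents[pf] + parents[pm]) / 2.0)
            assert h[name] == pytest.approx(expected, abs=1e-12)

    def test_missing_genotype_named(self):
        traits = _traits({"A": 100.0, "AxB": 165.0})
        with pytest.raises(ValueError, match="'B'"):
            trait_heterosis(traits, _panel([("AxB", "A", "B")]))


def _records(hybrid, ratios):
    return pd.DataFrame({"hybrid": hybrid, "ratio_mp": list(ratios.values())},
                        index=list(ratios))


class TestExpressionHeterosisMatrix:
    def test_two_by_three(self):
        eh = expression_heterosis_matrix(
            [_records("H1", {"f1": 1.1, "f2": 0.9}),
             _records("H2", {"f1": 1.2, "f2": 1.0}),
             _records("H3", {"f1": 1.3, "f2": 1.1})]
        )
        assert eh.shape == (2, 3)
        assert eh.loc["f1", "H2"] == pytest.approx(1.2)

    def test_missing_feature_keeps_row(self):
        eh = expression_heterosis_matrix(
            [_records("H1", {"f1": 1.1, "f2": 0.9}), _records("H2", {"f1": 1.2})]
        )
        assert np.isnan(eh.loc["f2", "H2"])
        assert "f2" in eh.index

    def test_column_order_follows_panel(self):
        eh = expression_heterosis_matrix(
            [_records("H2", {"f1": 1.0}), _records("H1", {"f1": 1.1})],
            order=["H1", "H2"],
        )
        assert list(eh.columns) == ["H1", "H2"]

    def test_duplicate_hybrid_rejected(self):
        with pytest.raises(ValueError, match="H1"):
            expression_heterosis_matrix(
                [_records("H1", {"f1": 1.0}), _records("H1", {"f1": 1.1})]
            )


class TestPearsonCorrelation:
    def test_proportional_gives_one(self):
        h = pd.Series([1.2, 1.3, 1.4, 1.5, 1.6, 1.7],
                      index=[f"H{i}" for i in range(6)])
        eh = pd.DataFrame([2.0 * h.to_numpy()], index=["f1"], columns=h.index)
        out = protein_trait_correlation(eh, h, min_hybrids=5)
        assert out.loc["f1", "r"] == pytest.approx(1.0)

    def test_perfect_decreasing_gives_minus_one(self):
        h = pd.Series([1.2, 1.3, 1.4, 1.5, 1.6], index=[f"H{i}" for i in range(5)])
        eh = pd.DataFrame([(2.0 - h).to_numpy()], index=["f1"], columns=h.index)
        out = protein_trait_correlation(eh, h, min_hybrids=5)
        assert out.loc["f1", "r"] == pytest.approx(-1.0)

    def test_four_point_covariance_formula(self):
        e = np.array([1.0, 1.2, 1.1, 1.3])
        h = np.array([1.1, 1.4, 1.2, 1.6])
        expected = (
            np.sum((e - e.mean()) * (h - h.mean()))
            / np.sqrt(np.sum((e - e.mean()) ** 2) * np.sum((h - h.mean()) ** 2))
        )
        eh = pd.DataFrame([e], index=["f1"], columns=[f"H{i}" for i in range(4)])
        out = protein_trait_correlation(eh, pd.Series(h, index=eh.columns), min_hybrids=3)
        assert out.loc["f1", "r"] == pytest.approx(expected, abs=1e-12)
        # p from the t transform with n-2 df
        from scipy import stats as sps
        t = expected * math.sqrt(2 / (1 - expected**2))
        assert out.loc["f1", "p"] == pytest.approx(2 * sps.t.sf(abs(t), 2), rel=1e-10)

    def test_zero_variance_and_short_rows_omitted(self):
        h = pd.Series([1.2, 1.3, 1.4, 1.5, 1.6], index=[f"H{i}" for i in range(5)])
        eh = pd.DataFrame(
            [[1.0] * 5, [1.0, 1.1, np.nan, np.nan, np.nan], list(h)],
            index=["const", "short", "ok"],
            columns=h.index,
        )
        out = protein_trait_correlation(eh, h, min_hybrids=5)
        assert list(out.index) == ["ok"]

    def test_invariance_under_rescaling(self):
        rng = np.random.default_rng(1)
        h = pd.Series(rng.uniform(1.2, 1.8, 8), index=[f"H{i}" for i in range(8)])
        eh = pd.DataFrame(rng.lognormal(0, 0.2, (10, 8)),
                          index=[f"f{i}" for i in range(10)], columns=h.index)
        base = protein_trait_correlation(eh, h, min_hybrids=5)["r"]
        cm_to_m = protein_trait_correlation(eh, h / 100.0 + 0.5, min_hybrids=5)["r"]
        scaled = protein_trait_correlation(eh * 4.0, h, min_hybrids=5)["r"]
        np.testing.assert_allclose(base, cm_to_m, rtol=1e-12)
        np.testing.assert_allclose(base, scaled, rtol=1e-12)


class TestSelectionSets:
    @pytest.fixture()
    def corr(self):
        return pd.DataFrame(
            {"r": [0.6, 0.4, -0.7]}, index=["f1", "f2", "f3"]
        ).rename_axis("feature_id")

    def test_upper_cutoff(self, corr):
        assert correlation_threshold_set(corr, 0.5, "upper") == ["f1"]

    def test_lower_cutoff(self, corr):
        assert correlation_threshold_set(corr, -0.5, "lower") == ["f3"]

    def test_boundary_empty(self, corr):
        assert correlation_threshold_set(corr, 1.0, "upper") == []

    def test_top_fraction_ceiling(self):
        corr = pd.DataFrame(
            {"r": np.linspace(-0.9, 0.9, 100)},
            index=[f"f{i:03d}" for i in range(100)],
        ).rename_axis("feature_id")
        assert len(top_fraction(corr, 0.015)) == 2
        assert top_fraction(corr, 0.015) == ["f099", "f098"]

    def test_top_fraction_full_set(self):
        corr = pd.DataFrame({"r": [0.1, 0.2]}, index=["f1", "f2"]).rename_axis("feature_id")
        assert set(top_fraction(corr, 0.99)) == {"f1", "f2"}

    def test_top_fraction_tie_breaks_lexicographically(self):
        corr = pd.DataFrame(
            {"r": [0.5, 0.5, 0.4]}, index=["fb", "fa", "fc"]
        ).rename_axis("feature_id")
        assert top_fraction(corr, 0.33) == ["fa"]


class TestEnrichment:
    @staticmethod
    def _enumerated_p(N, K, n, k_obs):
        universe = range(N)
        group = set(range(K))
        count = sum(
            1
            for subset in itertools.combinations(universe, n)
            if len(group & set(subset)) >= k_obs
        )
        return count / math.comb(N, n)

    def test_worked_case_five_over_210(self):
        ann = mp.AnnotationTable(
            pd.DataFrame(
                {"feature_id": [f"f{i}" for i in range(10)],
                 "groups": [frozenset({"TPR"})] * 5 + [frozenset()] * 5}
            )
        )
        universe = [f"f{i}" for i in range(10)]
        selected = [f"f{i}" for i in range(4)]  # all 4 in the group
        table = enrichment_hypergeometric(selected, ann, universe)
        row = table[table["group"] == "TPR"].iloc[0]
        assert row["p"] == pytest.approx(5 / 210, rel=1e-12)
        assert row["overlap"] == 4 and row["group_size"] == 5

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 4), (12, 6, 5), (11, 4, 6)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        ids = [f"f{i:02d}" for i in range(N)]
        ann = mp.AnnotationTable(
            pd.DataFrame(
                {"feature_id": ids,
                 "groups": [frozenset({"TPR"})] * K + [frozenset()] * (N - K)}
            )
        )
        for k in range(0, min(K, n) + 1):
            selected = ids[:k] + ids[K: K + (n - k)]
            table = enrichment_hypergeometric(selected, ann, ids)
            row = table[table["group"] == "TPR"].iloc[0]
            assert row["p"] == pytest.approx(self._enumerated_p(N, K, n, k), rel=1e-10)

    def test_empty_selection_gives_p_one(self):
        ann = mp.AnnotationTable(
            pd.DataFrame({"feature_id": ["f1", "f2"], "groups": [frozenset({"TPR"})] * 2})
        )
        table = enrichment_hypergeometric([], ann, ["f1", "f2"])
        assert (table["p"] == 1.0).all()

    def test_selected_outside_universe_rejected(self):
        ann = mp.AnnotationTable(
            pd.DataFrame({"feature_id": ["f1"], "groups": [frozenset({"TPR"})]})
        )
        with pytest.raises(ValueError, match="f9"):
            enrichment_hypergeometric(["f9"], ann, ["f1"])

    def test_empty_universe_rejected(self):
        ann = mp.AnnotationTable(pd.DataFrame({"feature_id": [], "groups": []}))
        with pytest.raises(ValueError, match="universe"):
            enrichment_hypergeometric([], ann, [])


class TestDensityCurves:
    @staticmethod
    def _annotation(n, group):
        return mp.AnnotationTable(
            pd.DataFrame({"feature_id": [f"f{i}" for i in range(n)],
                          "groups": [frozenset({group})] * n})
        )

    def test_degenerate_group_peaks_at_value(self):
        corr = pd.DataFrame({"r": [0.8] * 6}, index=[f"f{i}" for i in range(6)])
        curves = correlation_density_by_group(corr, self._annotation(6, "TPR"), ["TPR"])
        mode = curves.loc[curves["density"].idxmax(), "r"]
        assert abs(mode - 0.8) < 0.05

    def test_curves_integrate_to_one(self):
        rng = np.random.default_rng(2)
        corr = pd.DataFrame({"r": rng.uniform(-1, 1, 40)},
                            index=[f"f{i}" for i in range(40)])
        curves = correlation_density_by_group(corr, self._annotation(40, "PhANG"), ["PhANG"])
        integral = np.trapezoid(curves["density"].to_numpy(), curves["r"].to_numpy())
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_identical_groups_identical_curves(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(-0.5, 0.9, 12)
        corr = pd.DataFrame({"r": np.concatenate([r, r])},
                            index=[f"f{i}" for i in range(24)])
        ann = mp.AnnotationTable(
            pd.DataFrame({"feature_id": [f"f{i}" for i in range(24)],
                          "groups": [frozenset({"TPR"})] * 12 + [frozenset({"PhANG"})] * 12})
        )
        curves = correlation_density_by_group(corr, ann, ["TPR", "PhANG"])
        a = curves[curves["group"] == "TPR"]["density"].to_numpy()
        b = curves[curves["group"] == "PhANG"]["density"].to_numpy()
        assert np.array_equal(a, b)

    def test_undersized_group_skipped_with_warning(self):
        corr = pd.DataFrame({"r": [0.1, 0.2]}, index=["f0", "f1"])
        with pytest.warns(UserWarning, match="TPR"):
            curves = correlation_density_by_group(corr, self._annotation(2, "TPR"), ["TPR"])
        assert curves.empty

    def test_grid_matches_contract(self):
        assert DENSITY_GRID.size == 512
        assert DENSITY_GRID[0] == pytest.approx(-1.05)
        assert DENSITY_GRID[-1] == pytest.approx(1.05)


class TestNegativeControl:
    def test_levels_equal_heights_give_r_one(self):
        heights = pd.Series({"A": 100.0, "B": 150.0, "C": 130.0, "D": 170.0})
        levels = pd.DataFrame([heights.to_numpy()], index=["f1"], columns=heights.index)
        table, summary = negative_control_correlation(levels, heights)
        assert table.loc["f1", "r"] == pytest.approx(1.0)

    def test_constant_levels_omitted(self):
        heights = pd.Series({"A": 100.0, "B": 150.0, "C": 130.0})
        levels = pd.DataFrame([[2.0, 2.0, 2.0]], index=["f1"], columns=heights.index)
        table, summary = negative_control_correlation(levels, heights)
        assert table.empty

    def test_uncoupled_levels_do_not_track_height(self, default_sim, default_norm):
        """Absolute levels of uncoupled features are uncorrelated with raw height,
        in contrast to the heterosis-ratio correlations of the coupled group."""
        sim = default_sim
        levels = pd.DataFrame(
            {g: mp.genotype_stats(default_norm, sim.design, g).mean
             for g in sim.design.genotypes}
        )
        table, summary = negative_control_correlation(levels, sim.traits)
        truth = sim.truth.features
        uncoupled = table.index.intersection(truth.index[truth["beta"] == 0])
        assert table.loc[uncoupled, "r"].abs().median() <= 0.3
        assert summary["median_abs_r"] <= 0.3
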