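"""Abundance-weighted community metrics and the statistics stage."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cecogem import (
    EssentialityProfile,
    RankedFeatureList,
    UtilizationProfile,
    correlation_rank,
    mann_whitney,
    metabolite_demand,
    scale_and_impute,
    total_metabolic_demand,
    utilization_potential,
    welch_rank,
    zscore_rank,
)
from cecogem.community import Z_MAX
from cecogem.profiles import CommunityAbundance


def _ca(rows, genera, **kw):
    return CommunityAbundance(pd.DataFrame(np.atleast_2d(rows), columns=genera), **kw)


def _util(genus, carbon=(), nitrogen=()):
    def frame(usable):
        return pd.DataFrame(
            {"usable": [c in usable for c in ["cpdA", "cpdB"]],
             "baseline": 1.0, "test": 3.0},
            index=["cpdA", "cpdB"],
        )
    return UtilizationProfile(genus, frame(carbon), frame(nitrogen))


def _ess(genus, scores, mean=None):
    s = pd.Series(scores, dtype=float)
    return EssentialityProfile(
        genus=genus, scores=s, n_present=pd.Series(100, index=s.index),
        n_essential=(s * 100).astype(int),
        mean_essentiality=float(s.mean()) if mean is None else mean,
    )


class TestPotentialsAndDemands:
    def test_all_users_give_potential_one(self):
        ca = _ca([[0.4, 0.6]], ["g1", "g2"])
        profs = [_util("g1", carbon=("cpdA",)), _util("g2", carbon=("cpdA",))]
        assert utilization_potential(ca, profs, "cpdA").iloc[0] == pytest.approx(1.0)

    def test_partial_users_sum_their_abundance(self):
        ca = _ca([[0.7, 0.3], [0.2, 0.8]], ["g1", "g2"])
        profs = [_util("g1", carbon=("cpdA",)), _util("g2")]
        up = utilization_potential(ca, profs, "cpdA")
        assert list(up) == pytest.approx([0.7, 0.2])

    def test_nitrogen_element_and_missing_profile(self):
        ca = _ca([[1.0]], ["g1"])
        up = utilization_potential(ca, [_util("g1", nitrogen=("cpdB",))], "cpdB", "nitrogen")
        assert up.iloc[0] == 1.0
        with pytest.raises(ValueError, match="g1"):
            utilization_potential(ca, [], "cpdA")

    def test_total_demand_weighted_mean(self):
        ca = _ca([[0.5, 0.5]], ["g1", "g2"])
        profs = [_ess("g1", {"m": 0.2}), _ess("g2", {"m": 0.4})]
        assert total_metabolic_demand(ca, profs).iloc[0] == pytest.approx(0.3)

    def test_total_demand_single_genus_and_permutation_invariance(self):
        ca = _ca([[1.0]], ["g1"])
        assert total_metabolic_demand(ca, [_ess("g1", {"m": 0.7})]).iloc[0] == pytest.approx(0.7)
        ca2 = _ca([[0.25, 0.75]], ["g1", "g2"])
        profs = [_ess("g1", {"m": 0.1}), _ess("g2", {"m": 0.9})]
        assert total_metabolic_demand(ca2, profs).iloc[0] == pytest.approx(
            total_metabolic_demand(ca2, profs[::-1]).iloc[0]
        )

    def test_metabolite_demand_unscored_contributes_zero(self):
        ca = _ca([[0.25, 0.75]], ["g1", "g2"])
        profs = [_ess("g1", {"m": 1.0}), _ess("g2", {"other": 1.0})]
        assert metabolite_demand(ca, profs, "m").iloc[0] == pytest.approx(0.25)
        assert metabolite_demand(ca, profs, "nowhere").iloc[0] == 0.0

    def test_demand_bounded_by_per_genus_extremes(self):
        rng = np.random.default_rng(0)
        a = rng.dirichlet([1, 1, 1], size=4)
        ca = _ca(a, ["g1", "g2", "g3"])
        profs = [_ess(g, {"m": v}) for g, v in zip(["g1", "g2", "g3"], [0.2, 0.5, 0.9])]
        dem = total_metabolic_demand(ca, profs)
        assert ((dem >= 0.2 - 1e-12) & (dem <= 0.9 + 1e-12)).all()

    def test_demand_monotone_in_genus_essentiality(self):
        ca = _ca([[0.3, 0.7], [0.6, 0.4]], ["g1", "g2"])
        lo = [_ess("g1", {"m": 0.2}), _ess("g2", {"m": 0.5})]
        hi = [_ess("g1", {"m": 0.4}), _ess("g2", {"m": 0.5})]
        assert (
            total_metabolic_demand(ca, hi) >= total_metabolic_demand(ca, lo)
        ).all()


class TestMannWhitney:
    def test_exact_one_sided_textbook(self):
        # 20 arrangements, one as extreme: p = 0.05 for b systematically larger
        u, p = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(1 / 20)

    def test_identical_groups_two_sided_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3], alternative="two-sided")
        assert p == 1.0

    def test_u_identity(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=5), rng.normal(size=4)
        u_a, _ = mann_whitney(a, b)
        u_b, _ = mann_whitney(b, a)
        assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 5, size=10).astype(float)
        b = rng.integers(1, 6, size=10).astype(float)
        _, p = mann_whitney(a, b, alternative="two-sided")
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestZScoreRank:
    def _frame(self, agp_rows, ctrl_rows):
        data = np.vstack([agp_rows, ctrl_rows])
        idx = [f"t{i}" for i in range(len(agp_rows))] + [
            f"c{i}" for i in range(len(ctrl_rows))
        ]
        groups = pd.Series(
            ["agp"] * len(agp_rows) + ["control"] * len(ctrl_rows), index=idx
        )
        return pd.DataFrame(data, index=idx, columns=["f1"]), groups

    def test_worked_two_vs_four_example(self):
        df, groups = self._frame([[3.0], [5.0]], [[1.0], [1.0], [2.0], [2.0]])
        ranked = zscore_rank(df, groups, "agp")
        assert ranked.stats[0] == pytest.approx(2.402, abs=1e-3)

    def test_equal_means_give_zero(self):
        df, groups = self._frame([[2.0], [4.0]], [[1.0], [5.0]])
        assert zscore_rank(df, groups, "agp").stats[0] == pytest.approx(0.0)

    def test_degenerate_variance_sentinel(self):
        df, groups = self._frame([[2.0], [2.0]], [[1.0], [1.0]])
        assert zscore_rank(df, groups, "agp").stats[0] == Z_MAX

    def test_low_prevalence_features_filtered(self):
        df, groups = self._frame([[3.0], [5.0]], [[1.0], [1.0], [2.0], [2.0]])
        df["rare"] = [1.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        ranked = zscore_rank(df, groups, "agp")
        assert "rare" not in ranked.features


class TestCorrelationRank:
    def test_identity_and_reversal(self):
        w = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        df = pd.DataFrame({"same": w, "rev": w[::-1].to_numpy()}, index=w.index)
        ranked = correlation_rank(df, w, method="spearman")
        s = ranked.as_series()
        assert s["same"] == pytest.approx(1.0)
        assert s["rev"] == pytest.approx(-1.0)

    def test_one_swapped_pair_hand_rho(self):
        # sum d^2 = 2 -> rho = 1 - 12/120 = 0.9
        w = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0, 5.0, 4.0]}, index=w.index)
        assert correlation_rank(df, w).as_series()["f"] == pytest.approx(0.9)

    def test_pearson_log_matches_manual(self):
        w = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        df = pd.DataFrame({"f": [math.e, math.e**2, math.e**3]}, index=w.index)
        assert correlation_rank(df, w, method="pearson_log").as_series()["f"] == pytest.approx(1.0)

    def test_constant_feature_excluded_with_warning(self):
        w = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        df = pd.DataFrame({"f": [2.0, 2.0, 2.0], "g": [1.0, 2.0, 4.0]}, index=w.index)
        with pytest.warns(UserWarning, match="constant"):
            ranked = correlation_rank(df, w, min_nonzero_samples=1)
        assert "f" not in ranked.features


class TestMetabolomics:
    def test_scale_no_missing(self):
        auc = pd.DataFrame({"m": [2.0, 4.0, 6.0]})
        assert list(scale_and_impute(auc)["m"]) == pytest.approx([0.5, 1.0, 1.5])

    def test_min_imputation(self):
        auc = pd.DataFrame({"m": [10.0, np.nan, 30.0]})
        out = scale_and_impute(auc)
        assert list(out["m"]) == pytest.approx([0.5, 0.5, 1.5])

    def test_all_equal_and_never_observed(self):
        assert (scale_and_impute(pd.DataFrame({"m": [7.0, 7.0]}))["m"] == 1.0).all()
        with pytest.raises(ValueError, match="m"):
            scale_and_impute(pd.DataFrame({"m": [np.nan, np.nan]}))

    def test_observed_median_is_one(self):
        rng = np.random.default_rng(5)
        auc = pd.DataFrame(rng.lognormal(10, 1, size=(9, 4)))
        auc[auc < auc.quantile(0.2, axis=0)] = np.nan
        out = scale_and_impute(auc)
        for col in auc.columns:
            obs = auc[col].notna()
            assert out.loc[obs, col].median() == pytest.approx(1.0)

    def _welch_frame(self, a, b):
        idx = [f"t{i}" for i in range(len(a))] + [f"c{i}" for i in range(len(b))]
        groups = pd.Series(["t"] * len(a) + ["control"] * len(b), index=idx)
        df = pd.DataFrame({"m": np.exp(np.concatenate([a, b]))}, index=idx)
        return df, groups

    def test_equal_variance_toy_reduces_to_pooled(self):
        df, groups = self._welch_frame([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        _, table = welch_rank(df, groups, "t")
        assert table.loc["m", "t"] == pytest.approx(-math.sqrt(6), abs=1e-9)
        assert table.loc["m", "df"] == pytest.approx(4.0)

    def test_identical_groups_t_zero(self):
        df, groups = self._welch_frame([1.0, 2.0], [1.0, 2.0])
        _, table = welch_rank(df, groups, "t")
        assert table.loc["m", "t"] == 0.0

    def test_one_sided_variance_degenerate_is_finite(self):
        df, groups = self._welch_frame([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 2.0, 2.0])
        _, table = welch_rank(df, groups, "t")
        assert np.isfinite(table.loc["m", "t"])
        assert table.loc["m", "p"] < 0.05

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20))
    def test_bh_qvalues_monotone_and_bounded(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = multipletests(pvals, method="fdr_bh")[1]
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRankedFeatureList:
    def test_descending_with_id_tie_break(self):
        s = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0, "d": np.inf})
        ranked = RankedFeatureList.from_series(s)
        assert ranked.features == ("c", "a", "b")
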