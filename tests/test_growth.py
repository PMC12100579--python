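"""Relative growth rate, regression, ANOVA and post hoc machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermacclim import (
    DiameterCensus,
    a_per_nitrogen,
    group_anova,
    gs_at_growth_temperature,
    regress_rgr_on_agrowth,
    relative_growth_rate,
    sidak_posthoc,
)

from conftest import make_curve


def census(tree, day, diameter):
    return DiameterCensus(tree_id=tree, date=day, diameter=diameter)


class TestRGR:
    def test_exact_log_ratio(self):
        recs = [census("t", "2019-01-01", 10.0),
                census("t", "2021-01-01", 10.0 * np.exp(0.3))]
        r = relative_growth_rate(recs)
        span = (pd.Timestamp("2021-01-01") - pd.Timestamp("2019-01-01")).days / 365.25
        assert r.rgr == pytest.approx(0.3 / span, rel=1e-9)

    def test_no_growth_is_zero(self):
        recs = [census("t", "2019-01-01", 15.0), census("t", "2022-01-01", 15.0)]
        assert relative_growth_rate(recs).rgr == pytest.approx(0.0)

    def test_scale_invariance(self):
        recs = [census("t", "2019-01-01", 10.0), census("t", "2022-01-01", 14.0)]
        scaled = [census("t", "2019-01-01", 30.0), census("t", "2022-01-01", 42.0)]
        assert relative_growth_rate(recs).rgr == pytest.approx(
            relative_growth_rate(scaled).rgr, rel=1e-12
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            relative_growth_rate([census("t", "2019-01-01", 10.0)])
        with pytest.raises(ValueError):
            relative_growth_rate(
                [census("t", "2019-01-01", -1.0), census("t", "2020-01-01", 5.0)]
            )


class TestRegression:
    def test_perfect_line(self):
        pts = [(a, 0.01 + 0.02 * a) for a in (4, 6, 8, 10, 12)]
        res = regress_rgr_on_agrowth(pts)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(0.02)
        assert res["p_one_sided"] < 1e-8

    def test_zero_slope_gives_half(self):
        pts = [(4, 0.1), (6, 0.2), (8, 0.1), (10, 0.2), (12, 0.15)]
        # construct exactly zero sample slope by symmetrising
        x = np.array([4.0, 6.0, 8.0, 10.0, 12.0])
        y = np.array([0.1, 0.2, 0.15, 0.2, 0.1])  # symmetric about x mean
        res = regress_rgr_on_agrowth(list(zip(x, y)))
        assert res["slope"] == pytest.approx(0.0, abs=1e-15)
        assert res["p_one_sided"] == pytest.approx(0.5)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(101)
        x = rng.uniform(4, 14, 12)
        y = 0.05 + 0.004 * x + rng.normal(0, 0.02, 12)
        res = regress_rgr_on_agrowth(list(zip(x, y)))
        n_perm = 20000
        obs = stats.linregress(x, y).slope
        count = sum(
            stats.linregress(x, rng.permutation(y)).slope >= obs - 1e-15
            for _ in range(n_perm)
        )
        p_perm = count / n_perm
        assert abs(res["p_one_sided"] - p_perm) < 0.02

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            regress_rgr_on_agrowth([(5, 0.1), (5, 0.2), (5, 0.3)])


def study_shaped_table(rng, effects=False):
    """Species x site means shaped like the field design: montane at two
    sites, both lowland groups at three."""
    rows = []
    for group, n_sp, sites in [
        ("montane14", 9, ["14", "22"]),
        ("lowland22", 2, ["14", "22", "26"]),
        ("lowland26", 2, ["14", "22", "26"]),
    ]:
        for i in range(n_sp):
            for site in sites:
                mu = 25.0
                if effects:
                    mu += {"14": 0.0, "22": 2.0, "26": 4.0}[site]
                rows.append(
                    {"species": f"{group}_{i}", "group": group, "site": site,
                     "value": mu + rng.normal(0, 1.0)}
                )
    return pd.DataFrame(rows)


class TestAnova:
    def test_constant_response_gives_zero_f(self):
        df = study_shaped_table(np.random.default_rng(0))
        df["value"] = 7.0
        res = group_anova(df)
        for row in res["anova"]:
            if np.isfinite(row["F"]):
                assert row["F"] == pytest.approx(0.0, abs=1e-20)

    def test_study_shaped_df_structure(self):
        df = study_shaped_table(np.random.default_rng(1), effects=True)
        res = group_anova(df)
        rows = {r["factor"]: r for r in res["anova"]}
        assert rows["site"]["df"] == 2
        assert rows["group"]["df"] == 2
        # montane missing at 26 degC leaves the full interaction inestimable
        assert "flag" in rows["site:group"] or np.isfinite(rows["site:group"]["F"])
        assert 0 <= res["levene_p"] <= 1
        assert 0 <= res["shapiro_p"] <= 1

    def test_one_factor_reduction_equals_t_squared(self):
        rng = np.random.default_rng(5)
        rows = []
        for site, mu in [("14", 10.0), ("22", 12.0)]:
            for grp in ("g1", "g2"):
                for i in range(6):
                    rows.append({"site": site, "group": grp, "value": mu + rng.normal()})
        df = pd.DataFrame(rows)
        # collapse to one factor by making group orthogonal noise-free
        a = df[df.site == "14"]["value"]
        b = df[df.site == "22"]["value"]
        t2 = stats.ttest_ind(a, b, equal_var=True).statistic ** 2
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        m = smf.ols("value ~ C(site)", data=df.rename(columns={"value": "value"})).fit()
        f_site = anova_lm(m, typ=2).loc["C(site)", "F"]
        assert f_site == pytest.approx(t2, rel=1e-9)


class TestSidak:
    def test_single_comparison_unchanged(self):
        p = 0.031
        assert 1 - (1 - p) ** 1 == pytest.approx(p)

    def test_adjustment_arithmetic(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"site": ["14"] * 6 + ["22"] * 6,
             "group": (["g1"] * 3 + ["g2"] * 3) * 2,
             "value": rng.normal(10, 1, 12)}
        )
        res = sidak_posthoc(df)
        m = res["m"]
        assert m == 6  # C(4,2) pairs of cells
        for _, row in res["pairs"].iterrows():
            assert row["p_adj"] == pytest.approx(1 - (1 - row["p"]) ** m, rel=1e-12)

    def test_equal_cells_share_letters(self):
        df = pd.DataFrame(
            {"site": ["14"] * 4 + ["22"] * 4,
             "group": (["g1"] * 2 + ["g2"] * 2) * 2,
             "value": [5.0, 5.0] * 4}
        )
        res = sidak_posthoc(df)
        letters = set(res["letters"].values())
        assert letters == {"a"}

    def test_separated_cells_get_distinct_letters(self):
        df = pd.DataFrame(
            {"site": ["14"] * 6 + ["22"] * 6,
             "group": ["g1"] * 12,
             "value": [1.0, 1.01, 0.99, 1.02, 1.0, 0.98,
                       9.0, 9.01, 8.99, 9.02, 9.0, 8.98]}
        )
        res = sidak_posthoc(df)
        l = res["letters"]
        assert set(l["14:g1"]).isdisjoint(set(l["22:g1"]))


class TestGsExtraction:
    def test_returns_first_410_gs(self):
        curve = make_curve(60, 90, 1.0, 25.0)
        res = gs_at_growth_temperature([curve], site="22")
        first_410 = next(o for o in curve.observations
                         if abs(o.ca_setpoint - 410) < 1 and not o.return_410)
        assert res["gs"] == pytest.approx(first_410.gs)
        assert res["flag"] is None

    def test_site_to_temperature_mapping(self):
        c20 = make_curve(60, 90, 1.0, 20.0)
        c25 = make_curve(60, 90, 1.0, 25.0)
        res = gs_at_growth_temperature([c20, c25], site="22")
        assert res["t_leaf"] == 25.0

    def test_missing_temperature_flagged(self):
        c20 = make_curve(60, 90, 1.0, 20.0)
        res = gs_at_growth_temperature([c20], site="22")
        assert np.isnan(res["gs"]) and res["flag"] == "missing_temperature"


class TestAgN:
    def test_arithmetic(self):
        assert a_per_nitrogen(10.0, 2.0) == 5.0
        assert a_per_nitrogen(10.0, 4.0) == pytest.approx(a_per_nitrogen(10.0, 2.0) / 2)

    def test_invalid_nitrogen(self):
        with pytest.raises(ValueError):
            a_per_nitrogen(10.0, 0.0)

    def test_group_ordering_matches_recomputation(self):
        rng = np.random.default_rng(4)
        ag = rng.uniform(5, 15, 6)
        na = rng.uniform(1, 3, 6)
        vals = [a_per_nitrogen(a, n) for a, n in zip(ag, na)]
        assert np.argsort(vals).tolist() == np.argsort(ag / na).tolist()
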