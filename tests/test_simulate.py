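"""Synthetic campaign generator: determinism, truth recovery, oracle."""

import numpy as np
import pandas as pd
import pytest

from thermacclim import (
    default_truth_config,
    fit_aci_bilinear,
    fit_parabola,
    read_gas_exchange_table,
    simulate_campaign,
    simulate_growth,
    true_topt_oracle,
    validate_curve,
)
from thermacclim.simulate import _capacities_at, INTENDED_TOPTA_SHIFTS
from thermacclim import regress_rgr_on_agrowth, relative_growth_rate
from thermacclim.growth import DiameterCensus


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = default_truth_config(seed=42, species_per_group={"montane14": 1, "lowland22": 1, "lowland26": 0},
                                   trees_per_species_site=2)
        d1 = simulate_campaign(cfg)
        d2 = simulate_campaign(default_truth_config(seed=42, species_per_group={"montane14": 1, "lowland22": 1, "lowland26": 0},
                                                    trees_per_species_site=2))
        pd.testing.assert_frame_equal(d1.gas_exchange, d2.gas_exchange)
        pd.testing.assert_frame_equal(d1.growth, d2.growth)
        pd.testing.assert_frame_equal(d1.truth, d2.truth)

    def test_different_seed_differs(self):
        base = dict(species_per_group={"montane14": 1, "lowland22": 0, "lowland26": 0},
                    trees_per_species_site=1)
        d1 = simulate_campaign(default_truth_config(seed=1, **base))
        d2 = simulate_campaign(default_truth_config(seed=2, **base))
        assert not np.allclose(d1.gas_exchange["A"], d2.gas_exchange["A"])


class TestDesign:
    def test_montane_absent_at_hot_site(self, small_noisy_campaign):
        truth = small_noisy_campaign.truth
        montane = truth[truth["group"] == "montane14"]
        assert set(montane["site"]) == {"14", "22"}
        lowland = truth[truth["group"] == "lowland22"]
        assert set(lowland["site"]) == {"14", "22", "26"}

    def test_co2_sequence_and_return_tag(self, tiny_campaign):
        g = tiny_campaign.gas_exchange
        one = g[(g.tree_id == g.tree_id.iloc[0]) & (g.t_leaf_setpoint == 25.0)]
        assert list(one["co2_setpoint"]) == [410, 50, 100, 150, 250, 410, 800, 1200, 1600, 2000]
        assert list(one["return_410"]) == [False] * 5 + [True] + [False] * 4

    def test_site_temperature_ranges(self, small_noisy_campaign):
        g = small_noisy_campaign.gas_exchange
        assert set(g[g.site == "14"]["t_leaf_setpoint"]) == {15, 20, 25, 30, 35}
        assert set(g[g.site == "26"]["t_leaf_setpoint"]) == {20, 25, 30, 35, 40}

    def test_empty_design_rejected(self):
        cfg = default_truth_config(species_per_group={"montane14": 0, "lowland22": 0, "lowland26": 0})
        with pytest.raises(ValueError):
            simulate_campaign(cfg)


class TestTruthRecovery:
    def test_noiseless_bilinear_recovers_truth_on_clean_curves(self, tiny_campaign):
        curves = read_gas_exchange_table(tiny_campaign.gas_exchange)
        tree_truth = {r.tree_id: r for r in tiny_campaign.truth.itertuples()}
        checked = 0
        for c in curves:
            if not validate_curve(c)["pass"]:
                continue
            f = fit_aci_bilinear(c)
            if not f.converged or f.qc_flags:
                continue
            # only curves whose noiseless fit is exact (clean two-regime
            # geometry) are held to exact inversion
            if f.sse > 1e-12:
                continue
            tr = tree_truth[c.tree_id]
            vc, jm = _capacities_at(
                {k: getattr(tr, k) for k in
                 ("vcmax_kopt", "vcmax_topt", "vcmax_ea", "jmax_kopt", "jmax_topt", "jmax_ea")},
                c.t_leaf_setpoint,
            )
            assert f.params.vcmax == pytest.approx(vc, rel=1e-6)
            assert f.params.jmax == pytest.approx(jm, rel=1e-6)
            checked += 1
        assert checked >= 3

    def test_oracle_matches_parabola_on_dense_noiseless_sampling(self):
        cfg = default_truth_config()
        topt = true_topt_oracle(cfg, "montane14", "14")
        # parabola fit to dense noiseless ambient-CO2 response around optimum
        from thermacclim.simulate import _ci_ratio, _tree_params, _true_a_net

        tree = _tree_params(cfg.truths[("montane14", "14")],
                            {"kopt": 1.0, "topt": 0.0}, {"kopt": 1.0, "topt": 0.0})
        ts = np.arange(topt - 4, topt + 4.01, 0.5)
        pts = [(float(t), float(_true_a_net(tree, float(t), _ci_ratio(410.0, float(t), cfg) * 410.0, cfg)))
               for t in ts]
        f = fit_parabola(pts)
        assert abs(f.t_opt_a - topt) < 0.4

    def test_oracle_invariant_to_noise_setting(self):
        c1 = default_truth_config(noise_sd_a=0.0)
        c2 = default_truth_config(noise_sd_a=5.0)
        assert true_topt_oracle(c1, "lowland22", "22") == true_topt_oracle(c2, "lowland22", "22")

    def test_builtin_montane_shift_is_measured_by_oracle(self):
        cfg = default_truth_config()
        shift = (true_topt_oracle(cfg, "montane14", "22") - true_topt_oracle(cfg, "montane14", "14")) / 8.0
        assert shift == pytest.approx(INTENDED_TOPTA_SHIFTS[("montane14", "22")], abs=0.02)


class TestGrowthSimulation:
    def test_zero_noise_perfect_coupling(self):
        cfg = default_truth_config(seed=5, rgr_noise_sd=0.0,
                                   species_per_group={"montane14": 4, "lowland22": 1, "lowland26": 1})
        ds = simulate_campaign(cfg)
        merged = ds.growth.drop_duplicates("tree_id").merge(ds.truth, on="tree_id")
        sp = merged.groupby(["species", "site"])[["a_growth_true", "rgr_true"]].mean()
        res = regress_rgr_on_agrowth(sp.to_numpy())
        assert res["r_squared"] > 0.999

    def test_rgr_recoverable_from_census_series(self):
        cfg = default_truth_config(seed=5, species_per_group={"montane14": 1, "lowland22": 0, "lowland26": 0},
                                   trees_per_species_site=1)
        ds = simulate_campaign(cfg)
        for tid, g in ds.growth.groupby("tree_id"):
            recs = [DiameterCensus(tid, d, dia) for d, dia in zip(g["date"], g["diameter_mm"])]
            r = relative_growth_rate(recs)
            assert r.rgr == pytest.approx(g["rgr_true"].iloc[0], rel=1e-2)

    def test_coupling_calibrated_to_target_variance_explained(self):
        # defaults aim for ~30% of RGR variance explained by Agrowth at the
        # species x site level
        r2s = []
        for seed in range(30):
            cfg = default_truth_config(
                seed=seed, co2_sequence=(410.0,),
                site_temperatures={"14": (25.0,), "22": (25.0,), "26": (25.0,)},
            )
            ds = simulate_campaign(cfg)
            merged = ds.growth.drop_duplicates("tree_id").merge(ds.truth, on="tree_id")
            sp = merged.groupby(["species", "site"])[["a_growth_true", "rgr_true"]].mean()
            r2s.append(regress_rgr_on_agrowth(sp.to_numpy())["r_squared"])
        assert abs(float(np.mean(r2s)) - 0.30) < 0.08

    def test_null_coupling_gives_uniformish_p(self):
        ps = []
        for seed in range(40):
            cfg = default_truth_config(seed=seed, rgr_beta=0.0, rgr_noise_sd=0.01,
                                       species_per_group={"montane14": 4, "lowland22": 2, "lowland26": 2})
            ds = simulate_campaign(cfg)
            merged = ds.growth.drop_duplicates("tree_id").merge(ds.truth, on="tree_id")
            sp = merged.groupby(["species", "site"])[["a_growth_true", "rgr_true"]].mean()
            ps.append(regress_rgr_on_agrowth(sp.to_numpy())["p_one_sided"])
        # under the null the one-sided p is Uniform(0,1)
        assert 0.25 < np.mean(ps) < 0.75
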