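"""Readers, writers, configuration and the end-to-end analysis pipeline.

The canonical input is a long-format gas-exchange CSV (one row per A-Ci
observation) plus a diameter-census CSV.  ``run_pipeline`` chains the full
analysis: quality control, per-curve bilinear FvCB fits, per-tree thermal
response fits (parabola for net A, peaked Arrhenius for Vcmax/Jmax),
derived acclimation metrics (Tmax, Agrowth, AgN, gs at growth temperature),
the stomatal and respiratory counterfactual optima, relative growth rates
with the RGR~Agrowth regression, and the group-level ANOVA/post hoc tables.
Every stage's output is persisted as tidy CSV so each final number can be
recomputed from the intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aci import ACiCurve, LeafObservation, QCRules, fit_aci_bilinear, validate_curve
from .counterfactuals import (
    DEFAULT_CI_COMMON,
    common_ci_response,
    compare_topt,
    gross_response,
    topt_counterfactual,
)
from .fvcb import BERNACCHI_2001, KineticConstants
from .growth import (
    DiameterCensus,
    a_per_nitrogen,
    group_anova,
    gs_at_growth_temperature,
    regress_rgr_on_agrowth,
    relative_growth_rate,
    sidak_posthoc,
)
from .thermal import (
    DEFAULT_SITE_CLIMATES,
    fit_parabola,
    fit_peaked_arrhenius,
    per_degree_shift,
    tmax_from_parabola,
    value_at_growth_temperature,
)

__all__ = [
    "PipelineConfig",
    "read_gas_exchange_table",
    "read_growth_table",
    "write_gas_exchange_table",
    "run_pipeline",
]

log = logging.getLogger("thermacclim")

GASX_COLUMNS = ["tree_id", "species", "group", "site", "t_leaf_setpoint",
                "co2_setpoint", "A", "Ci", "Ca", "gs", "Q"]


@dataclass
class PipelineConfig:
    gasx_path: str | None = None
    growth_path: str | None = None
    out_dir: str | None = None
    site_climates: dict = field(default_factory=lambda: dict(DEFAULT_SITE_CLIMATES))
    kinetics: KineticConstants = BERNACCHI_2001
    qc_rules: QCRules = QCRules()
    h_d: float = 200.0  # kJ mol-1, fixed in the peaked-Arrhenius fits
    min_points_per_regime: int = 3
    ci_common: float = DEFAULT_CI_COMMON
    gross_ci_mode: str = "observed_410"
    n_area: float = 2.0  # g N m-2 used for AgN when no nitrogen column exists
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kin = raw.pop("kinetics", None)
        qc = raw.pop("qc_rules", None)
        cfg = cls(**raw)
        if kin:
            cfg.kinetics = KineticConstants(**kin)
        if qc:
            cfg.qc_rules = QCRules(**qc)
        return cfg


def read_gas_exchange_table(path_or_df, column_map: dict | None = None) -> list:
    """Parse a long-format gas-exchange CSV into ACiCurve objects.

    Rows are grouped by tree x leaf-temperature setpoint in measurement
    order (a ``seq`` column when present, file order otherwise); the second
    pass through the 410 umol mol-1 setpoint is tagged ``return_410``.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in GASX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gas-exchange table missing column(s): {', '.join(missing)}")

    bad = ~np.isfinite(df[["A", "Ci", "Ca", "t_leaf_setpoint"]].apply(pd.to_numeric, errors="coerce")).all(axis=1)
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("skipped %d unparseable gas-exchange rows", n_bad)
        df = df[~bad]
    if "seq" in df.columns:
        df = df.sort_values(["tree_id", "t_leaf_setpoint", "seq"], kind="stable")

    curves = []
    for (tree_id, t_set), g in df.groupby(["tree_id", "t_leaf_setpoint"], sort=True):
        obs = []
        seen_410 = False
        for _, row in g.iterrows():
            is_410 = abs(float(row["Ca"]) - 410.0) < 1.0
            obs.append(
                LeafObservation(
                    a_net=float(row["A"]),
                    ci=float(row["Ci"]),
                    ca_setpoint=float(row["Ca"]),
                    gs=float(row["gs"]),
                    t_leaf=float(row.get("t_leaf", t_set)),
                    ppfd=float(row["Q"]),
                    return_410=bool(is_410 and seen_410),
                )
            )
            if is_410:
                seen_410 = True
        first = g.iloc[0]
        curves.append(
            ACiCurve(
                tree_id=str(tree_id),
                species=str(first["species"]),
                provenance_group=str(first["group"]),
                site=str(first["site"]),
                t_leaf_setpoint=float(t_set),
                observations=obs,
            )
        )
    return curves


def write_gas_exchange_table(curves, path) -> None:
    rows = []
    for c in curves:
        for i, o in enumerate(c.observations):
            rows.append(
                {
                    "tree_id": c.tree_id, "species": c.species, "group": c.provenance_group,
                    "site": c.site, "t_leaf_setpoint": c.t_leaf_setpoint, "seq": i,
                    "co2_setpoint": o.ca_setpoint, "A": o.a_net, "Ci": o.ci,
                    "Ca": o.ca_setpoint, "gs": o.gs, "Q": o.ppfd, "t_leaf": o.t_leaf,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_growth_table(path_or_df) -> dict:
    """Growth CSV (tree_id, date ISO-8601, diameter_mm) -> censuses per tree."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    missing = [c for c in ("tree_id", "date", "diameter_mm") if c not in df.columns]
    if missing:
        raise ValueError(f"growth table missing column(s): {', '.join(missing)}")
    out = {}
    for tree_id, g in df.groupby("tree_id"):
        out[str(tree_id)] = [
            DiameterCensus(tree_id=str(tree_id), date=str(r["date"]), diameter=float(r["diameter_mm"]))
            for _, r in g.iterrows()
        ]
    return out


def _first_410(curve: ACiCurve):
    for o in curve.observations:
        if abs(o.ca_setpoint - 410.0) < 1.0 and not o.return_410:
            return o
    return None


def _fit_tree(tree_curves, fits_by_temp, config: PipelineConfig) -> dict:
    """All per-tree thermal metrics from its per-temperature curves/fits."""
    c0 = tree_curves[0]
    site = str(c0.site)
    climate = config.site_climates[site]
    row = {
        "tree_id": c0.tree_id, "species": c0.species, "group": c0.provenance_group,
        "site": site, "flags": [],
    }

    # net photosynthesis at ambient CO2 versus leaf temperature (measured A)
    at_pairs = []
    for curve in tree_curves:
        o = _first_410(curve)
        if o is not None:
            at_pairs.append((curve.t_leaf_setpoint, o.a_net))
    if len(at_pairs) >= 3:
        pfit = fit_parabola(at_pairs)
        if pfit.curvature_ok:
            row.update(t_opt_a=pfit.t_opt_a, b=pfit.b, a_opt=pfit.a_opt)
            row["t_max"] = tmax_from_parabola(pfit) if pfit.a_opt > 0 else float("nan")
            row["a_growth"] = value_at_growth_temperature(pfit, climate)
            row["a_g_n"] = a_per_nitrogen(row["a_growth"], config.n_area)
        else:
            row["flags"].append("parabola_no_peak")
    else:
        row["flags"].append("too_few_temperatures")

    # apparent capacity temperature responses
    conv = [f for f in fits_by_temp if f.converged]
    if len(conv) >= 4:
        v_pts = [(f.params.t_leaf, f.params.vcmax) for f in conv]
        j_pts = [(f.params.t_leaf, f.params.jmax) for f in conv]
        span_ok = max(p[0] for p in v_pts) - min(p[0] for p in v_pts) >= 10
        if span_ok:
            vfit = fit_peaked_arrhenius(v_pts, h_d=config.h_d)
            jfit = fit_peaked_arrhenius(j_pts, h_d=config.h_d)
            if vfit.converged:
                row.update(t_opt_v=vfit.t_opt, e_a_v=vfit.e_a, vcmax_opt=vfit.k_opt,
                           vcmax_growth=value_at_growth_temperature(vfit, climate))
                row["flags"].extend(f"vcmax_{fl}" for fl in vfit.qc_flags)
            if jfit.converged:
                row.update(t_opt_j=jfit.t_opt, e_a_j=jfit.e_a, jmax_opt=jfit.k_opt,
                           jmax_growth=value_at_growth_temperature(jfit, climate))
                row["flags"].extend(f"jmax_{fl}" for fl in jfit.qc_flags)

    # counterfactual optima
    if len(conv) >= 3:
        try:
            cf = topt_counterfactual(common_ci_response(conv, config.ci_common, config.kinetics))
            if cf.curvature_ok:
                row["t_opt_287"] = cf.t_opt_a
            gf = topt_counterfactual(
                gross_response(conv, config.gross_ci_mode, config.ci_common, config.kinetics)
            )
            if gf.curvature_ok:
                row["t_opt_gross"] = gf.t_opt_a
        except ValueError as exc:
            row["flags"].append(f"counterfactual_failed:{exc}")

    gs_res = gs_at_growth_temperature(tree_curves, site)
    row["gs_growth"] = gs_res["gs"]
    if gs_res["flag"]:
        row["flags"].append(f"gs_{gs_res['flag']}")
    row["flags"] = ";".join(row["flags"])
    return row


TRAITS_FOR_ANOVA = ["t_opt_a", "b", "a_opt", "t_max", "a_growth", "a_g_n",
                    "t_opt_v", "t_opt_j", "gs_growth"]


def run_pipeline(config: PipelineConfig, gasx=None, growth=None) -> dict:
    """Run the full acclimation analysis; returns a results bundle.

    ``gasx``/``growth`` may be DataFrames (overriding the config paths).
    The bundle holds the per-curve fits, the per-tree trait table, the
    species x site means, acclimation slopes, counterfactual comparisons,
    the RGR regression and the ANOVA tables, plus per-stage counts.
    """
    counts = {}
    curves = read_gas_exchange_table(gasx if gasx is not None else config.gasx_path)
    counts["curves_read"] = len(curves)
    if not curves:
        raise RuntimeError("stage read_gas_exchange: no curves in input")

    kept = []
    for c in curves:
        if validate_curve(c, config.qc_rules)["pass"]:
            kept.append(c)
    counts["curves_qc_passed"] = len(kept)
    if not kept:
        raise RuntimeError("stage qc: no curves passed quality control")

    fit_rows, fits_by_tree, curves_by_tree = [], {}, {}
    for c in kept:
        fit = fit_aci_bilinear(c, config.kinetics, config.min_points_per_regime)
        curves_by_tree.setdefault(c.tree_id, []).append(c)
        fits_by_tree.setdefault(c.tree_id, []).append(fit)
        fit_rows.append(
            {
                "tree_id": c.tree_id, "species": c.species, "group": c.provenance_group,
                "site": c.site, "t_leaf": c.t_leaf_setpoint,
                "vcmax": fit.params.vcmax if fit.converged else float("nan"),
                "jmax": fit.params.jmax if fit.converged else float("nan"),
                "rday": fit.params.rday if fit.converged else float("nan"),
                "ci_transition": fit.ci_transition, "sse": fit.sse,
                "n_rubisco": fit.n_rubisco, "n_rubp": fit.n_rubp,
                "converged": fit.converged, "flags": ";".join(fit.qc_flags),
            }
        )
    aci_fits = pd.DataFrame(fit_rows)
    counts["aci_fits_converged"] = int(aci_fits["converged"].sum())
    if counts["aci_fits_converged"] == 0:
        raise RuntimeError("stage aci_fitting: no curve fit converged")

    tree_rows = [
        _fit_tree(curves_by_tree[tid], fits_by_tree[tid], config) for tid in sorted(curves_by_tree)
    ]
    trees = pd.DataFrame(tree_rows)
    counts["trees_fit"] = len(trees)

    # species x site means (the paper-level analysis unit)
    numeric = [c for c in trees.columns if c not in ("tree_id", "species", "group", "site", "flags")]
    species_means = (
        trees.groupby(["species", "group", "site"], as_index=False)[numeric].mean()
    )

    # acclimation slopes per provenance group between adjacent sites
    shifts = []
    for group, g in species_means.groupby("group"):
        site_means = g.groupby("site")["t_opt_a"].mean().dropna()
        sites = sorted(site_means.index, key=lambda s: config.site_climates[s].mat)
        for s1, s2 in zip(sites, sites[1:]):
            shifts.append(
                {
                    "group": group, "site_from": s1, "site_to": s2,
                    "shift_per_degC": per_degree_shift(
                        {s1: site_means[s1], s2: site_means[s2]}, config.site_climates
                    ),
                }
            )
    shift_table = pd.DataFrame(shifts)

    # counterfactual comparisons per group x site
    cf_rows = []
    for (group, site), g in trees.groupby(["group", "site"]):
        for col, label in (("t_opt_287", "common_ci"), ("t_opt_gross", "gross")):
            if col in g.columns:
                obs = g["t_opt_a"].dropna()
                cfv = g[col].dropna()
                if obs.size >= 2 and cfv.size >= 2:
                    res = compare_topt(obs.to_numpy(), cfv.to_numpy())
                    cf_rows.append(
                        {
                            "group": group, "site": site, "counterfactual": label,
                            "n": int(min(obs.size, cfv.size)),
                            "mean_delta": float(cfv.mean() - obs.mean()),
                            "t": res["t_stat"], "df": res["df"], "p": res["p_two_sided"],
                        }
                    )
    counterfactual_table = pd.DataFrame(cf_rows)

    # growth
    rgr_df = regression = None
    growth_in = growth if growth is not None else config.growth_path
    if growth_in is not None:
        censuses = read_growth_table(growth_in)
        rgr_rows = []
        for tid, recs in censuses.items():
            try:
                r = relative_growth_rate(recs)
            except ValueError:
                continue
            rgr_rows.append({"tree_id": tid, "rgr": r.rgr, "span_years": r.span_years})
        rgr_df = pd.DataFrame(rgr_rows)
        counts["trees_with_rgr"] = len(rgr_df)
        merged = trees.merge(rgr_df, on="tree_id", how="inner")
        sp = merged.groupby(["species", "site"], as_index=False)[["a_growth", "rgr"]].mean().dropna()
        if len(sp) >= 3:
            regression = regress_rgr_on_agrowth(sp[["a_growth", "rgr"]].to_numpy())

    # group statistics on species x site means
    anova_tables, posthoc_letters = {}, {}
    stats_input = species_means.rename(columns={"group": "group"})
    for trait in TRAITS_FOR_ANOVA:
        if trait not in stats_input.columns:
            continue
        sub = stats_input[["site", "group", trait]].dropna()
        if sub["site"].nunique() < 2 or sub["group"].nunique() < 2 or len(sub) < 6:
            continue
        res = group_anova(sub, value_col=trait)
        anova_tables[trait] = {
            "anova": res["anova"], "levene_p": res["levene_p"], "shapiro_p": res["shapiro_p"],
        }
        posthoc_letters[trait] = sidak_posthoc(sub, value_col=trait)["letters"]

    bundle = {
        "curves": kept,
        "aci_fits": aci_fits,
        "trees": trees,
        "species_means": species_means,
        "shift_table": shift_table,
        "counterfactuals": counterfactual_table,
        "rgr": rgr_df,
        "rgr_regression": regression,
        "anova": anova_tables,
        "posthoc_letters": posthoc_letters,
        "counts": counts,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aci_fits.to_csv(out / "aci_fits.csv", index=False)
        trees.to_csv(out / "tree_traits.csv", index=False)
        species_means.to_csv(out / "species_means.csv", index=False)
        shift_table.to_csv(out / "acclimation_shifts.csv", index=False)
        counterfactual_table.to_csv(out / "counterfactual_tests.csv", index=False)
        if rgr_df is not None:
            rgr_df.to_csv(out / "rgr.csv", index=False)
        anova_rows = []
        for trait, res in anova_tables.items():
            for r in res["anova"]:
                anova_rows.append({"trait": trait, **r, "levene_p": res["levene_p"],
                                   "shapiro_p": res["shapiro_p"]})
        pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
        with open(out / "run_log.txt", "w") as fh:
            for k, v in counts.items():
                fh.write(f"{k}: {v}\n")
            if regression:
                fh.write(f"rgr_regression: slope={regression['slope']:.5g} "
                         f"r2={regression['r_squared']:.3f} p={regression['p_one_sided']:.3g}\n")
    return bundle
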