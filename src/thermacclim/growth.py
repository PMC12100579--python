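"""Relative growth rates and the group-level statistical analyses.

Relative growth rate follows the log-ratio convention

    RGR = (ln D_i - ln D_0) / (t_i - t_0)        [mm mm-1 year-1]

between a tree's first and latest diameter census.  Trait analysis uses
species x site means: a two-way ANOVA (site and provenance group as
factors, type-II sums of squares for the unbalanced design), Levene and
Shapiro-Wilk assumption checks, Sidak-adjusted pairwise post hoc contrasts
with a compact letter display, and a one-sided regression testing whether
net photosynthesis at growth temperature predicts RGR.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "DiameterCensus",
    "RGRResult",
    "relative_growth_rate",
    "regress_rgr_on_agrowth",
    "group_anova",
    "sidak_posthoc",
    "gs_at_growth_temperature",
    "a_per_nitrogen",
    "GS_EXTRACTION_TEMPERATURES",
]


@dataclass(frozen=True)
class DiameterCensus:
    tree_id: str
    date: date
    diameter: float  # mm


@dataclass(frozen=True)
class RGRResult:
    tree_id: str
    rgr: float  # mm mm-1 year-1
    span_years: float


def _as_date(d) -> date:
    if isinstance(d, datetime):
        return d.date()
    if isinstance(d, date):
        return d
    return datetime.strptime(str(d), "%Y-%m-%d").date()


def relative_growth_rate(censuses) -> RGRResult:
    """RGR from the first and latest census of one tree (natural log)."""
    if len(censuses) < 2:
        raise ValueError("need at least 2 censuses")
    recs = sorted(censuses, key=lambda c: _as_date(c.date))
    first, last = recs[0], recs[-1]
    if first.diameter <= 0 or last.diameter <= 0:
        raise ValueError("diameters must be positive")
    span = (_as_date(last.date) - _as_date(first.date)).days / 365.25
    if span <= 0:
        raise ValueError("census dates must span a positive interval")
    rgr = (np.log(last.diameter) - np.log(first.diameter)) / span
    return RGRResult(tree_id=first.tree_id, rgr=float(rgr), span_years=float(span))


def regress_rgr_on_agrowth(species_means) -> dict:
    """OLS of RGR on Agrowth over species means, one-sided test for slope > 0."""
    pts = np.asarray(species_means, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("species_means must be (a_growth, rgr) pairs")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 species means")
    x, y = pts[:, 0], pts[:, 1]
    if np.var(x) == 0:
        raise ValueError("a_growth has zero variance; slope undefined")
    res = stats.linregress(x, y)
    # one-sided: H1 slope > 0
    p_one = res.pvalue / 2.0 if res.slope > 0 else 1.0 - res.pvalue / 2.0
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_one_sided": float(p_one),
        "n": int(pts.shape[0]),
    }


def group_anova(trait_table: pd.DataFrame, value_col: str = "value") -> dict:
    """Two-way type-II ANOVA of a trait over species x site means.

    ``trait_table`` needs columns ``site``, ``group`` and ``value_col``; one
    row per species x site mean.  The site x group interaction is included
    only when every parameter is estimable (no empty cells); otherwise the
    interaction row is flagged and the main-effects model is reported.
    Levene's test runs across the site x group cells and Shapiro-Wilk on
    the model residuals.
    """
    df = trait_table.rename(columns={value_col: "_y"}).copy()
    for col in ("site", "group"):
        if col not in df.columns:
            raise ValueError(f"trait_table missing column {col!r}")
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    df["site"] = df["site"].astype(str)
    df["group"] = df["group"].astype(str)

    if np.ptp(df["_y"].to_numpy()) == 0:
        # degenerate constant response: every factor explains nothing
        cells = df.groupby(["site", "group"]).ngroups
        df_res = float(len(df) - cells)
        rows = [
            {"factor": f, "df": float(df[c].nunique() - 1), "df_res": df_res, "F": 0.0, "p": 1.0}
            for f, c in (("site", "site"), ("group", "group"))
        ]
        return {"anova": rows, "levene_p": float("nan"), "shapiro_p": float("nan"),
                "model": None, "residual_df": df_res}

    full = smf.ols("_y ~ C(site) * C(group)", data=df).fit()
    interaction_estimable = np.linalg.matrix_rank(full.model.exog) == full.model.exog.shape[1]
    model = full if interaction_estimable else smf.ols("_y ~ C(site) + C(group)", data=df).fit()
    table = anova_lm(model, typ=2)

    rows = []
    name_map = {"C(site)": "site", "C(group)": "group", "C(site):C(group)": "site:group"}
    df_res = float(table.loc["Residual", "df"])
    for idx, row in table.iterrows():
        if idx == "Residual":
            continue
        rows.append(
            {
                "factor": name_map.get(idx, idx),
                "df": float(row["df"]),
                "df_res": df_res,
                "F": float(row["F"]),
                "p": float(row["PR(>F)"]),
            }
        )
    if not interaction_estimable:
        rows.append(
            {"factor": "site:group", "df": float("nan"), "df_res": df_res,
             "F": float("nan"), "p": float("nan"), "flag": "inestimable_empty_cells"}
        )

    cells = [g["_y"].to_numpy() for _, g in df.groupby(["site", "group"]) if len(g) > 1]
    spread = [c for c in cells if np.ptp(c) > 0]
    levene_p = float(stats.levene(*cells).pvalue) if len(cells) >= 2 and len(spread) >= 2 else float("nan")
    resid = model.resid.to_numpy()
    shapiro_p = float(stats.shapiro(resid).pvalue) if resid.size >= 3 and np.ptp(resid) > 0 else float("nan")

    return {
        "anova": rows,
        "levene_p": levene_p,
        "shapiro_p": shapiro_p,
        "model": model,
        "residual_df": df_res,
    }


def sidak_posthoc(trait_table: pd.DataFrame, value_col: str = "value", alpha: float = 0.05) -> dict:
    """Sidak-adjusted pairwise contrasts among site x group cells.

    Pairwise Welch t-tests between every pair of non-empty cells; adjusted
    p_adj = 1 - (1 - p)^m with m the number of comparisons.  Returns the
    pairwise table and a compact letter display at ``alpha``: cells sharing
    a letter are not significantly different.
    """
    df = trait_table.rename(columns={value_col: "_y"}).copy()
    df["cell"] = df["site"].astype(str) + ":" + df["group"].astype(str)
    groups = {cell: g["_y"].to_numpy(dtype=float) for cell, g in df.groupby("cell")}
    cells = sorted(groups)
    pairs = list(combinations(cells, 2))
    m = len(pairs)
    if m == 0:
        return {"pairs": pd.DataFrame(), "letters": {c: "a" for c in cells}, "m": 0}

    records = []
    sig = set()
    for c1, c2 in pairs:
        a, b = groups[c1], groups[c2]
        if a.size < 2 or b.size < 2 or (np.var(a) == 0 and np.var(b) == 0):
            p = 1.0 if np.mean(a) == np.mean(b) else 0.0
            tstat = 0.0 if p == 1.0 else float("inf")
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            tstat, p = float(res.statistic), float(res.pvalue)
        p_adj = 1.0 - (1.0 - p) ** m
        if p_adj < alpha:
            sig.add((c1, c2))
        records.append({"cell_a": c1, "cell_b": c2, "t": tstat, "p": p, "p_adj": p_adj})

    letters = _compact_letter_display(cells, sig, means={c: float(np.mean(groups[c])) for c in cells})
    return {"pairs": pd.DataFrame(records), "letters": letters, "m": m}


def _compact_letter_display(cells, significant_pairs, means) -> dict:
    """Insert-and-absorb compact letter display.

    Cells in the same letter set are mutually non-significant; every
    significant pair ends up with disjoint letters.
    """
    order = sorted(cells, key=lambda c: -means[c])
    sets = [set(order)]
    for c1, c2 in significant_pairs:
        new_sets = []
        for s in sets:
            if c1 in s and c2 in s:
                new_sets.append(s - {c1})
                new_sets.append(s - {c2})
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: -max(means[c] for c in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {c: "" for c in cells}
    for i, s in enumerate(sets):
        for c in order:
            if c in s:
                letters[c] += alphabet[i % len(alphabet)]
    return letters


#: Leaf temperature at which gs-at-growth-temperature is read off, per site
#: (closest measured setpoint to each site's daytime growth temperature).
GS_EXTRACTION_TEMPERATURES = {"14": 20.0, "22": 25.0, "26": 30.0}


def gs_at_growth_temperature(curves, site: str, ca: float = 410.0) -> dict:
    """Stomatal conductance near growth temperature for one tree.

    Looks for the curve measured at the site's designated extraction
    temperature and returns gs at its first 410 umol mol-1 setpoint.
    """
    site = str(site)
    if site not in GS_EXTRACTION_TEMPERATURES:
        raise ValueError(f"unknown site {site!r}")
    t_want = GS_EXTRACTION_TEMPERATURES[site]
    for curve in curves:
        if abs(curve.t_leaf_setpoint - t_want) < 0.5:
            for obs in curve.observations:
                if abs(obs.ca_setpoint - ca) < 1.0 and not obs.return_410:
                    return {"gs": float(obs.gs), "t_leaf": curve.t_leaf_setpoint, "flag": None}
            return {"gs": float("nan"), "t_leaf": t_want, "flag": "missing_410_setpoint"}
    return {"gs": float("nan"), "t_leaf": t_want, "flag": "missing_temperature"}


def a_per_nitrogen(a_growth: float, n_area: float) -> float:
    """Photosynthesis at growth temperature per unit leaf nitrogen (AgN)."""
    if n_area <= 0:
        raise ValueError("n_area must be positive")
    return float(a_growth) / float(n_area)
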