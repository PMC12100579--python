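"""Forward simulation of a multi-site gas-exchange and growth campaign.

The generator emulates a common-garden thermosequence study: 13 species in
three provenance groups (nine montane "14C" species, two lowland "22C" and
two lowland "26C" species) planted at three sites whose mean annual
temperatures are 14, 22 and 26 degC, with about four trees per species and
site.  Montane trees are absent from the 26 degC site (mirroring their
total mortality there).  Each tree is measured with A-Ci curves at five
leaf temperatures (15-35 degC at the two cooler sites, 20-40 degC at the
warmest) over the CO2 setpoint sequence
410, 50, 100, 150, 250, 410, 800, 1200, 1600, 2000 umol mol-1.

Truth: per group x site, apparent Vcmax and Jmax follow peaked-Arrhenius
temperature responses whose optima are shifted between sites by built-in
acclimation slopes (0.6 degC per degC of warming for montane species);
day respiration rises linearly with temperature; the stomatal model holds
Ci/Ca at a per-setpoint ratio (0.7 at 410 umol mol-1), optionally drifting
with leaf temperature.  Gaussian instrument noise (sd 0.3 umol m-2 s-1)
is added to net assimilation only.  Tree diameters grow exponentially with
an RGR noisily coupled to each tree's photosynthesis at growth
temperature.  Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .fvcb import BERNACCHI_2001, FvCBParams, KineticConstants, fvcb_assimilation
from .thermal import DEFAULT_SITE_CLIMATES, PeakedArrheniusFit, peaked_rate

__all__ = [
    "GroupSiteTruth",
    "TruthConfig",
    "SimulatedDataset",
    "default_truth_config",
    "simulate_campaign",
    "simulate_growth",
    "true_topt_oracle",
]

CO2_SEQUENCE = (410.0, 50.0, 100.0, 150.0, 250.0, 410.0, 800.0, 1200.0, 1600.0, 2000.0)
SITE_TEMPERATURES = {
    "14": (15.0, 20.0, 25.0, 30.0, 35.0),
    "22": (15.0, 20.0, 25.0, 30.0, 35.0),
    "26": (20.0, 25.0, 30.0, 35.0, 40.0),
}
#: Ci/Ca declines as the reference CO2 rises; near the compensation point
#: (low Ca) assimilation is ~0 and Ci approaches Ca.
CI_RATIO_NODES = ((50.0, 0.95), (150.0, 0.80), (410.0, 0.70), (800.0, 0.66), (2000.0, 0.60))


@dataclass(frozen=True)
class GroupSiteTruth:
    """Peaked-Arrhenius truth for one provenance group at one site."""

    vcmax_kopt: float
    vcmax_topt: float
    vcmax_ea: float  # kJ mol-1
    jmax_kopt: float
    jmax_topt: float
    jmax_ea: float  # kJ mol-1


@dataclass
class TruthConfig:
    species_per_group: dict = field(
        default_factory=lambda: {"montane14": 9, "lowland22": 2, "lowland26": 2}
    )
    group_sites: dict = field(
        default_factory=lambda: {
            "montane14": ("14", "22"),
            "lowland22": ("14", "22", "26"),
            "lowland26": ("14", "22", "26"),
        }
    )
    trees_per_species_site: int = 4
    site_temperatures: dict = field(default_factory=lambda: dict(SITE_TEMPERATURES))
    co2_sequence: tuple = CO2_SEQUENCE
    truths: dict = field(default_factory=dict)  # (group, site) -> GroupSiteTruth
    rday_25: float = 1.0
    rday_slope: float = 0.04  # umol m-2 s-1 per degC; 0 = temperature-invariant
    ci_ratio_temp_slope: float = 0.0  # d(Ci/Ca)/dT; 0 = stomatally null
    noise_sd_a: float = 0.3  # umol m-2 s-1 on Anet
    species_kopt_cv: float = 0.10  # lognormal sd of species effects on kopt
    species_topt_sd: float = 0.8  # degC
    tree_kopt_cv: float = 0.05
    tree_topt_sd: float = 0.4  # degC
    rgr_alpha: float = 0.02  # mm mm-1 yr-1
    rgr_beta: float = 0.012  # per (umol m-2 s-1)
    rgr_target_r2: float = 0.30  # variance in RGR explained by Agrowth
    rgr_noise_sd: float | None = None  # overrides rgr_target_r2 when set
    n_area: float = 2.0  # g N m-2, used for the AgN column
    seed: int = 0
    kinetics: KineticConstants = BERNACCHI_2001

    def replace(self, **kw) -> "TruthConfig":
        return replace(self, **kw)


@dataclass
class SimulatedDataset:
    gas_exchange: pd.DataFrame  # long format, one row per observation
    growth: pd.DataFrame  # one row per census
    truth: pd.DataFrame  # one row per tree
    config: TruthConfig


#: Built-in thermal acclimation of net photosynthesis, as degC of ToptA
#: shift per degC of site MAT change from the group's home climate
#: (montane species warm-shift 0.6 degC/degC; the warm-origin lowland group
#: cool-shifts weakly).
INTENDED_TOPTA_SHIFTS = {
    ("montane14", "22"): 0.6,
    ("lowland22", "14"): 0.0,
    ("lowland22", "26"): 1.2,
    ("lowland26", "14"): 0.23,
    ("lowland26", "22"): 0.0,
}
HOME_MAT = {"montane14": 14.0, "lowland22": 22.0, "lowland26": 26.0}
#: Home-site truths: kopt at optimum (umol m-2 s-1), Topt (degC), Ea (kJ mol-1).
#: The Jmax:Vcmax balance keeps ambient-CO2 photosynthesis at or near the
#: Ac/Aj co-limitation point, so shifting both capacity optima moves the net
#: optimum almost one-for-one — the acclimation mechanism the generator uses.
HOME_TRUTHS = {
    "montane14": GroupSiteTruth(115.0, 32.622, 70.0, 86.0, 23.622, 38.0),
    "lowland22": GroupSiteTruth(125.0, 37.233, 70.0, 94.0, 28.233, 38.0),
    "lowland26": GroupSiteTruth(132.0, 38.620, 70.0, 99.0, 29.620, 38.0),
}
#: Capacity-optimum offsets (degC, applied to both ToptV and ToptJ) that
#: realise the intended ToptA shifts above in the noiseless forward model,
#: calibrated once against the 0.01 degC oracle grid.  The offsets are not
#: identical to the ToptA shifts because the Rubisco kinetics and the Rday
#: ramp, which do not acclimate, bend the net response.
CAPACITY_TOPT_OFFSETS = {
    ("montane14", "22"): 5.5189,
    ("lowland22", "14"): 0.0,
    ("lowland22", "26"): 4.7895,
    ("lowland26", "14"): -1.1236,
    ("lowland26", "22"): 0.0,
}


def _fill_truths(cfg: TruthConfig) -> None:
    truths = {}
    for group, sites in cfg.group_sites.items():
        base = HOME_TRUTHS[group]
        for site in sites:
            shift = CAPACITY_TOPT_OFFSETS.get((group, site), 0.0)
            truths[(group, site)] = GroupSiteTruth(
                vcmax_kopt=base.vcmax_kopt,
                vcmax_topt=base.vcmax_topt + shift,
                vcmax_ea=base.vcmax_ea,
                jmax_kopt=base.jmax_kopt,
                jmax_topt=base.jmax_topt + shift,
                jmax_ea=base.jmax_ea,
            )
    cfg.truths = truths


def default_truth_config(**overrides) -> TruthConfig:
    """The default campaign truth, acclimation shifts built in."""
    cfg = TruthConfig(**overrides)
    if not cfg.truths:
        _fill_truths(cfg)
    return cfg


def _ci_ratio(ca: float, t_leaf: float, config: TruthConfig) -> float:
    nodes_ca = [n[0] for n in CI_RATIO_NODES]
    nodes_r = [n[1] for n in CI_RATIO_NODES]
    r = float(np.interp(ca, nodes_ca, nodes_r))
    r += config.ci_ratio_temp_slope * (t_leaf - 25.0)
    return float(np.clip(r, 0.2, 0.95))


def _rday(t_leaf: float, config: TruthConfig) -> float:
    return max(config.rday_25 + config.rday_slope * (t_leaf - 25.0), 0.0)


def _tree_params(truth: GroupSiteTruth, sp_eff, tree_eff) -> dict:
    """Apply multiplicative kopt and additive Topt effects to a group truth."""
    return {
        "vcmax_kopt": truth.vcmax_kopt * sp_eff["kopt"] * tree_eff["kopt"],
        "vcmax_topt": truth.vcmax_topt + sp_eff["topt"] + tree_eff["topt"],
        "vcmax_ea": truth.vcmax_ea,
        "jmax_kopt": truth.jmax_kopt * sp_eff["kopt"] * tree_eff["kopt"],
        "jmax_topt": truth.jmax_topt + sp_eff["topt"] + tree_eff["topt"],
        "jmax_ea": truth.jmax_ea,
    }


def _capacities_at(tree: dict, t_leaf: float) -> tuple:
    vfit = PeakedArrheniusFit(tree["vcmax_kopt"], tree["vcmax_topt"], tree["vcmax_ea"])
    jfit = PeakedArrheniusFit(tree["jmax_kopt"], tree["jmax_topt"], tree["jmax_ea"])
    return float(peaked_rate(vfit, t_leaf)), float(peaked_rate(jfit, t_leaf))


def _true_a_net(tree: dict, t_leaf: float, ci, config: TruthConfig):
    vcmax, jmax = _capacities_at(tree, t_leaf)
    params = FvCBParams(vcmax=vcmax, jmax=jmax, rday=_rday(t_leaf, config), t_leaf=t_leaf)
    return fvcb_assimilation(params, ci, config.kinetics)["a_net"]


def simulate_campaign(config: TruthConfig | None = None) -> SimulatedDataset:
    """Simulate the full campaign: gas exchange, growth and truth tables."""
    config = config or default_truth_config()
    if not config.truths:
        _fill_truths(config)
    if config.trees_per_species_site < 1 or not any(config.species_per_group.values()):
        raise ValueError("design must contain at least one tree")
    rng = np.random.default_rng(config.seed)

    gas_rows = []
    truth_rows = []
    for group in sorted(config.species_per_group):
        n_sp = config.species_per_group[group]
        for i_sp in range(n_sp):
            species = f"{group}_sp{i_sp + 1:02d}"
            sp_eff = {
                "kopt": float(np.exp(rng.normal(0.0, config.species_kopt_cv))),
                "topt": float(rng.normal(0.0, config.species_topt_sd)),
            }
            for site in config.group_sites[group]:
                truth = config.truths[(group, site)]
                t_growth = DEFAULT_SITE_CLIMATES[site].t_growth_daytime
                for i_tree in range(config.trees_per_species_site):
                    tree_id = f"{species}_s{site}_t{i_tree + 1}"
                    tree_eff = {
                        "kopt": float(np.exp(rng.normal(0.0, config.tree_kopt_cv))),
                        "topt": float(rng.normal(0.0, config.tree_topt_sd)),
                    }
                    tree = _tree_params(truth, sp_eff, tree_eff)
                    ci_g = _ci_ratio(410.0, t_growth, config) * 410.0
                    a_growth_true = float(_true_a_net(tree, t_growth, ci_g, config))
                    truth_rows.append(
                        {
                            "tree_id": tree_id, "species": species, "group": group,
                            "site": site, **tree,
                            "rday_25": config.rday_25, "rday_slope": config.rday_slope,
                            "a_growth_true": a_growth_true, "n_area": config.n_area,
                        }
                    )
                    for t_leaf in config.site_temperatures[site]:
                        ca_arr = np.asarray(config.co2_sequence, dtype=float)
                        ci_arr = np.array([_ci_ratio(ca, t_leaf, config) * ca for ca in ca_arr])
                        a_true = _true_a_net(tree, t_leaf, ci_arr, config)
                        noise = rng.normal(0.0, config.noise_sd_a, size=ca_arr.size) if config.noise_sd_a > 0 else 0.0
                        a_obs = a_true + noise
                        # Fick's law for CO2 diffusion: gs = 1.6 A / (Ca - Ci), mol m-2 s-1
                        gs_arr = 1.6 * np.maximum(a_true, 0.05) / np.maximum(ca_arr - ci_arr, 1.0)
                        seen_410 = False
                        for seq, ca in enumerate(ca_arr):
                            is_410 = abs(ca - 410.0) < 1.0
                            gas_rows.append(
                                {
                                    "tree_id": tree_id, "species": species, "group": group,
                                    "site": site, "t_leaf_setpoint": t_leaf,
                                    "seq": seq, "co2_setpoint": float(ca), "A": float(a_obs[seq]),
                                    "Ci": float(ci_arr[seq]), "Ca": float(ca), "gs": float(gs_arr[seq]),
                                    "Q": 1800.0, "t_leaf": t_leaf,
                                    "return_410": bool(is_410 and seen_410),
                                }
                            )
                            if is_410:
                                seen_410 = True

    gas = pd.DataFrame(gas_rows)
    truth = pd.DataFrame(truth_rows)
    growth = simulate_growth(config, truth, rng)
    return SimulatedDataset(gas_exchange=gas, growth=growth, truth=truth, config=config)


def simulate_growth(config: TruthConfig, truth: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Quarterly 3-year diameter censuses with RGR coupled to Agrowth.

    rgr = alpha + beta * a_growth + eps, with eps drawn at the species x
    site level (so the species-mean regression carries the intended
    signal-to-noise) plus a small tree-level jitter.  When
    ``rgr_noise_sd`` is unset, the species-level sd is chosen so that the
    share of variance in RGR explained by Agrowth is ``rgr_target_r2``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if "a_growth_true" not in truth.columns:
        raise ValueError("truth table must carry a_growth_true")

    cell_means = truth.groupby(["species", "site"])["a_growth_true"].mean()
    spread = float(cell_means.std(ddof=1)) if len(cell_means) > 1 else 0.0
    if config.rgr_noise_sd is not None:
        sd_eps = config.rgr_noise_sd
    elif config.rgr_beta == 0 or config.rgr_target_r2 >= 1 or spread == 0:
        sd_eps = 0.01
    else:
        r2 = config.rgr_target_r2
        sd_eps = abs(config.rgr_beta) * spread * np.sqrt((1.0 - r2) / r2)

    eps_cell = {cell: float(rng.normal(0.0, sd_eps)) for cell in cell_means.index}
    rows = []
    start = date(2019, 2, 1)
    for _, tr in truth.iterrows():
        eps = eps_cell[(tr["species"], tr["site"])] + float(rng.normal(0.0, 0.1 * sd_eps + 1e-9))
        rgr = config.rgr_alpha + config.rgr_beta * tr["a_growth_true"] + eps
        d0 = float(np.exp(rng.normal(np.log(25.0), 0.15)))  # mm
        if d0 <= 0:
            raise ValueError("non-positive initial diameter")
        for q in range(13):  # quarterly over 3 years
            t_years = q * 0.25
            d = d0 * np.exp(rgr * t_years)
            rows.append(
                {
                    "tree_id": tr["tree_id"],
                    "date": (start + timedelta(days=round(t_years * 365.25))).isoformat(),
                    "diameter_mm": d,
                    "rgr_true": rgr,
                }
            )
    return pd.DataFrame(rows)


def true_topt_oracle(config: TruthConfig, group: str, site: str, ca: float = 410.0) -> float:
    """Noiseless thermal optimum of net A at ambient CO2, on a 0.01 degC grid.

    Uses the group x site truth with species and tree effects at zero, so it
    is invariant to the noise settings by construction.
    """
    truth = config.truths[(group, site)]
    tree = _tree_params(truth, {"kopt": 1.0, "topt": 0.0}, {"kopt": 1.0, "topt": 0.0})
    t_lo, t_hi = min(config.site_temperatures[site]), max(config.site_temperatures[site])
    grid = np.arange(t_lo, t_hi + 0.005, 0.01)
    a = np.array([float(_true_a_net(tree, float(t), _ci_ratio(ca, float(t), config) * ca, config)) for t in grid])
    return float(grid[int(np.argmax(a))])
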