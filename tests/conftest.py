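import numpy as np
import pytest

from thermacclim import (
    ACiCurve,
    FvCBParams,
    LeafObservation,
    default_truth_config,
    fvcb_assimilation,
    simulate_campaign,
)
from thermacclim.simulate import CI_RATIO_NODES, CO2_SEQUENCE


def ci_from_ca(ca: float, ratio_410: float = 0.70) -> float:
    nodes_ca = [n[0] for n in CI_RATIO_NODES]
    nodes_r = [n[1] for n in CI_RATIO_NODES]
    return float(np.interp(ca, nodes_ca, nodes_r)) * ca


def make_curve(vcmax, jmax, rday, t_leaf, noise_sd=0.0, rng=None, ca_seq=CO2_SEQUENCE):
    """A-Ci curve generated directly from the FvCB forward model."""
    params = FvCBParams(vcmax=vcmax, jmax=jmax, rday=rday, t_leaf=t_leaf)
    obs = []
    seen_410 = False
    for ca in ca_seq:
        ci = ci_from_ca(ca)
        a = fvcb_assimilation(params, ci)["a_net"]
        if noise_sd > 0:
            a += rng.normal(0.0, noise_sd)
        is_410 = abs(ca - 410.0) < 1.0
        obs.append(
            LeafObservation(
                a_net=float(a), ci=ci, ca_setpoint=ca,
                gs=1.6 * max(a, 0.05) / max(ca - ci, 1.0),
                t_leaf=t_leaf, return_410=bool(is_410 and seen_410),
            )
        )
        if is_410:
            seen_410 = True
    return ACiCurve(
        tree_id="T1", species="sp", provenance_group="montane14", site="14",
        t_leaf_setpoint=t_leaf, observations=obs,
    )


@pytest.fixture(scope="session")
def tiny_campaign():
    """One montane species, one tree per site, noiseless."""
    cfg = default_truth_config(
        seed=11, noise_sd_a=0.0,
        species_per_group={"montane14": 1, "lowland22": 0, "lowland26": 0},
        trees_per_species_site=1,
        species_kopt_cv=0.0, species_topt_sd=0.0, tree_kopt_cv=0.0, tree_topt_sd=0.0,
    )
    return simulate_campaign(cfg)


@pytest.fixture(scope="session")
def small_noisy_campaign():
    """Two montane + one lowland species, default noise, 2 trees each."""
    cfg = default_truth_config(
        seed=7,
        species_per_group={"montane14": 2, "lowland22": 1, "lowland26": 1},
        trees_per_species_site=2,
    )
    return simulate_campaign(cfg)
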