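"""Farquhar–von Caemmerer–Berry (FvCB) C3 photosynthesis model.

Net assimilation is the minimum of the Rubisco-limited rate

    Ac = Vcmax * (Ci - Gamma*) / (Ci + Kc * (1 + O/Ko)) - Rday

and the RuBP-regeneration-limited rate

    Aj = (Jmax / 4) * (Ci - Gamma*) / (Ci + 2 * Gamma*) - Rday

with kinetic constants (Gamma*, Kc, Ko) scaled from 25 degC to the leaf
temperature by exponential Arrhenius functions.  Parameters are "apparent"
(Ci-based): mesophyll conductance is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np

__all__ = [
    "KineticConstants",
    "FvCBParams",
    "BERNACCHI_2001",
    "kinetics_at_temperature",
    "fvcb_assimilation",
]

R_GAS = 8.314  # J mol-1 K-1
T_REF_K = 298.15  # 25 degC reference for kinetic constants


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetic constants at 25 degC with Arrhenius activation energies.

    Units: gamma_star_25 and kc_25 in umol mol-1, ko_25 and o2 in mmol mol-1,
    activation energies in J mol-1.
    """

    gamma_star_25: float = 42.75
    kc_25: float = 404.9
    ko_25: float = 278.4
    ea_gamma: float = 37830.0
    ea_kc: float = 79430.0
    ea_ko: float = 36380.0
    o2: float = 210.0
    r_gas: float = R_GAS

    def __post_init__(self) -> None:
        for name in ("gamma_star_25", "kc_25", "ko_25", "o2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kwargs) -> "KineticConstants":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticConstants":
        return cls(**d)


#: In-vivo Rubisco kinetics of Bernacchi et al. (2001), the de-facto standard
#: parameter set behind Ci-based ("apparent") A-Ci curve fitting.
BERNACCHI_2001 = KineticConstants()


@dataclass(frozen=True)
class FvCBParams:
    """Apparent FvCB parameters at one measurement leaf temperature.

    vcmax, jmax, rday in umol m-2 s-1; t_leaf in degC.
    """

    vcmax: float
    jmax: float
    rday: float
    t_leaf: float

    def __post_init__(self) -> None:
        if not self.vcmax > 0:
            raise ValueError("vcmax must be positive")
        if not self.jmax > 0:
            raise ValueError("jmax must be positive")
        if self.rday < 0:
            raise ValueError("rday must be non-negative")


def _arrhenius_scale(t_leaf, ea: float) -> np.ndarray:
    tk = np.asarray(t_leaf, dtype=float) + 273.15
    return np.exp(ea * (tk - T_REF_K) / (T_REF_K * R_GAS * tk))


def kinetics_at_temperature(t_leaf, constants: KineticConstants = BERNACCHI_2001) -> dict:
    """Kinetic constants at a leaf temperature (degC).

    Each constant k(T) = k25 * exp[Ea (Tk - 298.15) / (298.15 R Tk)].
    Returns gamma_star, kc, ko and the effective Michaelis constant
    km_effective = kc * (1 + O/ko), all in umol mol-1 terms (ko stays in
    mmol mol-1, matching o2).

    Scalars or arrays of temperatures are accepted.
    """
    t = np.asarray(t_leaf, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("leaf temperature must be finite")
    if np.any(t < -10) or np.any(t > 50):
        raise ValueError("leaf temperature outside supported range [-10, 50] degC")
    gamma_star = constants.gamma_star_25 * _arrhenius_scale(t, constants.ea_gamma)
    kc = constants.kc_25 * _arrhenius_scale(t, constants.ea_kc)
    ko = constants.ko_25 * _arrhenius_scale(t, constants.ea_ko)
    km = kc * (1.0 + constants.o2 / ko)
    if np.isscalar(t_leaf) or np.ndim(t_leaf) == 0:
        return {
            "gamma_star": float(gamma_star),
            "kc": float(kc),
            "ko": float(ko),
            "km_effective": float(km),
        }
    return {"gamma_star": gamma_star, "kc": kc, "ko": ko, "km_effective": km}


def fvcb_assimilation(
    params: FvCBParams,
    ci,
    constants: KineticConstants = BERNACCHI_2001,
    subtract_rday: bool = True,
) -> dict:
    """Evaluate the FvCB model at intercellular CO2 ci (umol mol-1).

    Returns ac, aj, a_net (= min(ac, aj)) and the limiting branch label
    ("rubisco" or "rubp", ties going to "rubisco").  With
    ``subtract_rday=False`` the gross rates are returned (Rday term dropped
    from both branches).
    """
    ci_arr = np.asarray(ci, dtype=float)
    if np.any(ci_arr < 0):
        raise ValueError("ci must be non-negative")
    kin = kinetics_at_temperature(params.t_leaf, constants)
    gamma_star = kin["gamma_star"]
    km = kin["km_effective"]
    rday = params.rday if subtract_rday else 0.0
    ac = params.vcmax * (ci_arr - gamma_star) / (ci_arr + km) - rday
    aj = (params.jmax / 4.0) * (ci_arr - gamma_star) / (ci_arr + 2.0 * gamma_star) - rday
    a_net = np.minimum(ac, aj)
    limitation = np.where(ac <= aj, "rubisco", "rubp")
    if np.isscalar(ci) or np.ndim(ci) == 0:
        return {
            "ac": float(ac),
            "aj": float(aj),
            "a_net": float(a_net),
            "limitation": str(limitation),
        }
    return {"ac": ac, "aj": aj, "a_net": a_net, "limitation": limitation}
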