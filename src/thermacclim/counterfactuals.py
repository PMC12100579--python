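"""Counterfactual thermal optima: stomatal and respiratory controls.

Two recomputations isolate what shapes the observed thermal optimum of net
photosynthesis (ToptA):

* common intercellular CO2 — net photosynthesis is re-evaluated at every
  measurement temperature from that temperature's fitted FvCB parameters at
  a fixed Ci (default 0.7 x 410 = 287 umol mol-1, a Ci/Ca ratio of 0.7),
  removing any temperature dependence of stomatal CO2 supply; the parabola
  fit of the result gives Topt287;

* gross photosynthesis — the Rday term is not subtracted, removing the
  respiratory drag on the optimum; the parabola fit gives ToptGross.

Observed and counterfactual optima are compared with Welch unpaired
t-tests.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .aci import ACiFitResult
from .fvcb import BERNACCHI_2001, KineticConstants, fvcb_assimilation
from .thermal import ParabolaFit, fit_parabola

__all__ = [
    "DEFAULT_CI_RATIO",
    "DEFAULT_CA",
    "DEFAULT_CI_COMMON",
    "common_ci_response",
    "gross_response",
    "topt_counterfactual",
    "compare_topt",
]

DEFAULT_CI_RATIO = 0.7
DEFAULT_CA = 410.0
DEFAULT_CI_COMMON = DEFAULT_CI_RATIO * DEFAULT_CA  # = 287 umol mol-1


def _check_fits(fits) -> list:
    good = [f for f in fits if f.converged and f.params is not None]
    if len(good) < 3:
        raise ValueError("need at least 3 converged per-temperature fits")
    return good


def common_ci_response(
    fits,
    ci_common: float = DEFAULT_CI_COMMON,
    constants: KineticConstants = BERNACCHI_2001,
) -> list:
    """Net photosynthesis at a common Ci for each measurement temperature.

    Each temperature's own fitted FvCB parameters are used — no Arrhenius
    interpolation between temperatures.  Returns (t_leaf, a_net) pairs.
    """
    good = _check_fits(fits)
    out = []
    for f in good:
        a = fvcb_assimilation(f.params, ci_common, constants, subtract_rday=True)
        out.append((f.params.t_leaf, a["a_net"]))
    return sorted(out)


def gross_response(
    fits,
    ci_mode: str = "observed_410",
    ci_common: float = DEFAULT_CI_COMMON,
    constants: KineticConstants = BERNACCHI_2001,
) -> list:
    """Gross photosynthesis (Rday not subtracted) per measurement temperature.

    ``ci_mode`` chooses the evaluation Ci: ``observed_410`` uses each
    curve's observed Ci at its first 410 umol mol-1 setpoint; ``common``
    uses ``ci_common`` everywhere.
    """
    if ci_mode not in ("observed_410", "common"):
        raise ValueError("ci_mode must be 'observed_410' or 'common'")
    good = _check_fits(fits)
    out = []
    for f in good:
        if ci_mode == "common":
            ci = ci_common
        else:
            ci = _observed_ci_410(f)
        a = fvcb_assimilation(f.params, ci, constants, subtract_rday=False)
        out.append((f.params.t_leaf, a["a_net"]))
    return sorted(out)


def _observed_ci_410(fit: ACiFitResult) -> float:
    if fit.curve is None:
        raise ValueError("fit carries no curve; cannot locate the 410 setpoint")
    for obs in fit.curve.observations:
        if abs(obs.ca_setpoint - DEFAULT_CA) < 1.0 and not obs.return_410:
            return obs.ci
    raise ValueError("curve has no 410 umol mol-1 setpoint")


def topt_counterfactual(pairs) -> ParabolaFit:
    """Parabola fit of a counterfactual (t, A) response (Topt287/ToptGross)."""
    return fit_parabola(pairs)


def compare_topt(group_a, group_b) -> dict:
    """Welch unpaired t-test between two sets of thermal optima."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: no within-group variance
        if np.mean(a) == np.mean(b):
            return {"t_stat": 0.0, "df": float(a.size + b.size - 2), "p_two_sided": 1.0}
        return {"t_stat": float("inf"), "df": float(a.size + b.size - 2), "p_two_sided": 0.0}
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t_stat": float(res.statistic), "df": float(res.df), "p_two_sided": float(res.pvalue)}
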