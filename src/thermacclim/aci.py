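"""Bilinear fitting of apparent Vcmax, Jmax and Rday to a single A-Ci curve.

The FvCB branches are linear in their parameters once the kinetic constants
are fixed: the Rubisco-limited branch is a straight line in
x_c = (Ci - Gamma*)/(Ci + Km) with slope Vcmax and intercept -Rday, and the
RuBP-regeneration branch is a line through the origin in
x_j = (Ci - Gamma*)/(Ci + 2 Gamma*) with slope Jmax/4 (after adding Rday
back to A).  The bilinear method assigns the low-Ci points to the Rubisco
regime and the high-Ci points to the RuBP regime, tries every admissible
split of the Ci-sorted observations, and keeps the partition with the
smallest total squared error.  Parameters are reported at the measurement
temperature — no normalisation to 25 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fvcb import BERNACCHI_2001, FvCBParams, KineticConstants, fvcb_assimilation, kinetics_at_temperature

__all__ = [
    "LeafObservation",
    "ACiCurve",
    "ACiFitResult",
    "QCRules",
    "validate_curve",
    "fit_aci_bilinear",
    "predict_aci",
]

MIN_POINTS_PER_REGIME = 3


@dataclass(frozen=True)
class LeafObservation:
    """One gas-exchange record within an A-Ci curve."""

    a_net: float  # umol m-2 s-1
    ci: float  # umol mol-1
    ca_setpoint: float  # umol mol-1
    gs: float  # mol m-2 s-1
    t_leaf: float  # degC
    ppfd: float = 1800.0  # umol photons m-2 s-1
    return_410: bool = False  # second pass through the 410 setpoint


@dataclass
class ACiCurve:
    """All observations for one tree at one leaf-temperature setpoint."""

    tree_id: str
    species: str
    provenance_group: str  # montane14 | lowland22 | lowland26
    site: str
    t_leaf_setpoint: float
    observations: list = field(default_factory=list)

    @property
    def ci(self) -> np.ndarray:
        return np.array([o.ci for o in self.observations], dtype=float)

    @property
    def a_net(self) -> np.ndarray:
        return np.array([o.a_net for o in self.observations], dtype=float)

    @property
    def gs(self) -> np.ndarray:
        return np.array([o.gs for o in self.observations], dtype=float)

    @property
    def t_leaf(self) -> float:
        return float(np.mean([o.t_leaf for o in self.observations]))


@dataclass
class ACiFitResult:
    """Bilinear fit of one A-Ci curve."""

    params: FvCBParams | None
    ci_transition: float
    sse: float
    n_rubisco: int
    n_rubp: int
    converged: bool
    qc_flags: list = field(default_factory=list)
    curve: ACiCurve | None = None


@dataclass(frozen=True)
class QCRules:
    """Deterministic pass/fail rules applied before fitting."""

    min_points: int = 2 * MIN_POINTS_PER_REGIME
    min_a_range: float = 1.0  # umol m-2 s-1; below this the response is flat
    min_distinct_ci: int = 4


def validate_curve(curve: ACiCurve, rules: QCRules = QCRules()) -> dict:
    """Check a curve against the QC rules; returns {'pass', 'reasons'}."""
    reasons = []
    n = len(curve.observations)
    if n < rules.min_points:
        reasons.append("min_points")
    if n:
        if np.all(curve.gs <= 0):
            reasons.append("nonpositive_gs")
        a = curve.a_net
        if a.max() - a.min() < rules.min_a_range:
            reasons.append("degenerate_response")
        if np.unique(curve.ci).size < rules.min_distinct_ci:
            reasons.append("duplicate_ci_collapse")
    return {"pass": not reasons, "reasons": reasons}


def fit_aci_bilinear(
    curve: ACiCurve,
    constants: KineticConstants = BERNACCHI_2001,
    min_points_per_regime: int = MIN_POINTS_PER_REGIME,
) -> ACiFitResult:
    """Fit apparent Vcmax, Jmax, Rday by the bilinear two-regime method.

    Every split of the Ci-sorted observations that leaves at least
    ``min_points_per_regime`` points in each regime (and does not split tied
    Ci values) is evaluated; the partition minimising the summed squared
    error of the two regressions wins.  Negative Rday estimates are clamped
    to zero (flag ``rday_clamped``); partitions with non-positive Vcmax or
    Jmax are inadmissible.  If no admissible partition exists the result is
    non-converged with flag ``no_valid_partition``.
    """
    t_leaf = curve.t_leaf
    kin = kinetics_at_temperature(t_leaf, constants)
    gamma_star, km = kin["gamma_star"], kin["km_effective"]

    order = np.argsort(curve.ci, kind="stable")
    ci = curve.ci[order]
    a = curve.a_net[order]
    n = ci.size

    x_c = (ci - gamma_star) / (ci + km)
    x_j = (ci - gamma_star) / (ci + 2.0 * gamma_star)

    best = None
    for k in range(min_points_per_regime, n - min_points_per_regime + 1):
        # split between sorted index k-1 and k; never inside a tie
        if ci[k - 1] >= ci[k]:
            continue
        xc, ac_obs = x_c[:k], a[:k]
        # Rubisco regime: a = vcmax * x_c - rday
        A = np.column_stack([xc, np.ones(k)])
        coef, *_ = np.linalg.lstsq(A, ac_obs, rcond=None)
        vcmax, intercept = float(coef[0]), float(coef[1])
        rday = -intercept
        flags = []
        if rday < 0:
            rday = 0.0
            flags.append("rday_clamped")
        if vcmax <= 0:
            continue
        # RuBP regime: (a + rday) = (jmax/4) * x_j, through the origin
        xj, aj_obs = x_j[k:], a[k:] + rday
        denom = float(xj @ xj)
        if denom <= 0:
            continue
        jmax4 = float(xj @ aj_obs) / denom
        jmax = 4.0 * jmax4
        if jmax <= 0:
            continue
        pred_c = vcmax * xc - rday
        pred_j = jmax4 * xj - rday
        sse = float(np.sum((ac_obs - pred_c) ** 2) + np.sum((a[k:] - pred_j) ** 2))
        if best is None or sse < best["sse"]:
            best = {
                "sse": sse,
                "vcmax": vcmax,
                "jmax": jmax,
                "rday": rday,
                "k": k,
                "flags": flags,
            }

    if best is None:
        return ACiFitResult(
            params=None,
            ci_transition=float("nan"),
            sse=float("nan"),
            n_rubisco=0,
            n_rubp=0,
            converged=False,
            qc_flags=["no_valid_partition"],
            curve=curve,
        )

    k = best["k"]
    flags = list(best["flags"])
    if k == min_points_per_regime or k == n - min_points_per_regime:
        flags.append("boundary_transition")
    return ACiFitResult(
        params=FvCBParams(vcmax=best["vcmax"], jmax=best["jmax"], rday=best["rday"], t_leaf=t_leaf),
        ci_transition=float(0.5 * (ci[k - 1] + ci[k])),
        sse=best["sse"],
        n_rubisco=k,
        n_rubp=n - k,
        converged=True,
        qc_flags=flags,
        curve=curve,
    )


def predict_aci(fit: ACiFitResult, ci_values, constants: KineticConstants = BERNACCHI_2001) -> np.ndarray:
    """Forward FvCB prediction of net assimilation at the fit's leaf temperature."""
    if not fit.converged or fit.params is None:
        raise ValueError("cannot predict from a non-converged fit")
    out = fvcb_assimilation(fit.params, np.asarray(ci_values, dtype=float), constants)
    return out["a_net"]
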