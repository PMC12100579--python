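"""Temperature responses of photosynthetic capacity and net photosynthesis.

Two response models:

* A peaked (modified) Arrhenius function in its optimum parameterisation
  (Medlyn et al. 2002) for apparent Vcmax and Jmax:

      f(Tk) = kopt * Hd * exp[Ea (Tk - ToptK) / (Tk R ToptK)]
              / (Hd - Ea * (1 - exp[Hd (Tk - ToptK) / (Tk R ToptK)]))

  with the deactivation energy Hd fixed (default 200 kJ mol-1) to avoid
  over-parameterisation.

* A parabola for net photosynthesis at ambient CO2 versus leaf temperature:

      A(T) = Aopt - b * (T - ToptA)^2

  whose vertex gives the thermal optimum ToptA and peak rate Aopt; b is the
  curvature (larger b = narrower thermal breadth).  Rearranging for A = 0
  gives the high-temperature compensation point Tmax = sqrt(Aopt/b) + ToptA.

Evaluating either fit at a site's mean daytime growth temperature yields the
rate "at growth temperature" (Agrowth for the parabola).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PeakedArrheniusFit",
    "ParabolaFit",
    "SiteClimate",
    "DEFAULT_SITE_CLIMATES",
    "peaked_rate",
    "fit_peaked_arrhenius",
    "fit_parabola",
    "parabola_value",
    "tmax_from_parabola",
    "value_at_growth_temperature",
    "per_degree_shift",
]

R_GAS = 8.314  # J mol-1 K-1
DEFAULT_HD_KJ = 200.0


@dataclass
class PeakedArrheniusFit:
    k_opt: float  # rate at the optimum, umol m-2 s-1
    t_opt: float  # degC
    e_a: float  # activation energy, kJ mol-1
    h_d: float = DEFAULT_HD_KJ  # deactivation energy, kJ mol-1 (fixed)
    rss: float = float("nan")
    converged: bool = True
    n_points: int = 0
    qc_flags: list = field(default_factory=list)


@dataclass
class ParabolaFit:
    a_opt: float  # umol m-2 s-1
    t_opt_a: float  # degC
    b: float  # umol m-2 s-1 degC-2
    rss: float = float("nan")
    n_points: int = 0
    curvature_ok: bool = True


@dataclass(frozen=True)
class SiteClimate:
    site_label: str
    mat: float  # mean annual temperature, degC
    t_growth_daytime: float  # mean daytime growth temperature, degC


#: Site climates of the three common gardens: mean annual temperature labels
#: the site; the mean daytime growth temperature of the month preceding the
#: campaign is where rates "at growth temperature" are evaluated.
DEFAULT_SITE_CLIMATES = {
    "14": SiteClimate("14", 14.0, 21.4),
    "22": SiteClimate("22", 22.0, 24.3),
    "26": SiteClimate("26", 26.0, 31.2),
}


def peaked_rate(fit: PeakedArrheniusFit, t) -> np.ndarray | float:
    """Peaked-Arrhenius rate at leaf temperature t (degC)."""
    ea = fit.e_a * 1e3  # kJ -> J
    hd = fit.h_d * 1e3
    if ea <= 0 or ea >= hd:
        raise ValueError("require 0 < e_a < h_d")
    tk = np.asarray(t, dtype=float) + 273.15
    to = fit.t_opt + 273.15
    arg = (tk - to) / (tk * R_GAS * to)
    num = hd * np.exp(ea * arg)
    den = hd - ea * (1.0 - np.exp(hd * arg))
    if np.any(den <= 0):
        raise ValueError("pathological parameters: denominator non-positive")
    out = fit.k_opt * num / den
    return float(out) if np.ndim(t) == 0 else out


def _peaked_model(theta, tk, hd):
    kopt, to_c, ea = theta
    to = to_c + 273.15
    arg = (tk - to) / (tk * R_GAS * to)
    den = hd - ea * (1.0 - np.exp(hd * arg))
    return kopt * hd * np.exp(ea * arg) / den


def fit_peaked_arrhenius(points, h_d: float = DEFAULT_HD_KJ) -> PeakedArrheniusFit:
    """Nonlinear least-squares fit of (kopt, Topt, Ea) with Hd fixed.

    ``points`` is a sequence of (temperature degC, rate) pairs; at least 4
    points spanning at least 10 degC are required.  A deterministic
    multi-start grid (Topt in {20,25,30,35,40} degC, Ea in {30,60,90}
    kJ mol-1, kopt at the maximum observed rate) makes the fit seed-free;
    the start reaching the lowest residual sum of squares wins, ties going
    to the lowest Ea.  Data still rising at the warmest measured
    temperature converge with the optimum at/above max(T) and are flagged
    ``topt_extrapolated``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (t, rate) pairs")
    t, rate = pts[:, 0], pts[:, 1]
    if t.size < 4:
        raise ValueError("need at least 4 points")
    if t.max() - t.min() < 10:
        raise ValueError("temperature span must be at least 10 degC")
    tk = t + 273.15
    hd_j = h_d * 1e3

    # kopt enters linearly: profile it out and search over (topt, ea) only
    def shape(topt_c, ea_kj):
        return _peaked_model((1.0, topt_c, ea_kj * 1e3), tk, hd_j)

    def profiled_kopt(topt_c, ea_kj):
        m = shape(topt_c, ea_kj)
        denom = float(m @ m)
        return float(m @ rate) / denom if denom > 0 else 0.0

    def resid(theta):
        m = shape(theta[0], theta[1])
        return profiled_kopt(theta[0], theta[1]) * m - rate

    starts = [(t0, ea0) for t0 in (20.0, 25.0, 30.0, 35.0, 40.0) for ea0 in (30.0, 60.0, 90.0)]
    starts.sort(key=lambda s: (float(np.sum(resid(s) ** 2)), s[1]))
    best = None
    for t0, ea0 in starts[:4]:
        try:
            sol = least_squares(
                resid,
                x0=[t0, ea0],
                bounds=([0.0, 1e-3], [60.0, h_d - 1e-3]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if (
            best is None
            or rss < best["rss"] * (1 - 1e-10)
            or (abs(rss - best["rss"]) <= 1e-10 * max(best["rss"], 1e-30) and sol.x[1] < best["x"][1])
        ):
            best = {"rss": rss, "x": sol.x, "ok": bool(sol.success)}

    if best is None:
        return PeakedArrheniusFit(
            k_opt=float("nan"), t_opt=float("nan"), e_a=float("nan"), h_d=h_d,
            converged=False, n_points=t.size, qc_flags=["fit_failed"],
        )

    topt, ea = (float(v) for v in best["x"])
    kopt = profiled_kopt(topt, ea)
    flags = []
    if topt >= t.max() - 1e-9:
        flags.append("topt_extrapolated")
    return PeakedArrheniusFit(
        k_opt=kopt, t_opt=topt, e_a=ea, h_d=h_d,
        rss=best["rss"], converged=best["ok"], n_points=t.size, qc_flags=flags,
    )


def fit_parabola(points) -> ParabolaFit:
    """Closed-form quadratic least squares of A versus leaf temperature.

    Solves A = c0 + c1 T + c2 T^2 exactly, then reparameterises to the
    vertex form: ToptA = -c1/(2 c2), b = -c2, Aopt = c0 - c1^2/(4 c2).
    If the fitted curvature opens upward (c2 >= 0) the vertex is a minimum;
    ``curvature_ok`` is False and downstream Tmax/Agrowth should be
    suppressed for that unit.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (t, a_net) pairs")
    t, a = pts[:, 0], pts[:, 1]
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct temperatures")
    c2, c1, c0 = np.polyfit(t, a, 2)
    resid = a - (c0 + c1 * t + c2 * t * t)
    rss = float(resid @ resid)
    if c2 >= 0:
        return ParabolaFit(
            a_opt=float("nan"), t_opt_a=float("nan"), b=float(-c2),
            rss=rss, n_points=t.size, curvature_ok=False,
        )
    t_opt = -c1 / (2.0 * c2)
    return ParabolaFit(
        a_opt=float(c0 - c1 * c1 / (4.0 * c2)),
        t_opt_a=float(t_opt),
        b=float(-c2),
        rss=rss,
        n_points=t.size,
        curvature_ok=True,
    )


def parabola_value(fit: ParabolaFit, t) -> np.ndarray | float:
    """Evaluate A(T) = Aopt - b (T - ToptA)^2."""
    if not fit.curvature_ok:
        raise ValueError("parabola has no interior maximum")
    t_arr = np.asarray(t, dtype=float)
    out = fit.a_opt - fit.b * (t_arr - fit.t_opt_a) ** 2
    return float(out) if np.ndim(t) == 0 else out


def tmax_from_parabola(fit: ParabolaFit) -> float:
    """High-temperature CO2 compensation point: Tmax = sqrt(Aopt/b) + ToptA."""
    if not fit.curvature_ok:
        raise ValueError("parabola has no interior maximum")
    if fit.a_opt <= 0 or fit.b <= 0:
        raise ValueError("Tmax undefined for a_opt <= 0 or b <= 0")
    return float(np.sqrt(fit.a_opt / fit.b) + fit.t_opt_a)


def value_at_growth_temperature(fit, climate: SiteClimate) -> float:
    """Rate at the site's mean daytime growth temperature (Agrowth etc.)."""
    tg = climate.t_growth_daytime
    if isinstance(fit, ParabolaFit):
        return float(parabola_value(fit, tg))
    if isinstance(fit, PeakedArrheniusFit):
        return float(peaked_rate(fit, tg))
    raise TypeError(f"unsupported fit type {type(fit)!r}")


def per_degree_shift(group_means: dict, climates: dict) -> float:
    """Acclimation slope: degC of Topt shift per degC of site warming.

    ``group_means`` maps exactly two site labels to mean Topt (degC);
    ``climates`` maps the same labels to SiteClimate.  The divisor is the
    difference in site mean annual temperature.
    """
    if len(group_means) != 2:
        raise ValueError("exactly two sites are compared")
    (s1, m1), (s2, m2) = sorted(group_means.items(), key=lambda kv: climates[kv[0]].mat)
    dmat = climates[s2].mat - climates[s1].mat
    if dmat == 0:
        raise ValueError("sites have equal mean annual temperature")
    return float((m2 - m1) / dmat)
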