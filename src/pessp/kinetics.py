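"""Quantitative enzyme characterization for nitrilase biochemistry.

Michaelis-Menten kinetics fitted by the double-reciprocal (Lineweaver-Burk)
linearization, specificity constants, specific activity, relative-activity
substrate profiles, enantiomeric excess, native-oligomer stoichiometry and
temperature/pH optimum profiles. Units follow biochemical convention: S and
Km in mM, rates and Vmax in umol min^-1 mg^-1, kcat in s^-1, kcat/Km in
M^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class FitError(ValueError):
    """Raised when a kinetic fit is undefined or fails."""


@dataclass(frozen=True)
class KineticPoint:
    """One initial-rate measurement: substrate concentration vs rate."""

    substrate_conc: float  # mM, > 0 for the reciprocal transform
    rate: float  # umol min^-1 mg^-1

    def __post_init__(self) -> None:
        if self.substrate_conc <= 0:
            raise ValueError("substrate_conc must be > 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


@dataclass
class KineticFit:
    """Km/Vmax from a fit, with optional turnover number and derived kcat/Km."""

    Km: float  # mM
    Vmax: float  # umol min^-1 mg^-1
    r_squared: float
    kcat: float | None = None  # s^-1, supplied independently
    kcat_over_Km: float | None = None  # M^-1 s^-1

    def __post_init__(self) -> None:
        if self.Km <= 0 or self.Vmax <= 0:
            raise FitError(f"non-positive constants: Km={self.Km}, Vmax={self.Vmax}")
        if not (0.0 <= self.r_squared <= 1.0):
            raise FitError(f"r_squared {self.r_squared} outside [0, 1]")
        if self.kcat is not None and self.kcat_over_Km is None:
            self.kcat_over_Km = specificity_constant(self.kcat, self.Km)


@dataclass(frozen=True)
class ActivityMeasurement:
    """Product formed (umol ammonia or acid) over time (min) per protein (mg)."""

    substrate: str
    product_amount: float
    time: float
    protein: float

    def __post_init__(self) -> None:
        if self.time <= 0 or self.protein <= 0:
            raise ValueError("time and protein must be > 0")
        if self.product_amount < 0:
            raise ValueError("product_amount must be >= 0")


def michaelis_menten_rate(S: float, Km: float, Vmax: float) -> float:
    """v = Vmax * S / (Km + S)."""
    if S < 0:
        raise ValueError("substrate concentration must be >= 0")
    if Km <= 0 or Vmax <= 0:
        raise ValueError("Km and Vmax must be > 0")
    return Vmax * S / (Km + S)


def lineweaver_burk_fit(
    points: list[KineticPoint],
    kcat: float | None = None,
    nonlinear_refit: bool = False,
) -> KineticFit | tuple[KineticFit, KineticFit]:
    """Estimate Km and Vmax by OLS on the double-reciprocal plot.

    1/v = (Km/Vmax) (1/S) + 1/Vmax, so Vmax = 1/intercept and
    Km = slope/intercept. Requires >= 3 points with strictly positive rates
    (the reciprocal is undefined at v = 0) and a positive intercept.

    With ``nonlinear_refit`` a direct nonlinear least-squares fit of the
    Michaelis-Menten curve is returned alongside as a cross-check.
    """
    if len(points) < 3:
        raise FitError("need at least 3 kinetic points")
    zero = [p for p in points if p.rate == 0]
    if zero:
        raise FitError(
            f"rate of 0 at S={[p.substrate_conc for p in zero]} mM: reciprocal undefined"
        )
    S = np.array([p.substrate_conc for p in points])
    v = np.array([p.rate for p in points])
    res = stats.linregress(1.0 / S, 1.0 / v)
    if res.intercept <= 0:
        raise FitError(f"non-positive intercept {res.intercept}: fit failed")
    Vmax = 1.0 / res.intercept
    Km = res.slope / res.intercept
    if Km <= 0:
        raise FitError(f"non-positive Km estimate {Km}")
    fit = KineticFit(Km=float(Km), Vmax=float(Vmax), r_squared=float(res.rvalue**2), kcat=kcat)
    if not nonlinear_refit:
        return fit
    popt, _ = optimize.curve_fit(
        lambda s, km, vmax: vmax * s / (km + s), S, v, p0=(Km, Vmax)
    )
    ss_res = float(np.sum((v - popt[1] * S / (popt[0] + S)) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    nl = KineticFit(Km=float(popt[0]), Vmax=float(popt[1]), r_squared=min(max(r2, 0.0), 1.0), kcat=kcat)
    return fit, nl


def specificity_constant(kcat: float, Km: float) -> float:
    """kcat/Km in M^-1 s^-1 from kcat (s^-1) and Km (mM)."""
    if kcat <= 0 or Km <= 0:
        raise ValueError("kcat and Km must be > 0")
    return kcat / (Km * 1e-3)


def round_sig(x: float, figures: int = 2) -> float:
    """Round to a number of significant figures (used for formatted reports)."""
    if x == 0:
        return 0.0
    return round(x, figures - 1 - int(math.floor(math.log10(abs(x)))))


def specific_activity(m: ActivityMeasurement) -> float:
    """U/mg: umol product per minute per mg protein."""
    return m.product_amount / (m.time * m.protein)


def relative_activity_profile(
    measurements: dict[str, float],
    reference_substrate: str,
    detection_floor: float = 0.005,
) -> dict[str, float | str]:
    """Activities as percent of a reference substrate (= 100).

    Activities below ``detection_floor`` (as a fraction of the reference
    activity) are reported as the string ``"N.D."`` — not detected.
    """
    if reference_substrate not in measurements:
        raise KeyError(f"reference substrate {reference_substrate!r} missing")
    ref = measurements[reference_substrate]
    if ref <= 0:
        raise ValueError("reference activity must be > 0")
    out: dict[str, float | str] = {}
    for name, activity in measurements.items():
        if activity < detection_floor * ref:
            out[name] = "N.D."
        else:
            out[name] = 100.0 * activity / ref
    out[reference_substrate] = 100.0
    return out


def enantiomeric_excess(cR: float, cS: float) -> tuple[float, str | None]:
    """ee% = 100 |[R]-[S]| / ([R]+[S]), with the excess enantiomer's label."""
    if cR < 0 or cS < 0:
        raise ValueError("concentrations must be >= 0")
    total = cR + cS
    if total == 0:
        raise ValueError("both concentrations are zero")
    ee = 100.0 * abs(cR - cS) / total
    label = "R" if cR > cS else "S" if cS > cR else None
    return ee, label


def oligomer_state(native_mw: float, subunit_mw: float) -> tuple[int, float]:
    """Subunit count of a native oligomer: nearest integer of the MW ratio."""
    if native_mw <= 0 or subunit_mw <= 0:
        raise ValueError("molecular weights must be > 0")
    if native_mw < subunit_mw:
        raise ValueError("native MW smaller than subunit MW")
    ratio = native_mw / subunit_mw
    return int(round(ratio)), ratio


def optimum_profile(
    readings: dict[float, float],
) -> tuple[dict[float, float], float]:
    """Normalize condition->activity readings to percent of maximum.

    Returns the normalized profile and the argmax condition (ties resolved
    to the smallest condition value).
    """
    if len(readings) < 2:
        raise ValueError("need at least two readings")
    vmax = max(readings.values())
    if vmax <= 0:
        raise ValueError("all readings are zero or negative")
    profile = {cond: 100.0 * act / vmax for cond, act in readings.items()}
    best = min(cond for cond, act in readings.items() if act == vmax)
    return profile, best
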