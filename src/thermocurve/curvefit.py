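"""Gibbs-Helmholtz stability curves fitted through three free-energy points.

With the melting temperature Tm as reference, a two-state transition with
temperature-independent heat capacity change dCp has the folding free
energy

    dG(T) = dHm (1 - T/Tm) + dCp (T - Tm - T ln(T/Tm))

(folding convention: dHm < 0, dCp < 0 and dG < 0 below Tm for a stable
protein).  This is linear in the basis {1, T, T ln T}:

    dG(T) = a + b T + c T ln T,
    a = dHm - dCp Tm,  b = -dHm/Tm + dCp (1 + ln Tm),  c = -dCp,

so fitting the curve through (temperature, dG) points is an ordinary least
squares problem, exact when exactly three distinct temperatures are given.
The limit dG(T -> 0+) equals the constant a, which is how the 0 K anchor is
imposed: as an equality constraint on a rather than as a data point at a
temperature outside the model's domain.

Because the three points come from dataset-averaged melting temperatures
rather than true physical temperatures, and because scores are in kT units
rather than kcal/mol, two per-protein corrections calibrated on homologous
family members are applied to the fitted curve:

* an amplitude factor k (ratio of experimental to fitted |dCp| summed over
  the family, with a trimmed-mean fallback across families), and
* a temperature factor omega aligning fitted zero crossings with
  experimental melting temperatures, giving dG_final(T) = k dG_fit(omega T).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "StabilityCurve",
    "CurveCorrections",
    "PredictionRecord",
    "gibbs_helmholtz",
    "fit_curve",
    "needs_anchor",
    "scale_factor_k",
    "omega_factor",
    "extract_thermo_params",
    "sample_curve",
    "CELSIUS_TO_KELVIN",
    "ROOM_TEMPERATURE_K",
]

CELSIUS_TO_KELVIN = 273.15
ROOM_TEMPERATURE_K = 298.15
#: zero crossings are searched on (0, T_SEARCH_MAX] Kelvin
T_SEARCH_MAX = 1000.0


@dataclass
class StabilityCurve:
    """A fitted stability curve in the linear basis {1, T, T ln T}.

    ``tm`` is the zero crossing (K) nearest the temperature range the curve
    was fitted on; ``dHm`` and ``dCp`` follow from the exact basis mapping.
    A curve with no zero crossing in (0, 1000] K carries ``no_melting`` and
    NaN thermodynamic parameters.
    """

    a: float
    b: float
    c: float
    t_range: tuple[float, float] | None = None
    tm: float = field(default=math.nan)
    no_melting: bool = field(default=False)

    def __post_init__(self) -> None:
        if math.isnan(self.tm) and not self.no_melting:
            roots = curve_roots(self.a, self.b, self.c)
            if not roots:
                self.no_melting = True
                return
            # the melting transition is the crossing above the stability
            # maximum; only without one fall back to the crossing nearest
            # the fitted temperature range
            ts = self.ts
            above = ([r for r in roots if r > ts]
                     if not math.isnan(ts) and self.c > 0 else [])
            if above:
                self.tm = _nearest_root(above, self.t_range)
            else:
                self.tm = _nearest_root(roots, self.t_range)

    @classmethod
    def from_params(cls, dHm: float, tm: float, dCp: float) -> "StabilityCurve":
        """Exact construction from the thermodynamic parameters."""
        if tm <= 0:
            raise ValueError("Tm must be positive (Kelvin)")
        a = dHm - dCp * tm
        b = -dHm / tm + dCp * (1.0 + math.log(tm))
        c = -dCp
        obj = cls.__new__(cls)
        obj.a, obj.b, obj.c = a, b, c
        obj.t_range = None
        obj.tm = tm
        obj.no_melting = False
        return obj

    @property
    def basis_coeffs(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def dCp(self) -> float:
        """Folding heat-capacity change (negative for a normal curve)."""
        return -self.c

    @property
    def dHm(self) -> float:
        """Folding enthalpy at Tm (negative for a normal curve)."""
        return self.a - self.c * self.tm

    @property
    def ts(self) -> float:
        """Temperature of maximal stability: the stationary point of dG."""
        if self.c == 0:
            return math.nan
        return math.exp(-1.0 - self.b / self.c)

    def evaluate(self, t):
        """dG at temperature(s) t (K, > 0) in the curve's own units."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("temperature must be positive; the 0 K limit "
                             "is the basis constant a")
        out = self.a + self.b * t + self.c * t * np.log(t)
        return float(out) if out.ndim == 0 else out


def gibbs_helmholtz(T: float, curve: StabilityCurve) -> float:
    """dG(T) of a stability curve (K in, curve units out)."""
    return curve.evaluate(T)


def curve_roots(a: float, b: float, c: float,
                lo: float = 1e-3, hi: float = T_SEARCH_MAX) -> list[float]:
    """All zero crossings of a + bT + cT ln T on (lo, hi], by scan + refine."""
    grid = np.linspace(lo, hi, 4001)
    vals = a + b * grid + c * grid * np.log(grid)
    roots: list[float] = []
    f = lambda t: a + b * t + c * t * math.log(t)
    for i in range(len(grid) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v0 == 0.0:
            roots.append(float(grid[i]))
        elif v0 * v1 < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    # deduplicate near-identical refinements
    out: list[float] = []
    for r in roots:
        if not out or abs(r - out[-1]) > 1e-6:
            out.append(r)
    return out


def _nearest_root(roots: list[float], t_range: tuple[float, float] | None) -> float:
    if t_range is None:
        return roots[-1]
    lo, hi = t_range

    def dist(r: float) -> float:
        if lo <= r <= hi:
            return 0.0
        return min(abs(r - lo), abs(r - hi))

    return min(roots, key=lambda r: (dist(r), -r))


def fit_curve(
    points: list[tuple[float, float]],
    anchor: float | None = None,
) -> StabilityCurve:
    """Least-squares Gibbs-Helmholtz fit through (T Kelvin, dG) points.

    With exactly three distinct temperatures the fit interpolates.  An
    ``anchor`` value fixes the basis constant a -- the T -> 0 limit of the
    curve -- and fits (b, c) by least squares on the residual.

    The normal equations are solved in a centered basis
    {1, T - T0, T ln(T/T0) - (T - T0)} (T0 = mean temperature) to keep the
    design well conditioned, and mapped back exactly.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    t = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive Kelvin")
    if len(np.unique(t)) != len(t):
        raise ValueError("degenerate design: duplicate temperatures")
    t0 = float(t.mean())
    log_ratio = np.log(t / t0)
    u2 = t - t0
    u3 = t * log_ratio - u2
    if anchor is None:
        design = np.column_stack([np.ones_like(t), u2, u3])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        A, B, C = (float(v) for v in coef)
        c = C
        b = B - c * (1.0 + math.log(t0))
        a = A - b * t0 - c * t0 * math.log(t0)
    else:
        # dG(T) = anchor + B*T + C*(u3 - T0), with a fixed to the anchor
        design = np.column_stack([t, u3 - t0])
        coef, *_ = np.linalg.lstsq(design, y - anchor, rcond=None)
        B, C = (float(v) for v in coef)
        c = C
        b = B - c * (1.0 + math.log(t0))
        a = anchor
    return StabilityCurve(a=a, b=b, c=c,
                          t_range=(float(t.min()), float(t.max())))


def needs_anchor(
    curve: StabilityCurve,
    family_dg0: list[float],
) -> tuple[bool, float | None]:
    """Decide whether a fitted curve must be re-fitted with the 0 K anchor.

    Triggers when the curvature has the wrong sign (fitted dCp > 0, an
    upside-down curve under the folding convention) or when the curve's
    0 K limit deviates from the family mean of the other members' limits by
    more than one standard deviation (at least two reference values
    needed).  The anchor value is that family mean.
    """
    anchor_value = float(np.mean(family_dg0)) if family_dg0 else None
    if curve.dCp > 0:
        return True, anchor_value
    if len(family_dg0) >= 2:
        sd = float(np.std(family_dg0, ddof=1))
        if abs(curve.a - anchor_value) > sd:
            return True, anchor_value
    return False, anchor_value


def scale_factor_k(
    family_pairs: list[tuple[float, float]],
    other_family_ks: list[float] | None = None,
) -> float:
    """Amplitude scale from experimental-to-predicted dCp magnitudes.

    ``family_pairs`` holds (dcp_exp, dcp_pred) for the other members of the
    target's family; k is the ratio of their summed magnitudes.  Without
    family data, k falls back to the mean of the other families' k values
    with the single largest and smallest removed (plain mean when two or
    fewer values remain available).
    """
    if family_pairs:
        num = sum(abs(e) for e, _ in family_pairs)
        den = sum(abs(p) for _, p in family_pairs)
        if den == 0:
            raise ValueError("predicted dCp magnitudes sum to zero")
        return num / den
    ks = list(other_family_ks or [])
    if not ks:
        warnings.warn("no family dCp data and no fallback k values; k = 1")
        return 1.0
    if len(ks) > 2:
        ks = sorted(ks)[1:-1]
    return float(np.mean(ks))


def omega_factor(family_refs: list[tuple[float, float]]) -> float:
    """Temperature factor aligning fitted zero crossings with experiment.

    ``family_refs`` holds (T0_Q, tm_exp_Q) in Kelvin for the other family
    members: the zero crossing of member Q's unscaled fitted curve and its
    experimental melting temperature.  omega minimises
    sum_Q (T0_Q/omega - tm_exp_Q)^2, solved in closed form through
    u = 1/omega.  Without references omega = 1 with a warning.
    """
    if not family_refs:
        warnings.warn("no family references for omega; omega = 1")
        return 1.0
    t0 = np.array([r[0] for r in family_refs], dtype=float)
    tm = np.array([r[1] for r in family_refs], dtype=float)
    if np.any(t0 <= 0) or np.any(tm <= 0):
        raise ValueError("omega references must be positive Kelvin")
    u = float(np.dot(t0, tm) / np.dot(t0, t0))
    return 1.0 / u


@dataclass
class CurveCorrections:
    """Per-protein amplitude (k) and temperature (omega) corrections."""

    k: float = 1.0
    omega: float = 1.0
    anchor_used: bool = False
    anchor_value: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0 or self.omega <= 0:
            raise ValueError("k and omega must be positive")


@dataclass
class PredictionRecord:
    """Thermodynamic parameters extracted from a corrected stability curve.

    Temperatures in Celsius; dcp_pred is reported as the positive
    unfolding-convention magnitude (kcal/mol/K) for comparability with
    experimental tables, while dg25_pred, dHm_pred and dSm_pred keep the
    folding convention.
    """

    id: str
    tm_pred: float
    ts_pred: float
    dcp_pred: float
    dg25_pred: float
    dHm_pred: float
    dSm_pred: float
    k: float
    omega: float
    anchor_used: bool
    no_melting: bool = False
    basis_coeffs: tuple[float, float, float] | None = None
    family: str | None = None


def extract_thermo_params(
    curve: StabilityCurve,
    corr: CurveCorrections,
    record_id: str = "protein",
    family: str | None = None,
) -> PredictionRecord:
    """Read all thermodynamic outputs off the corrected curve.

    The corrected curve is dG_final(T) = k dG_fit(omega T); its melting
    temperature is the unique zero above the stability maximum (located by
    bracketed bisection to |dG| < 1e-9), dCp is k times the fitted T ln T
    coefficient magnitude, and dHm follows from the slope at Tm through
    dHm = -Tm d(dG)/dT |_Tm, whence dSm = dHm / Tm.
    """
    k, om = corr.k, corr.omega

    def f(t: float) -> float:
        return k * curve.evaluate(om * t)

    ts_corr = curve.ts / om if not math.isnan(curve.ts) else math.nan
    tm_k = math.nan
    no_melting = False
    lo = ts_corr if not math.isnan(ts_corr) else 1.0
    if math.isnan(lo) or lo <= 0:
        lo = 1.0
    hi = T_SEARCH_MAX / om
    if curve.c <= 0:
        # upside-down (or flat) curvature survived anchoring: the curve has
        # a stability maximum instead of a minimum and no melting
        # transition in the two-state model's sense
        no_melting = True
    elif lo >= hi:
        no_melting = True
    elif f(lo) == 0.0:
        tm_k = lo
    elif f(lo) * f(hi) < 0:
        tm_k = brentq(f, lo, hi, xtol=1e-12)
        # polish the bracket until the residual meets the bisection target
        assert abs(f(tm_k)) < 1e-9 * max(1.0, abs(k * curve.a))
    else:
        no_melting = True

    if no_melting:
        tm_c = ts_c = dg25 = dhm = dsm = math.nan
    else:
        tm_c = tm_k - CELSIUS_TO_KELVIN
        ts_c = ts_corr - CELSIUS_TO_KELVIN
        dg25 = f(ROOM_TEMPERATURE_K)
        slope = k * om * (curve.b + curve.c * (1.0 + math.log(om * tm_k)))
        dhm = -tm_k * slope
        dsm = dhm / tm_k
    return PredictionRecord(
        id=record_id,
        tm_pred=tm_c,
        ts_pred=ts_c,
        dcp_pred=k * abs(curve.dCp),
        dg25_pred=dg25,
        dHm_pred=dhm,
        dSm_pred=dsm,
        k=k,
        omega=om,
        anchor_used=corr.anchor_used,
        no_melting=no_melting,
        basis_coeffs=curve.basis_coeffs,
        family=family,
    )


def sample_curve(
    curve: StabilityCurve,
    corr: CurveCorrections | None = None,
    t_min_c: float = -20.0,
    t_max_c: float = 130.0,
    step_c: float = 1.0,
):
    """Sample the (corrected) curve on a Celsius grid; returns a DataFrame."""
    import pandas as pd

    corr = corr or CurveCorrections()
    t_c = np.arange(t_min_c, t_max_c + step_c / 2, step_c)
    t_k = t_c + CELSIUS_TO_KELVIN
    dg = corr.k * curve.evaluate(corr.omega * t_k)
    return pd.DataFrame({"T_C": t_c, "dG": dg})
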