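"""Van't Hoff thermodynamics of binding.

ln Ka = -dH/(R T) + dS/R is fit by ordinary least squares of ln Ka on
1/T; dG(T) = dH - T dS.  The sign pattern of (dH, dS) classifies the
dominant non-covalent force by the Ross-Subramanian convention:
both negative -> van der Waals / hydrogen bonding, both positive ->
hydrophobic, dH < 0 with dS > 0 -> electrostatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .errors import DataError, InputError

R_GAS = 8.314  # J / mol / K


class Force(str, Enum):
    vdw_hbond = "vdw_hbond"
    hydrophobic = "hydrophobic"
    electrostatic = "electrostatic"
    indeterminate = "indeterminate"


@dataclass(frozen=True)
class ThermoResult:
    """Binding thermodynamics from a van't Hoff regression.

    delta_h in kJ/mol, delta_s in J/mol/K, delta_g_by_T maps each input
    temperature (K) to dG in kJ/mol computed as dH - T*dS.  Slope and
    intercept (with OLS standard errors) are those of ln Ka vs 1/T;
    ``delta_g_from_ka`` is the -RT ln Ka route, kept as a consistency
    diagnostic.
    """

    delta_h: float
    delta_s: float
    delta_g_by_T: dict
    slope: float
    intercept: float
    slope_stderr: float | None
    intercept_stderr: float | None
    r_squared: float | None
    force_label: Force
    delta_g_from_ka: dict = field(default_factory=dict)

    @property
    def delta_h_stderr(self):
        return None if self.slope_stderr is None else R_GAS * self.slope_stderr / 1000.0

    @property
    def delta_s_stderr(self):
        return None if self.intercept_stderr is None else R_GAS * self.intercept_stderr


def gibbs(delta_h: float, delta_s: float, T: float) -> float:
    """dG = dH - T dS, with dH in kJ/mol and dS in J/mol/K; returns kJ/mol."""
    if T <= 0:
        raise InputError("temperature must be > 0 K")
    return delta_h - T * delta_s / 1000.0


def classify_force(delta_h: float, delta_s: float) -> Force:
    """Ross-Subramanian sign rules for the dominant binding force.

    A zero on one side adopts the sign of the nonzero partner; (0, 0) is
    indeterminate, as is the (+, -) pattern (which implies dG > 0 at all
    temperatures).
    """
    if not (np.isfinite(delta_h) and np.isfinite(delta_s)):
        raise InputError("delta_h and delta_s must be finite")
    if delta_h == 0 and delta_s == 0:
        return Force.indeterminate
    sh = np.sign(delta_h) or np.sign(delta_s)
    ss = np.sign(delta_s) or np.sign(delta_h)
    if sh < 0 and ss < 0:
        return Force.vdw_hbond
    if sh > 0 and ss > 0:
        return Force.hydrophobic
    if sh < 0 and ss > 0:
        return Force.electrostatic
    return Force.indeterminate


def vant_hoff_fit(ka_by_T: dict) -> ThermoResult:
    """OLS of ln Ka on 1/T: dH = -R*slope, dS = R*intercept.

    With exactly two temperatures the line is determined exactly and
    r_squared / standard errors are reported as None.
    """
    pairs = list(ka_by_T.items()) if isinstance(ka_by_T, dict) else [
        (float(t), float(k)) for t, k in ka_by_T
    ]
    pairs.sort(key=lambda p: p[0])
    temps = np.array([t for t, _ in pairs], dtype=float)
    if temps.size < 2:
        raise InputError("need Ka at >= 2 temperatures")
    if np.unique(temps).size != temps.size:
        raise InputError("duplicate temperatures")
    ka = np.array([k for _, k in pairs], dtype=float)
    if np.any(ka <= 0):
        raise DataError("all Ka must be > 0")
    x = 1.0 / temps
    y = np.log(ka)
    if temps.size == 2:
        slope = float((y[1] - y[0]) / (x[1] - x[0]))
        intercept = float(y[0] - slope * x[0])
        slope_se = intercept_se = r2 = None
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        slope_se = float(res.stderr)
        intercept_se = float(res.intercept_stderr)
        r2 = float(res.rvalue**2)
    delta_h = -R_GAS * slope / 1000.0  # kJ/mol
    delta_s = R_GAS * intercept  # J/mol/K
    dg = {float(t): gibbs(delta_h, delta_s, float(t)) for t in temps}
    dg_ka = {
        float(t): -R_GAS * float(t) * float(np.log(k)) / 1000.0 for t, k in zip(temps, ka)
    }
    return ThermoResult(
        delta_h=delta_h,
        delta_s=delta_s,
        delta_g_by_T=dg,
        slope=slope,
        intercept=intercept,
        slope_stderr=slope_se,
        intercept_stderr=intercept_se,
        r_squared=r2,
        force_label=classify_force(delta_h, delta_s),
        delta_g_from_ka=dg_ka,
    )
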