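"""Fluorescence-quenching binding analysis.

The chain implemented here is the standard one for small-molecule /
serum-albumin titrations:

1. inner-filter correction  F_cor = F_obs * 10**((A_ex + A_em)/2)
2. Stern-Volmer fit         F0/F = 1 + Ksv [Q],  kq = Ksv / tau0
3. mechanism call from the temperature trend of Ksv and the size of kq
   relative to the diffusion-controlled ceiling (~2e10 /M/s)
4. double-log binding fit   log((F0-F)/F) = log Ka + n log[Q]
5. site-marker competition  (warfarin -> Sudlow site I, ibuprofen -> II,
   digitoxin -> III)

F is read as the peak intensity inside the emission window (parabolic
refinement), matching the convention of intensity-at-peak tables;
integrated area is available via ``intensity_mode="area"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .errors import DataError, DomainError, InputError, SizeError
from .spectra import Spectrum, peak_position


@dataclass(frozen=True)
class QuenchConfig:
    """Constants for quenching analysis.

    tau0 is the unquenched fluorophore lifetime in seconds (1e-8 s for
    Trp); diffusion_limit is the ceiling for diffusion-controlled
    bimolecular quenching in L/mol/s.
    """

    tau0: float = 1e-8
    diffusion_limit: float = 2e10

    def __post_init__(self):
        if self.tau0 <= 0 or self.diffusion_limit <= 0:
            raise InputError("tau0 and diffusion_limit must be > 0")


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered (quencher concentration, spectrum) pairs at one temperature.

    The first point must have q_conc == 0: it defines F0.  All spectra
    must share one axis grid.
    """

    points: tuple
    temperature: float
    protein_conc: float = 0.0

    def __post_init__(self):
        pts = tuple((float(q), s) for q, s in self.points)
        object.__setattr__(self, "points", pts)
        q = np.array([p[0] for p in pts])
        if q.size < 2:
            raise SizeError("titration needs at least 2 points")
        if q[0] != 0.0:
            raise InputError("first titration point must have q_conc == 0 (defines F0)")
        if np.any(q < 0) or not np.all(np.diff(q) > 0):
            raise InputError("q_conc must be non-negative and strictly increasing")
        axis0 = pts[0][1].axis
        for _, s in pts[1:]:
            if s.axis.shape != axis0.shape or not np.allclose(s.axis, axis0):
                raise InputError("all spectra in a titration must share one axis grid")

    @property
    def q_concs(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def spectra(self) -> list[Spectrum]:
        return [p[1] for p in self.points]


@dataclass(frozen=True)
class QuenchFit:
    """Stern-Volmer regression result: Ksv (L/mol), kq = Ksv/tau0 (L/mol/s)."""

    ksv: float
    kq: float
    intercept: float
    r_squared: float
    points: tuple
    temperature: float
    no_quenching: bool = False


@dataclass(frozen=True)
class BindingFit:
    """Double-log fit result: Ka = 10**intercept (L/mol), n = slope."""

    ka: float
    n: float
    r_squared: float
    points: tuple
    temperature: float


class Mechanism(str, Enum):
    static = "static"
    dynamic = "dynamic"
    mixed = "mixed"
    indeterminate = "indeterminate"


@dataclass(frozen=True)
class MechanismCall:
    label: Mechanism
    evidence: str


class Probe(str, Enum):
    """Sudlow site markers: which albumin pocket each probe reports on."""

    warfarin_siteI = "warfarin_siteI"
    ibuprofen_siteII = "ibuprofen_siteII"
    digitoxin_siteIII = "digitoxin_siteIII"


PROBE_SITE = {
    Probe.warfarin_siteI: "I",
    Probe.ibuprofen_siteII: "II",
    Probe.digitoxin_siteIII: "III",
}


@dataclass(frozen=True)
class DisplacementCurve:
    """Probe displacement (%) versus probe concentration (M)."""

    probe: Probe
    points: tuple  # ((probe_conc_M, displacement_pct), ...)

    def __post_init__(self):
        pts = tuple((float(c), float(d)) for c, d in self.points)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "probe", Probe(self.probe))
        if any(d <= 0 for _, d in pts):
            raise InputError("displacement % must be > 0")
        concs = [c for c, _ in pts]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise InputError("probe concentrations must be strictly increasing")


@dataclass(frozen=True)
class SiteAssignment:
    site: str  # "I", "II", "III", "ambiguous" or "none"
    verdicts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def correct_inner_filter(f_obs, a_ex, a_em):
    """Undo inner-filter attenuation: F_cor = F_obs * 10**((A_ex + A_em)/2).

    Vectorized over arrays; absorbances must be non-negative, so the
    corrected intensity is never smaller than the observed one.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise DomainError("absorbance must be >= 0")
    if np.any(f_obs < 0):
        raise DomainError("observed fluorescence must be >= 0")
    out = f_obs * 10.0 ** ((a_ex + a_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def _read_intensity(spectrum: Spectrum, em_window, mode: str) -> float:
    if mode == "peak":
        return peak_position(spectrum, em_window).intensity
    if mode == "area":
        sub = spectrum if em_window is None else spectrum.slice(*em_window)
        return float(np.trapezoid(sub.intensity, sub.axis))
    raise InputError(f"unknown intensity mode {mode!r}")


def stern_volmer_fit(
    series: TitrationSeries,
    config: QuenchConfig = QuenchConfig(),
    em_window: tuple[float, float] | None = None,
    intensity_mode: str = "peak",
    clamp_intercept: bool = False,
) -> QuenchFit:
    """Ordinary least squares of F0/F on [Q].

    Intensities must already be inner-filter corrected.  The intercept is
    left free by default (``clamp_intercept=True`` forces it to 1 by
    fitting F0/F - 1 through the origin).  A non-positive slope is
    returned with ``no_quenching=True`` rather than raising.
    """
    q = series.q_concs[1:]
    if q.size < 3:
        raise SizeError("Stern-Volmer fit needs >= 3 nonzero [Q] points")
    f0 = _read_intensity(series.spectra[0], em_window, intensity_mode)
    f = np.array([_read_intensity(s, em_window, intensity_mode) for s in series.spectra[1:]])
    if f0 <= 0 or np.any(f <= 0):
        raise DataError("fluorescence intensities must be > 0 for F0/F")
    ratio = f0 / f
    if clamp_intercept:
        slope = float(np.dot(q, ratio - 1) / np.dot(q, q))
        intercept = 1.0
        ss_res = float(np.sum((ratio - (1 + slope * q)) ** 2))
        ss_tot = float(np.sum((ratio - ratio.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(q, ratio)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    no_quench = slope <= 0
    if no_quench:
        warnings.warn("non-positive Stern-Volmer slope: no quenching detected", stacklevel=2)
    return QuenchFit(
        ksv=slope,
        kq=slope / config.tau0,
        intercept=intercept,
        r_squared=r2,
        points=tuple(zip(q.tolist(), ratio.tolist())),
        temperature=series.temperature,
        no_quenching=no_quench,
    )


def classify_mechanism(
    fits_by_temperature: list[QuenchFit], config: QuenchConfig = QuenchConfig()
) -> MechanismCall:
    """Call the quenching mechanism from Ksv(T) trend and kq magnitude.

    Criterion A: Ksv strictly increases with temperature (collisional
    signature).  Criterion B: every kq exceeds the diffusion-controlled
    ceiling (static signature).  A and B -> mixed; B alone -> static;
    A alone -> dynamic; neither -> indeterminate.
    """
    if len(fits_by_temperature) < 2:
        raise InputError("need fits at >= 2 temperatures")
    temps = [f.temperature for f in fits_by_temperature]
    if any(b <= a for a, b in zip(temps, temps[1:])):
        raise InputError("fits must be sorted by strictly increasing temperature")
    ksv = [f.ksv for f in fits_by_temperature]
    kq = [f.kq for f in fits_by_temperature]
    a = all(y > x for x, y in zip(ksv, ksv[1:]))
    b = all(k > config.diffusion_limit for k in kq)
    label = {
        (True, True): Mechanism.mixed,
        (False, True): Mechanism.static,
        (True, False): Mechanism.dynamic,
        (False, False): Mechanism.indeterminate,
    }[(a, b)]
    evidence = (
        f"Ksv strictly increasing with T: {a} (Ksv={ksv}); "
        f"all kq > diffusion limit {config.diffusion_limit:g}: {b} (kq={kq})"
    )
    return MechanismCall(label=label, evidence=evidence)


def double_log_fit(
    series: TitrationSeries,
    em_window: tuple[float, float] | None = None,
    intensity_mode: str = "peak",
) -> BindingFit:
    """Fit log10((F0-F)/F) = log10 Ka + n log10 [Q] by OLS.

    Points with F >= F0 or F <= 0 carry no binding information on the log
    scale and are excluded with a warning; at least 3 must survive.
    """
    q = series.q_concs[1:]
    f0 = _read_intensity(series.spectra[0], em_window, intensity_mode)
    f = np.array([_read_intensity(s, em_window, intensity_mode) for s in series.spectra[1:]])
    ok = (f > 0) & (f < f0)
    if not ok.all():
        warnings.warn(
            f"excluding {np.count_nonzero(~ok)} point(s) with F >= F0 or F <= 0",
            stacklevel=2,
        )
    q, f = q[ok], f[ok]
    if q.size < 3:
        raise DataError("fewer than 3 usable points for the double-log fit")
    x = np.log10(q)
    y = np.log10((f0 - f) / f)
    res = stats.linregress(x, y)
    return BindingFit(
        ka=float(10.0**res.intercept),
        n=float(res.slope),
        r_squared=float(res.rvalue**2),
        points=tuple(zip(x.tolist(), y.tolist())),
        temperature=series.temperature,
    )


def probe_displacement(f1: float, f2: float) -> float:
    """Probe displacement % = 100 * F2 / F1.

    F1 is the complex fluorescence without the site marker, F2 with it.
    100% means the marker displaced nothing; 0% means full displacement.
    """
    if f1 <= 0:
        raise DomainError("F1 must be > 0")
    if f2 < 0:
        raise DomainError("F2 must be >= 0")
    return 100.0 * f2 / f1


def assign_site(
    curves: list[DisplacementCurve],
    drop_threshold_pct: float = 15.0,
    trend_min_points: int = 3,
    trend_tolerance_pct: float = 2.0,
) -> SiteAssignment:
    """Identify the Sudlow site from marker displacement curves.

    A probe "competes" when its displacement is monotonically
    non-increasing (successive increases of up to ``trend_tolerance_pct``
    points are tolerated) and ends below 100 - drop_threshold_pct.
    Exactly one competitor names the site; zero -> "none"; several ->
    "ambiguous".
    """
    probes = [c.probe for c in curves]
    if len(set(probes)) != len(probes):
        raise InputError("duplicate probes in site assignment")
    verdicts = {}
    competitors = []
    for curve in curves:
        if len(curve.points) < trend_min_points:
            raise InputError(
                f"{curve.probe.value}: need >= {trend_min_points} points, got {len(curve.points)}"
            )
        disp = np.array([d for _, d in curve.points])
        monotone = bool(np.all(np.diff(disp) <= trend_tolerance_pct))
        dropped = bool(disp[-1] < 100.0 - drop_threshold_pct)
        competes = monotone and dropped
        verdicts[curve.probe.value] = {
            "monotone_non_increasing": monotone,
            "final_displacement_pct": float(disp[-1]),
            "competes": competes,
        }
        if competes:
            competitors.append(curve.probe)
    if len(competitors) == 1:
        site = PROBE_SITE[competitors[0]]
    elif not competitors:
        site = "none"
    else:
        site = "ambiguous"
    return SiteAssignment(site=site, verdicts=verdicts)
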