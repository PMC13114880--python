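"""Ground-truth generators for every analysis stage.

Each generator emulates one class of experimental input — quenching
titrations, van't Hoff Ka(T) sets, donor/acceptor FRET spectral pairs,
excitation-emission matrices with Rayleigh ridges, amide-I envelopes,
and biased umbrella-sampling coordinates — and returns the data together
with the exact truth used to build it, so downstream estimators can be
scored without re-deriving anything.

The titration model is the functional form under which the double-log
binding fit is exact, F = F0 / (1 + Ka [Q]^n), so noiseless recovery
tests isolate estimator correctness from model mismatch.  A mechanistic
1:1 free-ligand-depletion variant (:func:`gen_titration_depletion`) is
provided to quantify the bias of the double-log form against a physical
binding model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .spectra import EEM, Spectrum
from .thermo import R_GAS
from .wham import KB_KJ, UmbrellaWindow

# --------------------------------------------------------------------------
# fluorescence titrations
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TitrationTruth:
    """Parameters of a synthetic quenching titration.

    Defaults mirror a serum-albumin/flavonoid system at 298 K: moderate
    affinity (Ka = 3.22e4 L/mol, n = 1.07), tryptophan emission centered
    at 340.6 nm with a +4.8 nm red shift at full saturation, and ligand
    absorbances at the excitation/emission wavelengths that drive
    inner-filter attenuation.
    """

    ka: float = 3.22e4
    n: float = 1.07
    ksv_dynamic: float = 0.0  # extra collisional quenching, L/mol
    f0_peak: float = 1000.0
    peak_center: float = 340.6
    peak_sigma: float = 20.0
    shift_per_bound_fraction: float = 4.8
    ligand_eps_ex: float = 5000.0  # L/mol/cm at the excitation wavelength
    ligand_eps_em: float = 500.0  # L/mol/cm at the emission wavelength
    path_length: float = 1.0  # cm
    noise_sigma: float = 0.0  # multiplicative, fraction
    seed: int | None = None

    def __post_init__(self):
        if self.ka <= 0:
            raise InputError("ka must be > 0")
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be >= 0")


DEFAULT_Q_CONCS = tuple(np.linspace(0.0, 2.5e-5, 11))  # mol/L


def gen_titration(
    truth: TitrationTruth,
    q_concs=DEFAULT_Q_CONCS,
    temperature: float = 298.0,
    axis=None,
):
    """Synthesize a quenching titration plus its sidecar truth.

    Per concentration: the quenched peak intensity is
    F_ideal = F0 / ((1 + Ka [Q]^n)(1 + Ksv_dyn [Q])); a Gaussian emission
    band of that amplitude is centered at peak_center + shift * theta,
    with bound fraction theta = 1 - F_ideal(static part)/F0; the whole
    spectrum is attenuated by 10**-((A_ex + A_em)/2) with A = eps [Q] L;
    multiplicative Gaussian noise is applied last.

    Returns ``(series, sidecar)`` where sidecar records per-point bound
    fractions and absorbances (what a manifest would carry) and the truth.
    """
    q = np.asarray(q_concs, dtype=float)
    if q[0] != 0:
        raise InputError("q_concs must start at 0")
    if axis is None:
        axis = np.arange(280.0, 420.0 + 1e-9, 0.2)
    rng = np.random.default_rng(truth.seed)
    from .binding import TitrationSeries  # local import to avoid cycle

    points = []
    side_points = []
    for qi in q:
        static = 1.0 + truth.ka * qi**truth.n if qi > 0 else 1.0
        dynamic = 1.0 + truth.ksv_dynamic * qi
        f_ideal = truth.f0_peak / (static * dynamic)
        theta = 1.0 - 1.0 / static
        center = truth.peak_center + truth.shift_per_bound_fraction * theta
        a_ex = truth.ligand_eps_ex * qi * truth.path_length
        a_em = truth.ligand_eps_em * qi * truth.path_length
        atten = 10.0 ** (-(a_ex + a_em) / 2.0)
        y = f_ideal * np.exp(-0.5 * ((axis - center) / truth.peak_sigma) ** 2) * atten
        if truth.noise_sigma > 0:
            y = np.clip(y * (1.0 + truth.noise_sigma * rng.standard_normal(axis.size)), 0, None)
        points.append(
            (qi, Spectrum(axis, y, kind="emission", meta={"temperature_K": temperature}))
        )
        side_points.append(
            {
                "q_conc_M": float(qi),
                "bound_fraction": float(theta),
                "a_ex": float(a_ex),
                "a_em": float(a_em),
                "f_ideal_peak": float(f_ideal),
            }
        )
    series = TitrationSeries(points=tuple(points), temperature=temperature)
    sidecar = {"truth": truth, "points": side_points, "temperature_K": temperature}
    return series, sidecar


def correct_series(series, sidecar):
    """Apply the inner-filter correction to a generated series using its
    sidecar absorbances, mirroring what a manifest-driven run does."""
    from .binding import TitrationSeries, correct_inner_filter

    pts = []
    for (qi, spec), sp in zip(series.points, sidecar["points"]):
        y = correct_inner_filter(spec.intensity, sp["a_ex"], sp["a_em"])
        pts.append((qi, Spectrum(spec.axis, y, spec.kind, dict(spec.meta))))
    return TitrationSeries(pts, series.temperature, series.protein_conc)


def gen_titration_depletion(
    truth: TitrationTruth,
    protein_conc: float,
    q_concs=DEFAULT_Q_CONCS,
    temperature: float = 298.0,
    axis=None,
):
    """Mechanistic 1:1 variant: exact complexation with ligand depletion.

    Solves the quadratic [PL] equilibrium for total protein P0 and total
    ligand Q0, sets F = F0 (1 - [PL]/P0), and applies the same shift /
    inner-filter / noise pipeline.  Used to document the bias of the
    double-log fit (which assumes total == free ligand), not for
    acceptance scoring.
    """
    q = np.asarray(q_concs, dtype=float)
    if axis is None:
        axis = np.arange(280.0, 420.0 + 1e-9, 0.2)
    rng = np.random.default_rng(truth.seed)
    from .binding import TitrationSeries

    p0 = protein_conc
    points = []
    side_points = []
    for qi in q:
        b = p0 + qi + 1.0 / truth.ka
        pl = (b - np.sqrt(b * b - 4.0 * p0 * qi)) / 2.0
        theta = pl / p0
        f_ideal = truth.f0_peak * (1.0 - theta)
        center = truth.peak_center + truth.shift_per_bound_fraction * theta
        a_ex = truth.ligand_eps_ex * qi * truth.path_length
        a_em = truth.ligand_eps_em * qi * truth.path_length
        atten = 10.0 ** (-(a_ex + a_em) / 2.0)
        y = f_ideal * np.exp(-0.5 * ((axis - center) / truth.peak_sigma) ** 2) * atten
        if truth.noise_sigma > 0:
            y = np.clip(y * (1.0 + truth.noise_sigma * rng.standard_normal(axis.size)), 0, None)
        points.append(
            (qi, Spectrum(axis, y, kind="emission", meta={"temperature_K": temperature}))
        )
        side_points.append(
            {"q_conc_M": float(qi), "bound_fraction": float(theta), "a_ex": float(a_ex),
             "a_em": float(a_em), "f_ideal_peak": float(f_ideal)}
        )
    series = TitrationSeries(points=tuple(points), temperature=temperature,
                             protein_conc=p0)
    return series, {"truth": truth, "points": side_points, "temperature_K": temperature}


# --------------------------------------------------------------------------
# van't Hoff
# --------------------------------------------------------------------------

def gen_vant_hoff(delta_h: float, delta_s: float, temps) -> dict:
    """Ka(T) = exp(-dH/(R T) + dS/R), with dH in J/mol and dS in J/mol/K."""
    temps = np.asarray(temps, dtype=float)
    if np.any(temps <= 0):
        raise InputError("temperatures must be > 0 K")
    return {
        float(t): float(np.exp(-delta_h / (R_GAS * t) + delta_s / R_GAS)) for t in temps
    }


# --------------------------------------------------------------------------
# FRET spectral pairs
# --------------------------------------------------------------------------

def gen_fret_pair(
    donor_center: float = 340.0,
    donor_sigma: float = 20.0,
    donor_amp: float = 1000.0,
    acceptor_center: float = 340.0,
    acceptor_sigma: float = 40.0,
    acceptor_eps_max: float = 9.0e3,
    grid=(300.0, 450.0, 0.5),
    oracle_refinement: int = 100,
):
    """Gaussian donor-emission / acceptor-absorptivity pair plus a J oracle.

    The oracle evaluates the same discrete overlap sum on a grid
    ``oracle_refinement`` times finer, serving as the quadrature
    reference for the production-resolution integral.  Defaults give
    J ~ 1.2e-14 cm^3 L/mol, the magnitude typical of Trp-donor protein/
    ligand pairs.
    """
    lo, hi, step = grid
    axis = np.arange(lo, hi + 1e-9, step)
    donor = Spectrum(
        axis,
        donor_amp * np.exp(-0.5 * ((axis - donor_center) / donor_sigma) ** 2),
        kind="emission",
    )
    acceptor = Spectrum(
        axis,
        acceptor_eps_max * np.exp(-0.5 * ((axis - acceptor_center) / acceptor_sigma) ** 2),
        kind="absorbance",
    )
    fine = np.arange(lo, hi + 1e-9, step / oracle_refinement)
    f = donor_amp * np.exp(-0.5 * ((fine - donor_center) / donor_sigma) ** 2)
    eps = acceptor_eps_max * np.exp(-0.5 * ((fine - acceptor_center) / acceptor_sigma) ** 2)
    lam_cm = fine / 1e7
    dl = np.gradient(lam_cm)
    j_oracle = float(np.sum(f * eps * lam_cm**4 * dl) / np.sum(f * dl))
    return donor, acceptor, j_oracle


# --------------------------------------------------------------------------
# excitation-emission matrices
# --------------------------------------------------------------------------

DEFAULT_EEM_PEAKS = (
    (275.0, 340.0, 894.3, 12.0, 18.0),  # aromatic-residue peak
    (230.0, 340.0, 808.8, 10.0, 18.0),  # peptide-backbone peak
)


def gen_eem(
    peaks=DEFAULT_EEM_PEAKS,
    scatter_amp: float = 2000.0,
    scatter_width: float = 6.0,
    ex_grid=(200.0, 350.0, 5.0),
    em_grid=(250.0, 500.0, 5.0),
) -> EEM:
    """Sum of bivariate Gaussian peaks plus first/second-order Rayleigh
    ridges along em = ex and em = 2 ex.

    ``peaks`` entries are (ex_center, em_center, amplitude, sigma_ex,
    sigma_em); defaults reproduce the two-peak signature of a serum
    albumin EEM (275/340 and 230/340 nm).
    """
    ex = np.arange(ex_grid[0], ex_grid[1] + 1e-9, ex_grid[2])
    em = np.arange(em_grid[0], em_grid[1] + 1e-9, em_grid[2])
    exg = ex[:, None]
    emg = em[None, :]
    z = np.zeros((ex.size, em.size))
    for cx, cm, amp, sx, sm in peaks:
        z += amp * np.exp(-0.5 * (((exg - cx) / sx) ** 2 + ((emg - cm) / sm) ** 2))
    z += scatter_amp * np.exp(-0.5 * ((emg - exg) / scatter_width) ** 2)
    z += scatter_amp * np.exp(-0.5 * ((emg - 2 * exg) / scatter_width) ** 2)
    return EEM(ex, em, z)


# --------------------------------------------------------------------------
# amide-I envelopes
# --------------------------------------------------------------------------

DEFAULT_BAND_CENTERS = {
    "beta_sheet": 1625.0,
    "random_coil": 1645.0,
    "alpha_helix": 1654.0,
    "beta_turn": 1670.0,
    "antiparallel_beta": 1688.0,
}


def gen_amide1(
    fractions: dict,
    centers: dict | None = None,
    sigma: float = 7.0,
    total_area: float = 10.0,
    baseline=(0.02, 1e-4),
    noise_sigma: float = 0.0,
    seed: int | None = None,
    grid=(1580.0, 1720.0, 1.0),
):
    """Amide-I envelope as a Gaussian band sum with known class areas.

    ``fractions`` maps structure-class names to area fractions (sum 1);
    band areas are proportional to them.  A linear baseline
    (offset, slope per cm^-1 relative to 1600) and additive Gaussian
    noise emulate raw instrument output.  Returns ``(spectrum, truth)``.
    """
    centers = dict(DEFAULT_BAND_CENTERS, **(centers or {}))
    tot = sum(fractions.values())
    if abs(tot - 1.0) > 1e-9:
        raise InputError(f"fractions must sum to 1, got {tot}")
    axis = np.arange(grid[0], grid[1] + 1e-9, grid[2])
    rng = np.random.default_rng(seed)
    y = np.zeros_like(axis)
    bands = []
    for cls, frac in fractions.items():
        if frac == 0:
            continue
        c = centers[str(cls)]
        area = total_area * frac
        height = area / (sigma * np.sqrt(2 * np.pi))
        y += height * np.exp(-0.5 * ((axis - c) / sigma) ** 2)
        bands.append({"class": str(cls), "center": c, "sigma": sigma, "area": area})
    offset, slope = baseline
    y = y + offset + slope * (axis - 1600.0)
    if noise_sigma > 0:
        y = y + noise_sigma * rng.standard_normal(axis.size)
    spec = Spectrum(axis, np.clip(y, 0, None), kind="ftir")
    truth = {"fractions": {str(k): float(v) for k, v in fractions.items()},
             "bands": bands, "sigma": sigma, "total_area": total_area,
             "baseline": baseline, "noise_sigma": noise_sigma, "seed": seed}
    return spec, truth


# --------------------------------------------------------------------------
# umbrella sampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PmfTruth:
    """Parametric 1-D PMF: a sum of Gaussian wells (negative height) and
    barriers (positive height) over the reaction coordinate z.

    Defaults are a double well: a bound well of depth 15 kJ/mol at
    z = 0.3 nm, a 5 kJ/mol barrier crest at 1.0 nm (20 kJ/mol above the
    bound minimum) and a shallower well at 1.7 nm, sampled by 30 harmonic
    windows with the 1000 kJ/mol/nm^2 force constant typical of
    pull-coordinate umbrella protocols.  ``samples_per_window`` is the
    raw per-window draw count — 5000 emulates a 10 ns window written
    every 2 ps — of which the first ``burn_in`` fraction is discarded,
    mirroring the equilibration segment dropped from real trajectories.
    """

    terms: tuple = ((-15.0, 0.3, 0.15), (5.0, 1.0, 0.2), (-10.0, 1.7, 0.15))
    domain: tuple = (0.0, 2.0)
    temperature: float = 300.0
    window_centers: tuple = tuple(np.linspace(0.05, 1.95, 30))
    force_constant: float = 1000.0
    samples_per_window: int = 5000
    burn_in: float = 0.2
    seed: int | None = None

    def potential(self, z):
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for height, center, sigma in self.terms:
            u = u + height * np.exp(-0.5 * ((z - center) / sigma) ** 2)
        return u

    def profile(self, grid):
        """True PMF on ``grid``, min-shifted to 0."""
        u = self.potential(grid)
        return u - u.min()


def gen_umbrella(truth: PmfTruth, fine_points: int = 4000):
    """Exact i.i.d. biased Boltzmann samples for every umbrella window.

    Per window the density ~ exp(-(U(z) + k/2 (z - z_i)^2)/kT) is built
    on a ``fine_points`` grid over the domain and sampled by inverse-CDF
    transform; the first ``burn_in`` fraction of draws is discarded
    (a no-op statistically for i.i.d. draws, mirroring the discarded
    equilibration of real trajectories).  Returns ``(windows, z_grid,
    true_profile)`` with the truth min-shifted to 0.
    """
    rng = np.random.default_rng(truth.seed)
    kT = KB_KJ * truth.temperature
    z = np.linspace(truth.domain[0], truth.domain[1], fine_points)
    u = truth.potential(z)
    windows = []
    n_total = truth.samples_per_window
    n_keep = n_total - int(np.floor(truth.burn_in * n_total))
    for center in truth.window_centers:
        bias = 0.5 * truth.force_constant * (z - center) ** 2
        logw = -(u + bias) / kT
        logw -= logw.max()
        w = np.exp(logw)
        if w.sum() <= 0 or not np.isfinite(w.sum()):
            raise InputError(f"density numerically zero across window at {center}")
        cdf = np.cumsum(w)
        cdf += np.arange(1, cdf.size + 1) * (1e-13 * cdf[-1])  # strictify flat tails
        cdf /= cdf[-1]
        draws = np.interp(rng.random(n_total), cdf, z)
        samples = draws[n_total - n_keep:]
        windows.append(
            UmbrellaWindow(center=float(center), force_constant=truth.force_constant,
                           samples=samples)
        )
    return windows, z, truth.profile(z)
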