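"""Förster resonance energy transfer (FRET) between a protein donor and a
bound ligand acceptor.

The overlap integral is the discrete form

    J = sum(F(l) eps(l) l^4 dl) / sum(F(l) dl)

with the wavelength l expressed in cm, so that with eps in L/mol/cm the
integral carries cm^3 L/mol and the Förster radius follows from

    R0^6 = 8.8e-25 * K^2 * N^-4 * phi * J        (R0 in cm)

This cm convention is what makes the standard 8.8e-25 prefactor
dimensionally consistent; it is validated in the tests by reproducing a
published R0 from its own J.  Efficiency E = (F0 - F)/F0 = R0^6/(R0^6 +
r^6) then gives the donor-acceptor distance r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, LimitError, SizeError
from .spectra import Spectrum

NM_PER_CM = 1e7


@dataclass(frozen=True)
class FretConstants:
    """Photophysical constants: orientation factor K^2 (2/3 for isotropic
    tumbling), medium refractive index N, and donor quantum yield phi."""

    k2: float = 2.0 / 3.0
    n_refr: float = 1.336
    phi: float = 0.118

    def __post_init__(self):
        if self.k2 <= 0 or self.n_refr <= 0 or self.phi <= 0:
            raise DomainError("FRET constants must be > 0")
        if self.k2 > 4:
            raise DomainError("orientation factor K^2 cannot exceed 4")


@dataclass(frozen=True)
class FretResult:
    """j in cm^3 L/mol, efficiency e in [0,1], radii in nm."""

    j: float
    e: float
    r0: float
    r: float
    constants: FretConstants


def overlap_integral(
    donor_emission: Spectrum, acceptor_molar_absorptivity: Spectrum
) -> float:
    """Spectral overlap J of donor emission and acceptor absorptivity.

    Both spectra are linearly interpolated onto the donor's grid points
    inside the common wavelength range (no extrapolation).  Disjoint
    supports return J = 0 with a warning.
    """
    d, a = donor_emission, acceptor_molar_absorptivity
    if np.any(d.intensity < 0) or np.any(a.intensity < 0):
        raise DomainError("spectral intensities must be >= 0 for the overlap integral")
    lo = max(d.axis[0], a.axis[0])
    hi = min(d.axis[-1], a.axis[-1])
    grid = d.axis[(d.axis >= lo) & (d.axis <= hi)]
    if grid.size < 3:
        warnings.warn("donor and acceptor spectra do not overlap; J = 0", stacklevel=2)
        return 0.0
    f = np.interp(grid, d.axis, d.intensity)
    eps = np.interp(grid, a.axis, a.intensity)
    lam_cm = grid / NM_PER_CM
    dlam = np.gradient(lam_cm)
    denom = np.sum(f * dlam)
    if denom == 0:
        warnings.warn("donor intensity is zero across the overlap; J = 0", stacklevel=2)
        return 0.0
    return float(np.sum(f * eps * lam_cm**4 * dlam) / denom)


def forster_radius(j: float, constants: FretConstants = FretConstants()) -> float:
    """R0 in nm from R0^6 = 8.8e-25 K^2 N^-4 phi J (J in cm^3 L/mol)."""
    if j < 0:
        raise DomainError("overlap integral must be >= 0")
    r0_cm = (8.8e-25 * constants.k2 * constants.n_refr**-4 * constants.phi * j) ** (1.0 / 6.0)
    return r0_cm * NM_PER_CM


def transfer_efficiency(f0: float, f: float) -> float:
    """E = (F0 - F)/F0 from donor intensities without/with acceptor."""
    if f0 <= 0:
        raise DomainError("F0 must be > 0")
    if f < 0 or f > f0:
        raise DomainError("need 0 <= F <= F0 for a physical efficiency")
    return (f0 - f) / f0


def donor_acceptor_distance(e: float, r0: float) -> float:
    """Invert E = R0^6/(R0^6 + r^6):  r = R0 ((1-E)/E)^(1/6)."""
    if not 0 < e < 1:
        raise LimitError("r is undefined at E = 0 and collapses to 0 at E = 1")
    if r0 <= 0:
        raise DomainError("R0 must be > 0")
    return r0 * ((1.0 - e) / e) ** (1.0 / 6.0)


def efficiency_from_distance(r: float, r0: float) -> float:
    """Forward Förster law E = R0^6 / (R0^6 + r^6)."""
    if r <= 0 or r0 <= 0:
        raise DomainError("r and R0 must be > 0")
    return r0**6 / (r0**6 + r**6)


def fret_analysis(
    donor_emission: Spectrum,
    acceptor_molar_absorptivity: Spectrum,
    f0: float,
    f: float,
    constants: FretConstants = FretConstants(),
) -> FretResult:
    """Full chain: J -> R0, (F0, F) -> E -> r."""
    j = overlap_integral(donor_emission, acceptor_molar_absorptivity)
    r0 = forster_radius(j, constants)
    e = transfer_efficiency(f0, f)
    r = donor_acceptor_distance(e, r0)
    return FretResult(j=j, e=e, r0=r0, r=r, constants=constants)
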