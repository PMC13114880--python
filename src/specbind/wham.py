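"""Umbrella-sampling analysis: WHAM, overlap diagnostics, bootstrap errors.

Each umbrella window i restrains the reaction coordinate z with a
harmonic bias w_i(z) = k_i/2 (z - z_i)^2.  The weighted histogram
analysis method (WHAM) recovers the unbiased distribution P(z) by
iterating the self-consistent pair

    P_j = (sum_i H_ij) / (sum_i N_i exp[-(w_i(z_j) - f_i)/kT])
    f_i = -kT ln sum_j P_j exp(-w_i(z_j)/kT)

to convergence on the window free energies f_i; the potential of mean
force is PMF_j = -kT ln P_j, shifted so its minimum is zero.  Samples
are treated as independent; per-sample weights support the Bayesian
(Dirichlet-weight) bootstrap used for the error band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ConvergenceError, InputError, SizeError

KB_KJ = 0.0083144621  # kJ / mol / K
KCAL_PER_KJ = 1.0 / 4.184
MIN_SAMPLES = 50


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased window: harmonic anchor (nm), force constant
    (kJ/mol/nm^2) and the reaction-coordinate samples (nm).

    A force constant of 0 denotes an unbiased window (plain Boltzmann
    sampling), for which WHAM reduces to histogram inversion.
    """

    center: float
    force_constant: float
    samples: np.ndarray

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.force_constant < 0:
            raise InputError("force_constant must be >= 0")
        if samples.size < MIN_SAMPLES:
            raise SizeError(f"window needs >= {MIN_SAMPLES} samples, got {samples.size}")


@dataclass(frozen=True)
class GridSpec:
    """Uniform PMF grid: [lo, hi] split into n_bins bins."""

    lo: float
    hi: float
    n_bins: int = 200

    def __post_init__(self):
        if self.hi <= self.lo or self.n_bins < 2:
            raise InputError("grid needs hi > lo and n_bins >= 2")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_bins


def default_grid(windows, n_bins: int = 200, pad_fraction: float = 0.02) -> GridSpec:
    """Grid spanning the pooled sample range, padded by 2% per side."""
    lo = min(float(w.samples.min()) for w in windows)
    hi = max(float(w.samples.max()) for w in windows)
    pad = (hi - lo) * pad_fraction
    return GridSpec(lo - pad, hi + pad, n_bins)


@dataclass(frozen=True)
class PmfProfile:
    """Free-energy profile on ``grid`` (bin centers, nm).

    free_energy is in kJ/mol, min-shifted to 0; unsampled bins are NaN.
    error_band holds per-bin 68%-interval half-widths when a bootstrap
    has been run.  barrier is the maximum free energy over bins at or
    beyond the bound-state minimum.
    """

    grid: np.ndarray
    free_energy: np.ndarray
    window_free_energies: np.ndarray
    overlap_matrix: np.ndarray
    temperature: float
    bin_width: float
    n_iterations: int
    barrier: float
    error_band: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def kT(self) -> float:
        return KB_KJ * self.temperature

    @property
    def barrier_kcal(self) -> float:
        return self.barrier * KCAL_PER_KJ


def _bias_matrix(windows, centers: np.ndarray) -> np.ndarray:
    """w_i(z_j) for every window i and bin center z_j (kJ/mol)."""
    c = np.array([w.center for w in windows])[:, None]
    k = np.array([w.force_constant for w in windows])[:, None]
    return 0.5 * k * (centers[None, :] - c) ** 2


def _weighted_counts(windows, grid: GridSpec, weights) -> tuple[np.ndarray, np.ndarray]:
    """Per-window histogram row sums H_j (pooled) and effective counts N_i."""
    h_total = np.zeros(grid.n_bins)
    n_eff = np.zeros(len(windows))
    edges = grid.edges
    for i, w in enumerate(windows):
        wt = None if weights is None else weights[i]
        inside = (w.samples >= grid.lo) & (w.samples <= grid.hi)
        if not inside.any():
            raise InputError(f"window at {w.center}: all samples outside the grid")
        h, _ = np.histogram(w.samples, bins=edges, weights=wt)
        h_total += h
        n_eff[i] = h.sum()
    return h_total, n_eff


def wham_solve(
    windows,
    grid: GridSpec | None = None,
    temperature_K: float = 300.0,
    tol: float = 1e-6,
    max_iter: int = 100000,
    weights=None,
) -> PmfProfile:
    """Self-consistent WHAM solution for a set of umbrella windows.

    ``tol`` is the convergence threshold on max |delta f_i| in kT units.
    ``weights`` (optional) is one non-negative weight array per window,
    enabling the weighted-histogram bootstrap.  Raises
    :class:`ConvergenceError` (with the f-change trace) if ``max_iter``
    is exhausted.
    """
    windows = list(windows)
    if not windows:
        raise InputError("need at least one window")
    if grid is None:
        grid = default_grid(windows)
    kT = KB_KJ * temperature_K
    centers = grid.centers
    h_j, n_i = _weighted_counts(windows, grid, weights)
    bias = _bias_matrix(windows, centers)  # (n_win, n_bins)
    neg_b_over_kt = -bias / kT
    log_n = np.log(np.where(n_i > 0, n_i, 1.0))
    sampled = h_j > 0
    log_h = np.where(sampled, np.log(np.where(sampled, h_j, 1.0)), -np.inf)

    f = np.zeros(len(windows))  # in kJ/mol
    trace = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # log denominator_j = logsumexp_i [ ln N_i + (f_i - w_ij)/kT ]
        log_denom = logsumexp(log_n[:, None] + (f[:, None] / kT) + neg_b_over_kt, axis=0)
        log_p = log_h - log_denom  # unnormalized
        f_new = -kT * logsumexp(log_p[None, :] + neg_b_over_kt, axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f))) / kT
        f = f_new
        trace.append(delta)
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (last |df| = {trace[-1]:.3g} kT)",
            trace=trace,
        )

    log_denom = logsumexp(log_n[:, None] + (f[:, None] / kT) + neg_b_over_kt, axis=0)
    log_p = log_h - log_denom
    pmf = np.where(sampled, -kT * log_p, np.nan)
    pmf -= np.nanmin(pmf)
    overlap = _adjacent_overlap(windows, grid)
    barrier = _barrier_from_profile(pmf)
    return PmfProfile(
        grid=centers,
        free_energy=pmf,
        window_free_energies=f,
        overlap_matrix=overlap,
        temperature=temperature_K,
        bin_width=grid.width,
        n_iterations=n_iter,
        barrier=barrier,
    )


def _adjacent_overlap(windows, grid: GridSpec) -> np.ndarray:
    order = np.argsort([w.center for w in windows])
    hists = []
    for idx in order:
        h, _ = np.histogram(windows[idx].samples, bins=grid.edges)
        s = h.sum()
        hists.append(h / s if s > 0 else h.astype(float))
    return np.array(
        [float(np.minimum(hists[i], hists[i + 1]).sum()) for i in range(len(hists) - 1)]
    )


def histogram_overlap(
    windows, grid: GridSpec | None = None, threshold: float = 0.05
) -> tuple[np.ndarray, list[str]]:
    """Overlap coefficient sum_j min(h_i, h_i+1) for adjacent windows.

    Windows are sorted by center; unit-normalized histograms on the
    common grid are compared.  Pairs below ``threshold`` produce a
    warning string (poor overlap invalidates WHAM stitching).
    """
    windows = sorted(windows, key=lambda w: w.center)
    if len(windows) < 2:
        raise InputError("need >= 2 windows for overlap diagnostics")
    if grid is None:
        grid = default_grid(windows)
    coeffs = _adjacent_overlap(windows, grid)
    notes = []
    for i, c in enumerate(coeffs):
        if c < threshold:
            notes.append(
                f"overlap {c:.3f} between windows at {windows[i].center:g} and "
                f"{windows[i + 1].center:g} nm is below {threshold:g}"
            )
    return coeffs, notes


def bootstrap_pmf(
    windows,
    grid: GridSpec | None = None,
    temperature_K: float = 300.0,
    n_boot: int = 50,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 100000,
) -> PmfProfile:
    """Bayesian-bootstrap error band for the WHAM profile.

    Each replicate reweights every window's samples with Dirichlet(1,...,1)
    weights (scaled to preserve the sample count) and re-solves WHAM; the
    error band is the per-bin half-width of the central 68% interval over
    replicates.  Deterministic under a fixed ``seed``.  Replicates that
    fail to converge are dropped with a warning.
    """
    windows = list(windows)
    if grid is None:
        grid = default_grid(windows)
    base = wham_solve(windows, grid, temperature_K, tol=tol, max_iter=max_iter)
    rng = np.random.default_rng(seed)
    profiles = []
    dropped = 0
    for _ in range(n_boot):
        weights = [
            rng.dirichlet(np.ones(w.samples.size)) * w.samples.size for w in windows
        ]
        try:
            rep = wham_solve(
                windows, grid, temperature_K, tol=tol, max_iter=max_iter, weights=weights
            )
        except ConvergenceError:
            dropped += 1
            continue
        profiles.append(rep.free_energy)
    if dropped:
        warnings.warn(f"{dropped} bootstrap replicate(s) did not converge", stacklevel=2)
    if not profiles:
        raise ConvergenceError("no bootstrap replicate converged")
    stack = np.vstack(profiles)
    if stack.shape[0] == 1:
        band = np.where(np.isfinite(stack[0]), 0.0, np.nan)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            hi = np.nanpercentile(stack, 84.0, axis=0)
            lo = np.nanpercentile(stack, 16.0, axis=0)
        band = (hi - lo) / 2.0
    meta = dict(base.meta)
    meta["n_boot"] = n_boot
    meta["n_dropped"] = dropped
    return PmfProfile(
        grid=base.grid,
        free_energy=base.free_energy,
        window_free_energies=base.window_free_energies,
        overlap_matrix=base.overlap_matrix,
        temperature=base.temperature,
        bin_width=base.bin_width,
        n_iterations=base.n_iterations,
        barrier=base.barrier,
        error_band=band,
        meta=meta,
    )


def _barrier_from_profile(free_energy: np.ndarray, min_index: int | None = None) -> float:
    if min_index is None:
        min_index = int(np.nanargmin(free_energy))
    beyond = free_energy[min_index:]
    if np.all(np.isnan(beyond)):
        raise InputError("all bins beyond the bound minimum are unsampled")
    return float(np.nanmax(beyond))


def pmf_barrier(
    profile: PmfProfile, bound_region: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Dissociation barrier: max PMF at/beyond the bound-state minimum.

    ``bound_region`` (nm) must contain the global minimum; defaults to
    the whole grid.  Returns (kJ/mol, kcal/mol).
    """
    fe = profile.free_energy
    gmin = int(np.nanargmin(fe))
    if bound_region is not None:
        lo, hi = bound_region
        if not (lo <= profile.grid[gmin] <= hi):
            raise InputError(
                f"global minimum at {profile.grid[gmin]:.3f} nm lies outside "
                f"bound_region {bound_region}"
            )
    barrier = _barrier_from_profile(fe, gmin)
    return barrier, barrier * KCAL_PER_KJ


# --------------------------------------------------------------------------
# window-file I/O: header (center_nm, k_kJ_mol_nm2), one sample per line
# --------------------------------------------------------------------------

def read_window(path) -> UmbrellaWindow:
    """Read one TSV window file: a header row then one sample per line."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise InputError(f"{path}: window file needs a header and samples")
    head = lines[0].replace(",", "\t").split("\t")
    try:
        center, k = float(head[0]), float(head[1])
    except (ValueError, IndexError):
        raise InputError(f"{path}: header must be 'center_nm<TAB>k_kJ_mol_nm2'")
    samples = np.array([float(v) for v in lines[1:]])
    return UmbrellaWindow(center=center, force_constant=k, samples=samples)


def write_window(window: UmbrellaWindow, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{window.center:.12g}\t{window.force_constant:.12g}\n")
        for s in window.samples:
            fh.write(f"{s:.12g}\n")
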