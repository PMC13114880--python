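# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Spectral handling and peaks

A `Spectrum` is a strictly increasing axis (nm or cm⁻¹) with
non-negative intensities; readers sniff comma/tab delimiters, skip one
header row and `#` comments, and reject duplicate axis values. Peak
positions are refined by a parabola through the discrete maximum and its
two neighbours — adequate sub-grid accuracy for smooth bands at
1–2.5 nm scan resolution without assuming a line shape. At an axis
boundary the grid point is reported unrefined. Equal maxima resolve to
the smallest axis value with a warning. "Red/blue shift" vocabulary is
used only on nm axes; on cm⁻¹ axes shifts are reported as signed numbers.

Excitation–emission matrices are masked around the first- and
second-order Rayleigh ridges (|λem−λex| and |λem−2λex| ≤ 15 nm by
default, the typical ridge width) before peak picking. Local maxima
below 5 % of the unmasked global maximum are discarded: the Gaussian
tails of a strong ridge leak past any finite mask and create sub-percent
wrinkles at the mask boundary that are not spectroscopic features.
Synchronous spectra are extracted along λem = λex + Δλ by linear
interpolation on the emission axis; Δλ = 15 nm targets tyrosine and
Δλ = 60 nm tryptophan microenvironments.

## Quenching and binding fits

All fits run on inner-filter-corrected intensities,
F_cor = F_obs·10^((A_ex+A_em)/2), with absorbances taken from the
titration manifest. F is read as the peak intensity inside the emission
window (matching intensity-at-peak reporting conventions); integrated
area is available as an option. Design choices:

- The Stern–Volmer intercept is left free; reporting R² implies an
  unconstrained fit. A clamped (intercept = 1) variant is a flag.
- The double-log fit uses base-10 logs; K_a = 10^intercept. Points with
  F ≥ F₀ or F ≤ 0 carry no information on the log scale and are excluded
  with a warning.
- [Q] is total added ligand; no free-ligand depletion correction. The
  synthetic module includes a mechanistic 1:1 depletion generator to
  quantify the resulting bias (a few percent at 2 µM protein with µM–tens
  of µM ligand).
- Mechanism call: K_SV strictly rising with temperature (criterion A)
  and every k_q above the 2×10¹⁰ L·mol⁻¹·s⁻¹ diffusion ceiling
  (criterion B). A∧B → mixed, B alone → static, A alone → dynamic,
  neither → indeterminate.
- Site competition: a probe competes when its displacement curve is
  monotone non-increasing (successive rises of up to 2 percentage points
  tolerated as noise) and ends more than 15 points below 100 %.

## Van't Hoff thermodynamics

One global OLS of ln K_a on 1/T across all temperatures: ΔH = −R·slope,
ΔS = R·intercept, with R = 8.314 J·mol⁻¹·K⁻¹ and standard errors from
the OLS covariance (no bootstrap — three points cannot support one).
ΔG(T) is reported from ΔH − TΔS; the −RT·ln K_a route is also emitted as
a consistency diagnostic. The force classification follows the
Ross–Subramanian sign rules; the (−, +) → electrostatic case is included
for completeness even where a study only discusses the two cases it
observed, and (+, −) is labelled indeterminate (it implies non-spontaneous
binding at all temperatures). A zero on one side adopts the partner's
sign.

## FRET

The discrete overlap integral J = ΣFελ⁴Δλ / ΣFΔλ is evaluated with λ in
cm so that the conventional prefactor 8.8×10⁻²⁵ in
R₀⁶ = 8.8×10⁻²⁵·K²·N⁻⁴·φ·J yields R₀ in cm (converted to nm). This
convention is validated by reproducing a published R₀ of 2.53 nm from
its own J = 1.21×10⁻¹⁴ cm³·L·mol⁻¹ — the printed unit is dimensionally
loose (cm³·M⁻¹ is meant) and the cm convention is the one that makes the
numbers cohere. Spectra are linearly interpolated onto the donor's grid
points inside the common support; there is no extrapolation, and
disjoint supports return J = 0 with a warning. Default constants:
K² = 2/3 (isotropic), N = 1.336, φ = 0.118 (tryptophan donor in aqueous
protein). Per-point Δλ from `np.gradient` keeps the sums exact on
non-uniform grids.

## Amide-I deconvolution

Two-point linear baseline through the 1600 and 1700 cm⁻¹ endpoints
(simplest defensible choice over a 100 cm⁻¹ window; negatives clipped
with a logged count). Candidate centers come from minima of the second
derivative of a Savitzky–Golay-smoothed signal (window 11 points, order
3), merged within 8 cm⁻¹. Components are Gaussian — the conventional
amide-I choice — fit by bounded trust-region least squares with centers
constrained to seed ± 4 cm⁻¹, heights ≥ 0 and widths in 3–15 cm⁻¹;
starts are deterministic so results are bit-for-bit reproducible.

Heavily overlapped shoulders (e.g. random coil at ~1645 cm⁻¹ under a
dominant helix band at ~1654 cm⁻¹) leave no separate curvature minimum
and are not identifiable with independent per-band widths at realistic
noise. The `deconvolve` convenience therefore (a) augments derivative
seeds with the canonical five-component set (1625, 1645, 1654, 1670,
1688 cm⁻¹) wherever no seed is nearby, and (b) ties all components to a
shared width — both standard constraints in amide-I curve fitting.
Assignment windows (β-sheet 1600–1640, coil 1640–1650, helix 1650–1660,
turn 1660–1680, antiparallel β 1680–1700) follow the common literature
convention and are overridable; fractions are class area over total
area and always sum to 1.

## WHAM

The solver iterates the standard pair — unbiased bin probability
P_j = ΣᵢH_ij / ΣᵢNᵢ·exp[−(wᵢ(z_j)−fᵢ)/kT] with harmonic bias
wᵢ(z) = k/2(z−zᵢ)², and fᵢ = −kT·ln Σ_j P_j·exp(−wᵢ(z_j)/kT) — in
log space (`logsumexp`) until max|Δfᵢ| < 10⁻⁶ kT, anchoring f₁ = 0.
PMF_j = −kT·ln P_j, min-shifted to zero; empty bins are NaN and excluded
from the barrier search. The default grid is 200 bins over the pooled
sample range padded 2 % per side; k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹ at
300 K by default. With a single unbiased window the iteration reduces
algebraically to histogram Boltzmann inversion, which the tests verify
to 1×10⁻¹⁰.

Samples are treated as independent. Error bands use the Bayesian
bootstrap: each replicate reweights every window's samples with
Dirichlet(1,…,1) weights (scaled to preserve counts), re-solves WHAM,
and the band is the per-bin half-width of the central 68 % interval;
fully deterministic under a fixed seed. Adjacent-window overlap is the
min-sum of unit-normalized histograms, flagged below 0.05. The barrier
is the maximum PMF over bins at or beyond the bound-state minimum,
reported in kJ/mol and kcal/mol (1 kcal = 4.184 kJ).

## Synthetic data: what it emulates, and what it does not

Every generator is deterministic under a fixed seed and returns a truth
sidecar sufficient to score its downstream stage.

- **Titrations** use F = F₀/(1 + K_a[Q]ⁿ), the form under which the
  double-log fit is exact, so recovery tests isolate fitting correctness
  from model mismatch; the emission peak red-shifts in proportion to the
  bound fraction, ligand absorbance attenuates the signal by
  10^−((A_ex+A_em)/2), and noise is multiplicative Gaussian. Defaults
  mirror a moderate-affinity albumin/flavonoid system at 298–310 K
  (K_a ≈ 3×10⁴ L/mol, n ≈ 1, tryptophan band at 340.6 nm, +4.8 nm shift
  at saturation, ligand concentrations 0–25 µM). Not emulated: detector
  nonlinearity, photobleaching, free-ligand depletion (available as the
  separate mechanistic variant), real band asymmetry.
- **Van't Hoff sets** invert the regression exactly: K_a(T) =
  exp(−ΔH/RT + ΔS/R).
- **FRET pairs** are Gaussian donor-emission / acceptor-absorptivity
  bands plus a 100×-finer-grid quadrature oracle for J; defaults sit at
  the 10⁻¹⁴ cm³·L·mol⁻¹ overlap scale of tryptophan/flavonoid pairs.
- **EEMs** are bivariate Gaussian peaks (defaults at 275/340 and
  230/340 nm, the aromatic-residue and peptide-backbone signatures of
  serum albumin) plus Gaussian Rayleigh ridges along λem = λex and 2λex.
- **Amide-I envelopes** are Gaussian sums with class areas proportional
  to the requested structure fractions on a linear baseline.
- **Umbrella windows** draw exact i.i.d. inverse-CDF samples from the
  biased Boltzmann density on a 4000-point grid. The default truth is a
  double well — a 15 kJ/mol-deep bound well at 0.3 nm, a crest at
  1.0 nm giving a 20 kJ/mol barrier above the bound minimum, a shallower
  well at 1.7 nm — covered by 30 windows with k = 1000 kJ·mol⁻¹·nm⁻²,
  the force constant of typical pulling protocols. 5000 draws per window
  emulate a 10 ns window written every 2 ps, with the first 20 %
  discarded the way equilibration segments are (a statistical no-op for
  i.i.d. draws, kept for interface fidelity). Not emulated:
  autocorrelation of real trajectories — so real-data error bars will be
  wider than the i.i.d. bootstrap suggests — nor any 2-D coordinate.

Because the generators share the estimators' functional forms, passing
recovery tests demonstrate correctness of the inference machinery, not
robustness to model misspecification on real spectra.

## Problem sizes and tolerances in the test suite

Noise-free recoveries assert 10⁻⁶ relative (titrations) or machine-level
(van't Hoff inversion, Boltzmann inversion). The stochastic recovery
suite uses 200 seeds at 1 % multiplicative noise and asserts median
K_SV/K_a/n within 5 %. WHAM recovery runs the 30-window double well at 5
seeds, asserting profile RMSE < 0.3 kT and barrier within 5 %; these
sizes keep the whole suite around a minute on one core while leaving the
statistical assertions comfortably powered. Amide-I recovery asserts
each class fraction within 3 percentage points at 0.2 % additive noise.

## Known limitations

- No multi-site or cooperative binding models; n is the empirical
  double-log slope, not a site count.
- The Stern–Volmer and double-log fits are unweighted OLS on means.
- No sphere-of-action or combined static+dynamic quantitative model —
  the mechanism call is qualitative.
- FRET assumes a single donor–acceptor pair with isotropic orientation;
  no lifetime-based efficiency.
- Amide-I analysis has no Fourier self-deconvolution and no amide-II/III
  support; fractions inherit the usual ambiguity of band assignment.
- WHAM is 1-D, harmonic-bias only; no MBAR-style reweighting to new
  Hamiltonians and no work-based (Jarzynski) estimators.
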