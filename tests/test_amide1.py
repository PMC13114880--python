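import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specbind import errors
from specbind.amide1 import (
    BandComponent,
    Structure,
    assign_band,
    baseline_correct,
    deconvolve,
    fit_bands,
    seed_bands,
    structure_fractions,
)
from specbind.spectra import Spectrum
from specbind.synthetic import gen_amide1

FOUR_CLASS = {"alpha_helix": 0.55, "beta_sheet": 0.20, "beta_turn": 0.15,
              "random_coil": 0.10}


class TestBaseline:
    def test_zero_endpoints_leave_interior_unchanged(self):
        axis = np.arange(1580.0, 1721.0, 1.0)
        y = 2.0 * np.exp(-0.5 * ((axis - 1650) / 8) ** 2)
        spec = Spectrum(axis, y, "ftir")
        out = baseline_correct(spec)
        inner = (out.axis > 1600) & (out.axis < 1700)
        # endpoints carry ~7e-9 Gaussian tail, so the subtracted line is
        # not exactly zero; interior agreement is to that tail magnitude
        assert np.allclose(out.intensity[inner],
                           2.0 * np.exp(-0.5 * ((out.axis[inner] - 1650) / 8) ** 2),
                           atol=2e-8)

    def test_linear_ramp_maps_to_zero(self):
        axis = np.arange(1580.0, 1721.0, 1.0)
        spec = Spectrum(axis, 0.1 + 0.002 * (axis - 1580), "ftir")
        out = baseline_correct(spec)
        assert np.allclose(out.intensity, 0.0, atol=1e-12)

    def test_gaussian_on_ramp_recovered(self):
        axis = np.arange(1580.0, 1721.0, 0.5)
        gauss = 1.5 * np.exp(-0.5 * ((axis - 1652) / 7) ** 2)
        spec = Spectrum(axis, gauss + 0.3 + 0.001 * (axis - 1580), "ftir")
        out = baseline_correct(spec)
        true_area = 1.5 * 7 * np.sqrt(2 * np.pi)
        got_area = np.trapezoid(out.intensity, out.axis)
        assert got_area == pytest.approx(true_area, rel=0.01)

    def test_region_outside_axis_rejected(self):
        axis = np.arange(1620.0, 1680.0, 1.0)
        with pytest.raises(errors.RangeError):
            baseline_correct(Spectrum(axis, np.ones_like(axis), "ftir"))


class TestSeedBands:
    def test_single_band_seeded_within_one_wavenumber(self):
        spec, _ = gen_amide1({"alpha_helix": 1.0})
        seeds = seed_bands(baseline_correct(spec))
        assert len(seeds) == 1
        assert seeds[0] == pytest.approx(1654.0, abs=1.0)

    def test_two_separated_bands_seeded(self):
        spec, _ = gen_amide1({"beta_sheet": 0.5, "beta_turn": 0.5},
                             centers={"beta_sheet": 1625.0, "beta_turn": 1675.0})
        seeds = seed_bands(baseline_correct(spec))
        assert len(seeds) == 2
        assert seeds[0] == pytest.approx(1625.0, abs=1.5)
        assert seeds[1] == pytest.approx(1675.0, abs=1.5)

    def test_flat_signal_raises(self):
        axis = np.arange(1580.0, 1721.0, 1.0)
        with pytest.raises(errors.SeedError):
            seed_bands(Spectrum(axis, np.full(axis.size, 0.0), "ftir"))


class TestFitBands:
    def test_single_exact_gaussian_recovered(self):
        axis = np.arange(1600.0, 1701.0, 1.0)
        true = BandComponent(center=1652.0, height=1.2, sigma=8.0,
                             assignment=Structure.alpha_helix)
        y = true.height * np.exp(-0.5 * ((axis - true.center) / true.sigma) ** 2)
        fit = fit_bands(Spectrum(axis, y, "ftir"), seeds=[1653.0])
        band = fit.components[0]
        assert band.center == pytest.approx(true.center, rel=1e-6)
        assert band.height == pytest.approx(true.height, rel=1e-6)
        assert band.sigma == pytest.approx(true.sigma, rel=1e-6)
        assert band.area == pytest.approx(true.area, rel=1e-6)

    def test_four_band_envelope_areas_within_five_percent(self):
        # resolvable 4-Gaussian envelope with 1% multiplicative noise
        rng = np.random.default_rng(11)
        axis = np.arange(1600.0, 1701.0, 1.0)
        truth = [(1620.0, 0.6, 6.0), (1645.0, 0.4, 5.0),
                 (1668.0, 0.9, 7.0), (1690.0, 0.3, 5.0)]
        y = sum(h * np.exp(-0.5 * ((axis - c) / s) ** 2) for c, h, s in truth)
        y = y * (1.0 + 0.01 * rng.standard_normal(axis.size))
        fit = fit_bands(Spectrum(axis, np.clip(y, 0, None), "ftir"),
                        seeds=[c for c, _, _ in truth])
        assert len(fit.components) == 4
        for band, (c, h, s) in zip(fit.components, truth):
            assert band.area == pytest.approx(h * s * np.sqrt(2 * np.pi), rel=0.05)

    def test_overlapping_pair_conserves_combined_area(self):
        axis = np.arange(1600.0, 1701.0, 0.5)
        y = (1.0 * np.exp(-0.5 * ((axis - 1650) / 6) ** 2)
             + 0.8 * np.exp(-0.5 * ((axis - 1660) / 6) ** 2))
        fit = fit_bands(Spectrum(axis, y, "ftir"), seeds=[1650.0, 1660.0])
        total_true = (1.0 * 6 + 0.8 * 6) * np.sqrt(2 * np.pi)
        assert sum(b.area for b in fit.components) == pytest.approx(total_true, rel=0.02)

    def test_total_area_matches_trapezoid_of_signal(self):
        spec, _ = gen_amide1(FOUR_CLASS, noise_sigma=0.0)
        corrected = baseline_correct(spec)
        fit = fit_bands(corrected, seed_bands(corrected))
        trap = np.trapezoid(corrected.intensity, corrected.axis)
        assert sum(b.area for b in fit.components) == pytest.approx(trap, rel=0.03)

    def test_reproducible_bit_for_bit(self):
        spec, _ = gen_amide1(FOUR_CLASS, noise_sigma=0.002, seed=3)
        fit1, _ = deconvolve(spec)
        fit2, _ = deconvolve(spec)
        assert [(b.center, b.height, b.sigma) for b in fit1.components] == [
            (b.center, b.height, b.sigma) for b in fit2.components
        ]

    def test_needs_at_least_one_seed(self):
        spec, _ = gen_amide1({"alpha_helix": 1.0})
        with pytest.raises(errors.InputError):
            fit_bands(baseline_correct(spec), seeds=[])


class TestStructureFractions:
    def test_single_band_is_pure_class(self):
        band = BandComponent(center=1654.0, height=1.0, sigma=7.0,
                             assignment=Structure.alpha_helix)
        fracs = structure_fractions([band])
        assert fracs[Structure.alpha_helix] == 1.0

    def test_equal_areas_split_evenly(self):
        bands = [
            BandComponent(center=1625.0, height=1.0, sigma=7.0,
                          assignment=Structure.beta_sheet),
            BandComponent(center=1672.0, height=1.0, sigma=7.0,
                          assignment=Structure.beta_turn),
        ]
        fracs = structure_fractions(bands)
        assert fracs[Structure.beta_sheet] == pytest.approx(0.5)
        assert fracs[Structure.beta_turn] == pytest.approx(0.5)

    def test_four_class_mixture_recovered_within_three_points(self):
        spec, _ = gen_amide1(FOUR_CLASS, noise_sigma=0.002, seed=7)
        _, fracs = deconvolve(spec)
        for cls, truth in FOUR_CLASS.items():
            assert abs(fracs[Structure(cls)] - truth) < 0.03

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(
        st.tuples(st.floats(min_value=1601, max_value=1699),
                  st.floats(min_value=0.1, max_value=5.0),
                  st.floats(min_value=3.0, max_value=15.0)),
        min_size=1, max_size=6,
    ))
    def test_fractions_always_sum_to_one(self, specs):
        bands = [BandComponent(center=c, height=h, sigma=s,
                               assignment=assign_band(c)) for c, h, s in specs]
        fracs = structure_fractions(bands)
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in fracs.values())

    def test_assignment_is_pure_function_of_center(self):
        assert assign_band(1625.0) is Structure.beta_sheet
        assert assign_band(1645.0) is Structure.random_coil
        assert assign_band(1654.0) is Structure.alpha_helix
        assert assign_band(1670.0) is Structure.beta_turn
        assert assign_band(1688.0) is Structure.antiparallel_beta
        assert assign_band(1700.0) is Structure.antiparallel_beta

    def test_center_outside_region_rejected(self):
        with pytest.raises(errors.AssignmentError):
            assign_band(1590.0)

    def test_helix_loss_sheet_gain_ordering_between_paired_spectra(self):
        # free-protein vs complex envelopes built with helix down, sheet up
        free_spec, _ = gen_amide1(
            {"alpha_helix": 0.55, "beta_sheet": 0.15, "beta_turn": 0.20,
             "random_coil": 0.10}, noise_sigma=0.002, seed=21)
        bound_spec, _ = gen_amide1(
            {"alpha_helix": 0.45, "beta_sheet": 0.22, "beta_turn": 0.15,
             "random_coil": 0.18}, noise_sigma=0.002, seed=22)
        _, free = deconvolve(free_spec)
        _, bound = deconvolve(bound_spec)
        assert bound[Structure.alpha_helix] < free[Structure.alpha_helix]
        assert bound[Structure.beta_turn] < free[Structure.beta_turn]
        assert bound[Structure.beta_sheet] > free[Structure.beta_sheet]
        assert bound[Structure.random_coil] > free[Structure.random_coil]
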