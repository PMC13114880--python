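import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specbind import errors
from specbind.binding import (
    DisplacementCurve,
    Mechanism,
    QuenchConfig,
    QuenchFit,
    TitrationSeries,
    assign_site,
    classify_mechanism,
    correct_inner_filter,
    double_log_fit,
    probe_displacement,
    stern_volmer_fit,
)
from specbind.spectra import Spectrum


def make_series(q_concs, peak_intensities, temperature=298.0, center=340.0, sigma=20.0):
    axis = np.arange(280.0, 420.0 + 1e-9, 0.5)
    pts = [
        (q, Spectrum(axis, f * np.exp(-0.5 * ((axis - center) / sigma) ** 2)))
        for q, f in zip(q_concs, peak_intensities)
    ]
    return TitrationSeries(points=tuple(pts), temperature=temperature)


def two_point_line(x, y):
    """Independent closed-form OLS check using only the first/last points of
    exactly linear data."""
    slope = (y[-1] - y[0]) / (x[-1] - x[0])
    return slope, y[0] - slope * x[0]


class TestInnerFilter:
    @pytest.mark.parametrize(
        "f_obs, a_ex, a_em, expected",
        [
            (100.0, 0.0, 0.0, 100.0),
            (100.0, 1.0, 1.0, 1000.0),
            (250.0, 0.08, 0.04, 287.0384053742207),
        ],
    )
    def test_correction_values(self, f_obs, a_ex, a_em, expected):
        assert correct_inner_filter(f_obs, a_ex, a_em) == pytest.approx(expected, rel=1e-12)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(errors.DomainError):
            correct_inner_filter(100.0, -0.1, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        f=st.floats(min_value=0, max_value=1e6),
        a1=st.floats(min_value=0, max_value=2),
        a2=st.floats(min_value=0, max_value=2),
        bump=st.floats(min_value=1e-6, max_value=1),
    )
    def test_monotone_and_never_below_observed(self, f, a1, a2, bump):
        base = correct_inner_filter(f, a1, a2)
        assert base >= f
        assert correct_inner_filter(f, a1 + bump, a2) >= base
        assert correct_inner_filter(f, a1, a2 + bump) >= base

    def test_vectorized_over_series(self):
        out = correct_inner_filter([100.0, 100.0], [0.0, 1.0], [0.0, 1.0])
        assert np.allclose(out, [100.0, 1000.0])


class TestSternVolmer:
    def test_exact_linear_data_recovered(self):
        ksv = 2.0e4
        q = np.linspace(0, 2.5e-5, 6)
        series = make_series(q, 1000.0 / (1 + ksv * q))
        fit = stern_volmer_fit(series)
        assert fit.ksv == pytest.approx(ksv, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        slope, intercept = two_point_line(*map(np.array, zip(*fit.points)))
        assert fit.ksv == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)

    def test_kq_is_ksv_over_tau0(self):
        # the tabulated identity: Ksv = 1.63e4 L/mol with tau0 = 1e-8 s
        q = np.linspace(0, 2.5e-5, 6)
        series = make_series(q, 1000.0 / (1 + 1.63e4 * q))
        fit = stern_volmer_fit(series, QuenchConfig(tau0=1e-8))
        assert fit.kq == pytest.approx(1.63e12, rel=1e-9)

    def test_constant_intensity_flags_no_quenching(self):
        series = make_series(np.linspace(0, 1e-5, 5), np.full(5, 800.0))
        with pytest.warns(UserWarning, match="no quenching"):
            fit = stern_volmer_fit(series)
        assert fit.no_quenching
        assert fit.ksv == pytest.approx(0.0, abs=1e-9)

    def test_clamped_intercept_variant(self):
        ksv = 1.5e4
        q = np.linspace(0, 2e-5, 6)
        series = make_series(q, 900.0 / (1 + ksv * q))
        fit = stern_volmer_fit(series, clamp_intercept=True)
        assert fit.intercept == 1.0
        assert fit.ksv == pytest.approx(ksv, rel=1e-9)

    def test_needs_three_nonzero_points(self):
        series = make_series([0.0, 1e-6, 2e-6], [100.0, 90.0, 80.0])
        with pytest.raises(errors.SizeError):
            stern_volmer_fit(series)


class TestMechanism:
    def _fit(self, ksv, T, tau0=1e-8):
        return QuenchFit(ksv=ksv, kq=ksv / tau0, intercept=1.0, r_squared=0.99,
                         points=(), temperature=T)

    def test_rising_ksv_and_super_diffusion_kq_is_mixed(self):
        fits = [self._fit(k, t) for k, t in
                zip((1.63e4, 1.75e4, 1.95e4), (298, 304, 310))]
        call = classify_mechanism(fits)
        assert call.label is Mechanism.mixed
        assert "Ksv strictly increasing" in call.evidence

    def test_falling_ksv_with_high_kq_is_static(self):
        fits = [self._fit(k, t) for k, t in zip((2e4, 1.5e4), (298, 310))]
        assert classify_mechanism(fits).label is Mechanism.static

    def test_rising_ksv_with_low_kq_is_dynamic(self):
        fits = [QuenchFit(ksv=k, kq=5e9, intercept=1, r_squared=1, points=(),
                          temperature=t) for k, t in zip((1e2, 2e2), (298, 310))]
        assert classify_mechanism(fits).label is Mechanism.dynamic

    def test_falling_ksv_with_low_kq_is_indeterminate(self):
        fits = [QuenchFit(ksv=k, kq=5e9, intercept=1, r_squared=1, points=(),
                          temperature=t) for k, t in zip((2e2, 1e2), (298, 310))]
        assert classify_mechanism(fits).label is Mechanism.indeterminate

    def test_unsorted_temperatures_rejected(self):
        fits = [self._fit(1e4, 310), self._fit(2e4, 298)]
        with pytest.raises(errors.InputError):
            classify_mechanism(fits)

    def test_pure_function_of_inputs(self):
        fits = [self._fit(k, t) for k, t in zip((1.0e4, 1.2e4), (298, 310))]
        assert classify_mechanism(fits) == classify_mechanism(list(fits))


class TestDoubleLog:
    @pytest.mark.parametrize("ka, n", [(3.22e4, 1.0), (0.27e4, 0.82)])
    def test_noiseless_recovery(self, ka, n):
        q = np.linspace(0, 2.5e-5, 9)
        f = 1000.0 / (1 + np.where(q > 0, ka * q**n, 0.0))
        fit = double_log_fit(make_series(q, f))
        assert fit.ka == pytest.approx(ka, rel=1e-6)
        assert fit.n == pytest.approx(n, rel=1e-6)
        slope, intercept = two_point_line(*map(np.array, zip(*fit.points)))
        assert fit.n == pytest.approx(slope, rel=1e-9)
        assert fit.ka == pytest.approx(10**intercept, rel=1e-9)

    def test_half_saturation_identity(self):
        # F = F0/2 at [Q] = 1/Ka for n = 1, i.e. the fit line crosses 0 at -log Ka
        ka = 5.0e4
        q = np.array([0.0, 0.5 / ka, 1.0 / ka, 2.0 / ka])
        f = 1000.0 / (1 + ka * q)
        fit = double_log_fit(make_series(q, f))
        xs, ys = map(np.array, zip(*fit.points))
        i = int(np.argmin(np.abs(xs - np.log10(1 / ka))))
        assert xs[i] == pytest.approx(np.log10(1 / ka), abs=1e-12)
        assert ys[i] == pytest.approx(0.0, abs=1e-9)

    def test_unquenched_points_excluded_with_warning(self):
        q = np.array([0.0, 1e-6, 2e-6, 4e-6, 8e-6, 1.6e-5])
        f = 1000.0 / (1 + 3e4 * q)
        f[1] = 1000.0  # F == F0 carries no information
        with pytest.warns(UserWarning, match="excluding"):
            fit = double_log_fit(make_series(q, f))
        assert len(fit.points) == 4

    def test_too_few_surviving_points_raise(self):
        q = np.array([0.0, 1e-6, 2e-6, 4e-6])
        f = np.array([1000.0, 1000.0, 1000.0, 900.0])
        with pytest.warns(UserWarning):
            with pytest.raises(errors.DataError):
                double_log_fit(make_series(q, f))


class TestProbeDisplacement:
    @pytest.mark.parametrize("f1, f2, expected", [(500, 500, 100.0),
                                                  (500, 250, 50.0),
                                                  (500, 0, 0.0)])
    def test_values(self, f1, f2, expected):
        assert probe_displacement(f1, f2) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(errors.DomainError):
            probe_displacement(0.0, 10.0)


class TestAssignSite:
    @staticmethod
    def _curve(probe, values):
        concs = np.linspace(2e-6, 10e-6, len(values))
        return DisplacementCurve(probe=probe, points=tuple(zip(concs, values)))

    def test_warfarin_drop_assigns_site_one(self):
        curves = [
            self._curve("warfarin_siteI", [95.0, 88.0, 80.0, 74.0, 70.0]),
            self._curve("ibuprofen_siteII", [100.0, 99.5, 100.2, 99.8, 100.1]),
            self._curve("digitoxin_siteIII", [99.0, 99.4, 98.8, 99.2, 99.0]),
        ]
        result = assign_site(curves)
        assert result.site == "I"
        assert result.verdicts["warfarin_siteI"]["competes"]
        assert not result.verdicts["ibuprofen_siteII"]["competes"]

    def test_all_flat_gives_none(self):
        curves = [self._curve(p, [100.0, 99.8, 100.1]) for p in
                  ("warfarin_siteI", "ibuprofen_siteII", "digitoxin_siteIII")]
        assert assign_site(curves).site == "none"

    def test_two_droppers_is_ambiguous(self):
        curves = [
            self._curve("warfarin_siteI", [90.0, 80.0, 70.0]),
            self._curve("ibuprofen_siteII", [92.0, 81.0, 72.0]),
        ]
        assert assign_site(curves).site == "ambiguous"

    def test_duplicate_probe_rejected(self):
        curves = [self._curve("warfarin_siteI", [90.0, 80.0, 70.0])] * 2
        with pytest.raises(errors.InputError):
            assign_site(curves)

    def test_nonmonotone_dropper_does_not_compete(self):
        curves = [
            self._curve("warfarin_siteI", [95.0, 70.0, 99.0, 75.0, 60.0]),
            self._curve("ibuprofen_siteII", [100.0, 99.9, 99.8, 100.0, 99.7]),
        ]
        assert assign_site(curves).site == "none"
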