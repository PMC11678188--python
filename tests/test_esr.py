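"""ESR stage: lineshape metrics, component fitting, two-component
decomposition, population series, model selection, order parameter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import simpson

from memtherm.esr import (EsrSpectrum, OrderingPotential,
                          build_population_series, decompose_two_components,
                          fit_single_component, lineshape_metrics,
                          model_selection, order_parameter)
from memtherm.synthetic import (NitroxideComponentModel,
                                generate_nitroxide_spectrum,
                                nitroxide_component_trace)

NARROW = NitroxideComponentModel(3350.0, 15.2, (1.6, 1.6, 2.2),
                                 gauss_fraction=0.2)
BROAD = NitroxideComponentModel(3350.0, 28.0, (5.0, 5.0, 7.0),
                                gauss_fraction=0.3)


def _mix(p_ord, field, noise_sd=0.0, rng=None):
    from memtherm.esr import _area_normalized
    bo = _area_normalized(field, nitroxide_component_trace(BROAD, field))
    bd = _area_normalized(field, nitroxide_component_trace(NARROW, field))
    y = p_ord * bo + (1.0 - p_ord) * bd
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd * np.abs(y).max(), field.shape)
    return EsrSpectrum(field, y, temperature_C=25.0)


class TestLineshapeMetrics:
    def test_narrow_line_splitting(self):
        grid = np.linspace(3280.0, 3420.0, 8001)
        s = generate_nitroxide_spectrum(
            NitroxideComponentModel(3350.0, 17.0, (0.5, 0.5, 0.5),
                                    gauss_fraction=1.0), grid)
        m = lineshape_metrics(s)
        assert m.two_Amax == pytest.approx(34.0, abs=0.6)
        assert m.central_crossing == pytest.approx(3350.0, abs=0.02)

    def test_central_width_matches_parameter(self):
        grid = np.linspace(3280.0, 3420.0, 8001)
        w = 2.4
        s = generate_nitroxide_spectrum(
            NitroxideComponentModel(3350.0, 17.0, (1.0, w, 1.0)), grid)
        m = lineshape_metrics(s)
        assert m.dH0 == pytest.approx(w, abs=2 * (grid[1] - grid[0]))

    def test_translation_invariance(self, field_grid):
        s = generate_nitroxide_spectrum(NARROW, field_grid)
        shifted = EsrSpectrum(field_grid + 5.0, s.intensity)
        m0, m1 = lineshape_metrics(s), lineshape_metrics(shifted)
        assert m1.two_Amax == pytest.approx(m0.two_Amax, abs=1e-9)
        assert m1.dH0 == pytest.approx(m0.dH0, abs=1e-9)
        assert m1.central_crossing == pytest.approx(
            m0.central_crossing + 5.0, abs=1e-9)

    def test_no_central_crossing_rejected(self, field_grid):
        y = np.ones_like(field_grid)
        with pytest.raises(ValueError):
            lineshape_metrics(EsrSpectrum(field_grid, y))


class TestSingleComponentFit:
    def test_fixed_point_on_own_spectrum(self, field_grid):
        s = generate_nitroxide_spectrum(NARROW, field_grid)
        fit = fit_single_component(s, NARROW)
        assert fit.residual_rms < 1e-9 * np.abs(s.intensity).max()
        assert fit.model.hyperfine_A == pytest.approx(15.2, rel=1e-6)
        assert fit.model.center_field == pytest.approx(3350.0, rel=1e-6)

    def test_mixture_fits_worse_than_two_components(self, field_grid):
        s = _mix(0.5, field_grid)
        bo = generate_nitroxide_spectrum(BROAD, field_grid)
        bd = generate_nitroxide_spectrum(NARROW, field_grid)
        fit1 = fit_single_component(s, NARROW)
        _, _, rms2 = decompose_two_components(s, bo, bd)
        assert fit1.residual_rms > rms2

    def test_pure_noise_flagged_or_null(self, field_grid):
        rng = np.random.default_rng(0)
        s = EsrSpectrum(field_grid, rng.normal(0, 1.0, field_grid.shape))
        fit = fit_single_component(s, NARROW)
        # no three-line signal: either non-convergent or negligible amplitude
        scale = np.abs(nitroxide_component_trace(NARROW, field_grid)).max()
        amp_scale = abs(fit.model.amplitude) * scale
        assert (not fit.success) or amp_scale < 10 * fit.residual_rms


class TestDecomposition:
    def test_exact_recovery_noiseless(self, field_grid):
        s = _mix(0.30, field_grid)
        bo = generate_nitroxide_spectrum(BROAD, field_grid)
        bd = generate_nitroxide_spectrum(NARROW, field_grid)
        po, pd_, rms = decompose_two_components(s, bo, bd)
        assert po == pytest.approx(0.30, abs=1e-6)
        assert pd_ == pytest.approx(0.70, abs=1e-6)
        assert rms < 1e-12

    def test_pure_component_is_identified(self, field_grid):
        bo = generate_nitroxide_spectrum(BROAD, field_grid)
        bd = generate_nitroxide_spectrum(NARROW, field_grid)
        po, pd_, _ = decompose_two_components(bo, bo, bd)
        assert po == pytest.approx(1.0, abs=1e-9)
        assert pd_ == pytest.approx(0.0, abs=1e-9)

    def test_weights_invariant_to_basis_rescaling(self, field_grid):
        s = _mix(0.42, field_grid)
        bo = generate_nitroxide_spectrum(BROAD, field_grid)
        bd = generate_nitroxide_spectrum(NARROW, field_grid)
        bo5 = EsrSpectrum(field_grid, 5.0 * bo.intensity)
        bd03 = EsrSpectrum(field_grid, 0.3 * bd.intensity)
        p1 = decompose_two_components(s, bo, bd)[0]
        p2 = decompose_two_components(s, bo5, bd03)[0]
        assert p2 == pytest.approx(p1, abs=1e-9)

    def test_collinear_bases_rejected(self, field_grid):
        bo = generate_nitroxide_spectrum(NARROW, field_grid)
        bd = EsrSpectrum(field_grid, 2.0 * bo.intensity)
        with pytest.raises(ValueError, match="collinear"):
            decompose_two_components(_mix(0.5, field_grid), bo, bd)

    def test_shift_alignment_recovers_offset_mixture(self, field_grid):
        s = _mix(0.30, field_grid)
        shifted = EsrSpectrum(field_grid, np.interp(
            field_grid - 0.8, field_grid, s.intensity))
        bo = generate_nitroxide_spectrum(BROAD, field_grid)
        bd = generate_nitroxide_spectrum(NARROW, field_grid)
        po, _, _ = decompose_two_components(shifted, bo, bd,
                                            allow_shift=True)
        assert po == pytest.approx(0.30, abs=0.01)

    def test_monte_carlo_recovery_at_snr50(self, field_grid):
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(200):
            p = rng.uniform(0.0, 1.0)
            s = _mix(p, field_grid, noise_sd=0.02, rng=rng)
            bo = generate_nitroxide_spectrum(BROAD, field_grid)
            bd = generate_nitroxide_spectrum(NARROW, field_grid)
            po, _, _ = decompose_two_components(s, bo, bd)
            errs.append(abs(po - p))
        assert np.mean(np.asarray(errs) <= 0.02) >= 0.95


class TestModelSelection:
    def test_equal_residuals_prefer_one(self):
        assert model_selection(0.5, 0.5, 1000) is False

    def test_worse_two_component_prefer_one(self):
        assert model_selection(0.5, 0.6, 1000) is False

    def test_mixture_at_snr50_prefers_two(self, field_grid):
        rng = np.random.default_rng(5)
        from memtherm.esr import _area_normalized, _best_single_basis
        bo = _area_normalized(field_grid,
                              nitroxide_component_trace(BROAD, field_grid))
        bd = _area_normalized(field_grid,
                              nitroxide_component_trace(NARROW, field_grid))
        s = _mix(0.5, field_grid, noise_sd=0.02, rng=rng)
        rms1, _ = _best_single_basis(s.intensity, bo, bd)
        bo_s = generate_nitroxide_spectrum(BROAD, field_grid)
        bd_s = generate_nitroxide_spectrum(NARROW, field_grid)
        _, _, rms2 = decompose_two_components(s, bo_s, bd_s)
        assert model_selection(rms1, rms2, field_grid.size) is True

    def test_type_one_error_rate_on_pure_component(self, field_grid):
        rng = np.random.default_rng(17)
        from memtherm.esr import _area_normalized, _best_single_basis
        bo = _area_normalized(field_grid,
                              nitroxide_component_trace(BROAD, field_grid))
        bd = _area_normalized(field_grid,
                              nitroxide_component_trace(NARROW, field_grid))
        bo_s = generate_nitroxide_spectrum(BROAD, field_grid)
        bd_s = generate_nitroxide_spectrum(NARROW, field_grid)
        false_pos = 0
        n_rep = 200
        for _ in range(n_rep):
            clean = bd  # pure disordered
            y = clean + rng.normal(0, 0.02 * np.abs(clean).max(),
                                   field_grid.shape)
            s = EsrSpectrum(field_grid, y)
            rms1, _ = _best_single_basis(y, bo, bd)
            _, _, rms2 = decompose_two_components(s, bo_s, bd_s)
            if model_selection(rms1, rms2, field_grid.size):
                false_pos += 1
        assert false_pos / n_rep <= 0.05


class TestPopulationSeries:
    def test_roundtrip_with_supplied_bases(self, noiseless_series):
        _, spectra, truth, bases = noiseless_series
        series = build_population_series(spectra, basis_strategy="supplied",
                                         bases=bases)
        assert np.allclose(series.P_disordered, truth.P_disordered,
                           atol=1e-4)

    def test_constant_spectra_give_constant_population(self, field_grid):
        bo = generate_nitroxide_spectrum(BROAD, field_grid)
        bd = generate_nitroxide_spectrum(NARROW, field_grid)
        spectra = [EsrSpectrum(field_grid, _mix(0.4, field_grid).intensity,
                               temperature_C=20.0 + k) for k in range(6)]
        series = build_population_series(spectra, basis_strategy="supplied",
                                         bases=(bo, bd))
        assert np.allclose(series.P_ordered, series.P_ordered[0])

    def test_shuffled_input_order_invariant(self, noiseless_series):
        _, spectra, _, bases = noiseless_series
        rng = np.random.default_rng(2)
        shuffled = [spectra[i] for i in rng.permutation(len(spectra))]
        a = build_population_series(spectra, "supplied", bases=bases)
        b = build_population_series(shuffled, "supplied", bases=bases)
        assert np.array_equal(a.temperature_K, b.temperature_K)
        assert np.allclose(a.P_ordered, b.P_ordered)

    def test_endpoint_strategy_on_wide_series(self, field_grid):
        # series reaching purity at both ends: endpoints are valid bases
        fracs = [0.0, 0.02, 0.25, 0.5, 0.75, 0.98, 1.0]
        spectra = [EsrSpectrum(field_grid,
                               _mix(1.0 - f, field_grid).intensity,
                               temperature_C=15.0 + 5 * k)
                   for k, f in enumerate(fracs)]
        series = build_population_series(spectra, "endpoints",
                                         use_model_selection=False)
        assert np.allclose(series.P_disordered, fracs, atol=1e-6)

    def test_too_few_spectra_rejected(self, field_grid):
        spectra = [EsrSpectrum(field_grid, _mix(0.5, field_grid).intensity,
                               temperature_C=20.0 + k) for k in range(4)]
        with pytest.raises(ValueError):
            build_population_series(spectra)


class TestOrderParameter:
    def _simpson_oracle(self, c20, n=20001):
        x = np.linspace(-1.0, 1.0, n)
        p2 = 0.5 * (3 * x ** 2 - 1)
        w = np.exp(c20 * p2 - c20 * np.abs(p2).max())
        return simpson(p2 * w, x=x) / simpson(w, x=x)

    def test_isotropic_is_zero(self):
        assert order_parameter(OrderingPotential(0.0)) == pytest.approx(
            0.0, abs=1e-14)

    @pytest.mark.parametrize("c20", [-5.0, -1.0, 0.5, 2.0, 8.0])
    def test_matches_independent_simpson_quadrature(self, c20):
        S = order_parameter(OrderingPotential(c20))
        assert S == pytest.approx(self._simpson_oracle(c20), abs=1e-8)

    def test_strictly_increasing_in_c20_and_bounded(self):
        cs = np.linspace(-10, 10, 41)
        Ss = [order_parameter(OrderingPotential(c)) for c in cs]
        assert np.all(np.diff(Ss) > 0)
        assert all(-0.5 < s < 1.0 for s in Ss)

    def test_node_doubling_converged(self):
        for c20 in (-10.0, -2.0, 3.0, 10.0):
            s1 = order_parameter(OrderingPotential(c20), 256)
            s2 = order_parameter(OrderingPotential(c20), 512)
            assert abs(s1 - s2) < 1e-8

    def test_biaxial_term_lowers_uniaxial_order(self):
        s_uni = order_parameter(OrderingPotential(2.0))
        s_bi = order_parameter(OrderingPotential(2.0, c22=1.0))
        assert s_bi != pytest.approx(s_uni, abs=1e-6)
        # phi average of the c22 term vanishes to first order, effect small
        assert abs(s_bi - s_uni) < 0.2

    def test_rank4_terms_accepted(self):
        s = order_parameter(OrderingPotential(2.0, c40=0.5))
        assert -0.5 < s < 1.0

    def test_nonfinite_potential_rejected(self):
        with pytest.raises(ValueError):
            OrderingPotential(np.nan)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(c=st.floats(-10.0, 10.0), dc=st.floats(1e-3, 2.0))
    def test_property_monotone_and_bounded(self, c, dc):
        s1 = order_parameter(OrderingPotential(c))
        s2 = order_parameter(OrderingPotential(c + dc))
        assert -0.5 < s1 < 1.0
        assert s2 > s1
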