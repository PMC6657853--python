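"""Flux laws, derived rates, and the dark steady state."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import conesim as cs
import conesim.params as bp


class TestEtaAndBeta:
    @pytest.mark.parametrize("nu,eps0,expected", [
        (1.0, 15.0, 7.5),      # printed volume-to-surface ratio, nm
        (2.0, 10.0, 10.0),
        (1.0, 0.015, 0.0075),  # same in um
    ])
    def test_eta(self, nu, eps0, expected):
        assert bp.compute_eta(nu, eps0) == pytest.approx(expected)

    def test_eta_vanishing_layer(self):
        assert bp.compute_eta(1e-12, 15.0) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("nu,eps0", [(0, 15), (-1, 15), (1, 0)])
    def test_eta_domain(self, nu, eps0):
        with pytest.raises(ValueError):
            bp.compute_eta(nu, eps0)

    def test_beta_dark_matches_printed_value(self):
        # surface rate * PDE density / eta reproduces the tabulated 67 1/s
        beta = bp.compute_beta_dark(5.02e-4, 1000.0, 7.5e-3)
        assert beta == pytest.approx(67.0, rel=0.01)

    def test_beta_dark_direct(self):
        assert bp.compute_beta_dark(1e-3, 500.0, 5e-3) == pytest.approx(100.0)
        assert bp.compute_beta_dark(0.0, 123.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            bp.compute_beta_dark(1e-3, 500.0, 0.0)


class TestHillLaws:
    def test_cyclase_limits(self, params):
        assert bp.cyclase_rate(0.0, params) == pytest.approx(1311.0)
        mid = bp.cyclase_rate(params.K_cyc, params)
        assert mid == pytest.approx(0.5 * (1311.0 + 1311.0 / 13.9), rel=1e-12)
        assert mid == pytest.approx(702.66, rel=1e-3)
        assert bp.cyclase_rate(1e9, params) == pytest.approx(params.alpha_min,
                                                             rel=1e-6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(ca=st.floats(min_value=0.0, max_value=50.0),
           dca=st.floats(min_value=1e-3, max_value=50.0))
    def test_cyclase_monotone_bounded(self, ca, dca, params):
        a1 = bp.cyclase_rate(ca, params)
        a2 = bp.cyclase_rate(ca + dca, params)
        assert params.alpha_min <= a2 < a1 <= params.alpha_max

    def test_channel_half_saturation(self, params):
        assert bp.channel_current(params.K_cG, params) == pytest.approx(1250.0)
        assert bp.channel_current(0.0, params) == 0.0

    def test_channel_hill_m25(self, params):
        # direct Hill evaluation, cross-checked by high-precision arithmetic
        p = params.replace(m_cG=2.5)
        assert bp.channel_current(2.0, p) == pytest.approx(7.880773, rel=1e-6)

    def test_exchanger(self, params):
        assert bp.exchanger_current(params.K_ex, params) == pytest.approx(2.435)
        assert bp.exchanger_current(0.0, params) == 0.0
        assert bp.exchanger_current(0.4, params) == pytest.approx(1.787156, rel=1e-6)

    def test_monotone_saturating(self, params):
        cg = np.linspace(0.0, 500.0, 200)
        j = bp.channel_current(cg, params)
        assert np.all(np.diff(j) > 0)
        assert j[-1] < params.J_cG_max
        ca = np.linspace(0.0, 200.0, 200)
        jex = bp.exchanger_current(ca, params)
        assert np.all(np.diff(jex) > 0)
        assert jex[-1] < params.J_ex_sat
        # concavity beyond half-saturation
        k = np.searchsorted(cg, params.K_cG)
        assert np.all(np.diff(j, 2)[k:] < 0)

    def test_negative_inputs_rejected(self, params):
        for fn in (bp.cyclase_rate, bp.exchanger_current):
            with pytest.raises(ValueError):
                fn(-0.1, params)
        with pytest.raises(ValueError):
            bp.channel_current(-0.1, params)


class TestBoundaryFluxes:
    def test_cg_flux_dark_balance(self, params, derived, dark):
        f = bp.cg_boundary_flux(dark.cG_dark, dark.Ca_dark, 0.0, False,
                                params, derived)
        assert abs(f) < 1e-12

    def test_cg_flux_pure_synthesis(self, params, derived):
        f = bp.cg_boundary_flux(0.0, 0.5, 0.0, False, params, derived)
        assert f == pytest.approx(
            derived.eta * bp.cyclase_rate(0.5, params))
        assert f > 0

    def test_cg_flux_activated_face(self, params, derived, dark):
        f = bp.cg_boundary_flux(dark.cG_dark, dark.Ca_dark, 10.0, True,
                                params, derived)
        assert f == pytest.approx(
            -params.k_sigma_hyd_star * 10.0 * dark.cG_dark, rel=1e-10)

    def test_ca_flux_dark_balance(self, params, geom, dark):
        f = bp.ca_boundary_flux(dark.cG_dark, dark.Ca_dark, params,
                                geom.Sigma_cone)
        assert abs(f) < 1e-12

    def test_ca_flux_pure_extrusion(self, params, geom):
        assert bp.ca_boundary_flux(0.0, 0.5, params, geom.Sigma_cone) < 0

    def test_ca_flux_linear_in_channel_current(self, params, geom, dark):
        # doubling the channel term adds an influx equal to the dark
        # exchanger magnitude (linearity of the bracket)
        jex = bp.exchanger_current_density(dark.Ca_dark, params, geom.Sigma_cone)
        f0 = bp.ca_boundary_flux(dark.cG_dark, dark.Ca_dark, params,
                                 geom.Sigma_cone)
        cg2 = bp.channel_current_density(dark.cG_dark, params, geom.Sigma_cone)
        f2 = (bp.CURRENT_DENSITY_TO_MOLAR_FLUX / (params.B_Ca * params.faraday)
              ) * (0.5 * params.f_Ca * 2 * cg2 - jex)
        expected = f0 + (bp.CURRENT_DENSITY_TO_MOLAR_FLUX /
                         (params.B_Ca * params.faraday)) * jex
        assert f2 == pytest.approx(expected, rel=1e-12)


class TestDarkState:
    def test_reference_dark_current(self, dark):
        # total circulating dark current from mass balance, channel-only
        assert dark.j_dark == pytest.approx(14.95, rel=0.02)
        assert dark.residual_cg < 1e-10
        assert dark.residual_ca < 1e-10
        assert dark.cG_dark > 0 and dark.Ca_dark > 0

    def test_flux_laws_vanish_at_dark(self, params, derived, geom, dark):
        assert bp.cyclase_rate(dark.Ca_dark, params) == pytest.approx(
            derived.beta_dark * dark.cG_dark, rel=1e-10)
        assert abs(bp.ca_boundary_flux(dark.cG_dark, dark.Ca_dark, params,
                                       geom.Sigma_cone)) < 1e-12

    def test_monotone_in_alpha_max(self, params, derived):
        # a stronger cyclase raises the dark cGMP level (the saturable
        # exchanger bounds how large a scaling still admits a balance)
        d2 = bp.solve_dark_state(params.replace(alpha_max=1.1 * 1311.0), derived)
        d1 = bp.solve_dark_state(params, derived)
        assert d2.cG_dark > d1.cG_dark

    def test_degenerate_exchanger_raises(self, params, derived):
        with pytest.raises(bp.DarkStateError):
            bp.solve_dark_state(params.replace(J_ex_sat=1e-12), derived)

    def test_roundtrip_reproduces_derived_rates(self, params, tmp_path, geom):
        path = tmp_path / "p.yaml"
        params.to_yaml(path)
        p2 = cs.BiochemParams.from_yaml(path)
        assert p2 == params
        d1 = bp.derived_rates(params, geom.eps0, geom.nu)
        d2 = bp.derived_rates(p2, geom.eps0, geom.nu)
        assert d1 == d2  # bit-identical derived rates

    def test_validation(self):
        with pytest.raises(ValueError):
            cs.BiochemParams(f_Ca=1.5)
        with pytest.raises(ValueError):
            cs.BiochemParams(alpha_suppression_ratio=0.5)
        with pytest.raises(ValueError):
            cs.BiochemParams(m_cG=0.5)
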