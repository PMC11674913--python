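"""Dielectric models: complex permittivities, shell reduction, CMF spectra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depcyte import dielectrics as dx

EPS0 = dx.EPS0
DEP_MEDIUM = dx.MEDIA["dep_medium"]
DI_WATER = dx.MEDIA["di_water"]


class TestComplexPermittivity:
    @pytest.mark.parametrize("eps_r,sigma,f,expected", [
        # lossless: purely real
        (78.0, 0.0, 1e6, 78 * EPS0 + 0j),
        # hand-evaluated eps0*eps_r - j*sigma/(2*pi*f)
        (78.0, 0.17, 6e6, 6.906e-10 - 4.509e-9j),
        (2.5, 2.548e-4, 1e6, 2.214e-11 - 4.055e-11j),
    ])
    def test_worked_values(self, eps_r, sigma, f, expected):
        got = dx.complex_permittivity(eps_r, sigma, f)
        assert got.real == pytest.approx(expected.real, rel=1e-3)
        assert got.imag == pytest.approx(expected.imag, rel=1e-3, abs=1e-30)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            dx.complex_permittivity(78, 0.1, 0.0)
        with pytest.raises(ValueError):
            dx.complex_permittivity(78, 0.1, -1e6)


class TestClausiusMossotti:
    def test_matched_particle_is_zero(self):
        e = dx.complex_permittivity(50, 0.3, 1e6)
        assert dx.clausius_mossotti(e, e) == 0

    def test_analytic_limits(self):
        em = dx.complex_permittivity(78, 0.1, 1e6)
        assert dx.clausius_mossotti(1e6 * em, em).real == pytest.approx(1.0, abs=1e-5)
        assert dx.clausius_mossotti(0j, em).real == pytest.approx(-0.5)

    def test_pss_in_di_water_near_minus_half(self):
        """15.7 um polystyrene sphere in DI water at 1 MHz: the calibration
        particle's Re{Kcm} is about -0.5 (exact value -0.475)."""
        pss = dx.load_preset("pss_15p7um")
        k = dx.cmf_at(pss, DI_WATER, 1e6)
        assert k.real == pytest.approx(-0.4751, abs=2e-3)
        assert round(k.real, 1) == -0.5

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            dx.clausius_mossotti(-2.0 + 0j, 1.0 + 0j)


class TestShellReduce:
    def test_homogeneous_and_zero_thickness_identities(self):
        e1 = dx.complex_permittivity(60, 0.5, 2e6)
        e2 = dx.complex_permittivity(10, 1e-6, 2e6)
        # matched shell and core
        got = dx.shell_reduce(e1, e1, 1e-6, 2e-6)
        assert got == pytest.approx(e1, rel=1e-12)
        # zero-thickness shell
        got = dx.shell_reduce(e1, e2, 3e-6, 3e-6)
        assert got == pytest.approx(e1, rel=1e-12)

    def test_nucleus_stage_equivalent_conductivity(self):
        """Nucleoplasm inside its envelope at 6 MHz (viable parameters):
        equivalent conductivity -Im{eps_eq}*omega = 0.1371 S/m (independent
        high-precision evaluation of the confocal reduction)."""
        cell = dx.load_preset("cho_viable")
        e_n = dx.complex_permittivity(cell.eps_n, cell.sigma_n, 6e6)
        e_ne = dx.complex_permittivity(cell.eps_ne, cell.sigma_ne, 6e6)
        eq = dx.shell_reduce(e_n, e_ne, cell.r_n - cell.d_n, cell.r_n)
        sigma_eq = -eq.imag * 2 * math.pi * 6e6
        assert sigma_eq == pytest.approx(0.1371, abs=0.001)

    def test_invalid_radii(self):
        e = 50 * EPS0 + 0j
        with pytest.raises(ValueError):
            dx.shell_reduce(e, e, 2e-6, 1e-6)


class TestCellEquivalentPermittivity:
    def test_uniform_cell_collapses_to_material(self):
        cell = dx.DoubleShellCell(
            r_cell=6e-6, r_n=3.3e-6, d_n=40e-9, d_mem=5e-9,
            sigma_mem=0.4, sigma_ne=0.4, sigma_cyt=0.4, sigma_n=0.4,
            eps_mem=60.0, eps_ne=60.0, eps_cyt=60.0, eps_n=60.0)
        got = dx.cell_equivalent_permittivity(cell, 5e6)
        want = dx.complex_permittivity(60.0, 0.4, 5e6)
        assert got == pytest.approx(want, rel=1e-10)

    @pytest.mark.parametrize("preset,expected", [
        ("cho_viable", 0.3531), ("cho_nonviable", -0.1988)])
    def test_nominal_cho_kcm_at_6mhz(self, preset, expected):
        """Full double-shell chain, verified against an independent
        brute-force evaluation before the build."""
        k = dx.cmf_at(dx.load_preset(preset), DEP_MEDIUM, 6e6)
        assert k.real == pytest.approx(expected, abs=0.002)

    def test_viability_sign_split_at_6mhz(self):
        kv = dx.cmf_at(dx.load_preset("cho_viable"), DEP_MEDIUM, 6e6).real
        kn = dx.cmf_at(dx.load_preset("cho_nonviable"), DEP_MEDIUM, 6e6).real
        assert kv > 0 and kn < 0  # pDEP vs nDEP


class TestSpectrum:
    def test_bounds_and_high_frequency_limit(self):
        cell = dx.load_preset("cho_viable")
        spec = dx.cmf_spectrum(cell, DEP_MEDIUM)
        assert np.all(spec.re >= -0.5 - 1e-9)
        assert np.all(spec.re <= 1.0 + 1e-9)
        # f -> inf: pure-permittivity contrast of the outermost interface
        # chain evaluated at 10 GHz
        k_inf = dx.cmf_at(cell, DEP_MEDIUM, 1e10).real
        e_p = dx.cell_equivalent_permittivity(cell, 1e10).real
        e_m = DEP_MEDIUM.rel_permittivity * EPS0
        closed = (e_p - e_m) / (e_p + 2 * e_m)
        assert k_inf == pytest.approx(closed, abs=1e-3)

    def test_homogeneous_sphere_frequency_limits(self):
        """Low/high-frequency CMF of a homogeneous sphere matches the
        conductivity / permittivity closed forms."""
        sph = dx.SurfaceConductingSphere(radius=5e-6,
                                         bulk_rel_permittivity=2.5,
                                         surface_conductance=1e-9)
        med = dx.Medium(78.0, 1e-3)
        k_lo = dx.cmf_at(sph, med, 1.0).real
        sp, sm = sph.conductivity, med.conductivity
        assert k_lo == pytest.approx((sp - sm) / (sp + 2 * sm), abs=1e-3)
        k_hi = dx.cmf_at(sph, med, 1e12).real
        ep, em = 2.5, 78.0
        assert k_hi == pytest.approx((ep - em) / (ep + 2 * em), abs=1e-3)

    def test_crossover_located_by_bisection(self):
        spec = dx.cmf_spectrum(dx.load_preset("cho_viable"), DEP_MEDIUM)
        crossings = spec.crossover_frequencies()
        assert crossings, "viable CHO spectrum must cross zero"
        for f0 in crossings:
            k = dx.cmf_at(dx.load_preset("cho_viable"), DEP_MEDIUM, f0).real
            assert abs(k) < 1e-3

    def test_empty_and_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            dx.cmf_spectrum(dx.load_preset("cho_viable"), DEP_MEDIUM, [])
        with pytest.raises(ValueError):
            dx.cmf_spectrum(dx.load_preset("cho_viable"), DEP_MEDIUM,
                            [1e6, 1e5])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        eps_cyt=st.floats(30, 80), sigma_cyt=st.floats(0.01, 1.5),
        eps_n=st.floats(30, 150), sigma_n=st.floats(0.05, 2.0),
        r_um=st.floats(3.5, 9.0), f_log=st.floats(4, 9),
    )
    def test_cmf_bound_property(self, eps_cyt, sigma_cyt, eps_n, sigma_n,
                                r_um, f_log):
        """-0.5 <= Re{Kcm} <= 1 for any physical double-shell parameters."""
        r = r_um * 1e-6
        cell = dx.DoubleShellCell(
            r_cell=r, r_n=0.55 * r, d_n=40e-9, d_mem=5e-9,
            sigma_mem=1e-6, sigma_ne=1e-3, sigma_cyt=sigma_cyt,
            sigma_n=sigma_n, eps_mem=8.5, eps_ne=11.5,
            eps_cyt=eps_cyt, eps_n=eps_n)
        k = dx.cmf_at(cell, DEP_MEDIUM, 10 ** f_log).real
        assert -0.5 - 1e-9 <= k <= 1.0 + 1e-9


class TestSensitivityBand:
    def test_zero_fraction_collapses_to_nominal(self):
        cell = dx.load_preset("cho_viable")
        f = dx.default_frequency_grid(n=50)
        lo, hi = dx.sensitivity_band(cell, DEP_MEDIUM, f, "sigma_cyt", 0.0)
        nom = dx.cmf_spectrum(cell, DEP_MEDIUM, f)
        np.testing.assert_allclose(lo.re, nom.re, rtol=1e-12)
        np.testing.assert_allclose(hi.re, nom.re, rtol=1e-12)

    def test_band_contains_nominal(self):
        cell = dx.load_preset("cho_viable")
        f = dx.default_frequency_grid(n=80)
        nom = dx.cmf_spectrum(cell, DEP_MEDIUM, f)
        for param in ("sigma_cyt", "r_cell", "eps_mem"):
            lo, hi = dx.sensitivity_band(cell, DEP_MEDIUM, f, param, 0.2)
            assert np.all(lo.re <= nom.re + 1e-12)
            assert np.all(hi.re >= nom.re - 1e-12)

    def test_printed_band_endpoints(self):
        """+/-20% sweeps reproduce the printed parameter ranges:
        sigma_cyt 0.43-0.63 S/m and r_cell 5-7.5 um for viable cells."""
        cell = dx.load_preset("cho_viable")
        assert cell.sigma_cyt * 0.8 == pytest.approx(0.424, abs=0.01)
        assert cell.sigma_cyt * 1.2 == pytest.approx(0.636, abs=0.01)
        assert cell.r_cell * 0.8 == pytest.approx(5e-6, rel=1e-9)
        assert cell.r_cell * 1.2 == pytest.approx(7.5e-6, rel=1e-9)
        scaled = cell.with_radius(cell.r_cell * 1.2)
        assert scaled.r_n == pytest.approx(0.55 * scaled.r_cell)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            dx.sensitivity_band(dx.load_preset("cho_viable"), DEP_MEDIUM,
                                None, "sigma_bogus")


def test_spectrum_csv_roundtrip(tmp_path):
    import pandas as pd

    spec = dx.cmf_spectrum(dx.load_preset("pss_10um"), DI_WATER,
                           dx.default_frequency_grid(n=20))
    path = tmp_path / "spec.csv"
    spec.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["frequency_hz", "re_kcm", "im_kcm"]
    np.testing.assert_allclose(df.re_kcm, spec.re, rtol=1e-6)
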