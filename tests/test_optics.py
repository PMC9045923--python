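"""Tissue optical property models: absorption mixture, Rayleigh/Mie
scattering, refractive indices, tumour contrast, variability perturbations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cherenkovmrt.materials import Material
from cherenkovmrt.optics import (ChromophoreBasis, MaterialOptics,
                                 OpticalPropertyTable, ScatteringModelParams,
                                 TissueComposition, WAVELENGTH_NM,
                                 apply_tumour_contrast, build_optical_table,
                                 compute_mu_a, compute_scattering,
                                 perturb_parameters, refractive_index)


def flat_basis(hbo2=0.0, hb=0.0, water=0.0, fat=0.0, mel=0.0):
    wl = WAVELENGTH_NM
    return ChromophoreBasis(wl, *(np.full_like(wl, v)
                                  for v in (hbo2, hb, water, fat, mel)))


class TestAbsorptionMixture:
    def test_single_chromophore_reduction(self):
        basis = flat_basis(hbo2=3.7)
        comp = TissueComposition(so2=1.0, water=0.0, fat=0.0)
        assert compute_mu_a(comp, basis, 700.0) == pytest.approx(3.7)

    def test_hand_evaluated_mixture(self):
        # 0.5*2 + 0.5*4 + 0.5*1 = 3.5 per the mixing rule
        basis = flat_basis(hbo2=2.0, hb=4.0, water=1.0)
        comp = TissueComposition(so2=0.5, water=0.5, fat=0.0)
        assert compute_mu_a(comp, basis, 800.0) == pytest.approx(3.5)

    def test_zero_basis_gives_zero(self):
        comp = TissueComposition(so2=0.3, water=0.9, fat=0.4, melanin=0.01)
        assert compute_mu_a(comp, flat_basis(), 1000.0) == 0.0

    def test_out_of_range_wavelength_rejected(self):
        comp = TissueComposition(so2=0.5, water=0.5, fat=0.0)
        with pytest.raises(ValueError):
            compute_mu_a(comp, flat_basis(water=1.0), 499.0)
        with pytest.raises(ValueError):
            compute_mu_a(comp, flat_basis(water=1.0), 1201.0)

    @settings(deadline=None, derandomize=True)
    @given(so2=st.floats(0, 1), w=st.floats(0, 1), f=st.floats(0, 1),
           m=st.floats(0, 1))
    def test_matches_manual_formula_and_nonnegative(self, so2, w, f, m):
        basis = ChromophoreBasis.default()
        comp = TissueComposition(so2, w, f, m)
        lam = 750.0
        got = compute_mu_a(comp, basis, lam)
        manual = (so2 * basis.at("mu_hbo2", lam)
                  + (1 - so2) * basis.at("mu_hb", lam)
                  + w * basis.at("mu_water", lam)
                  + f * basis.at("mu_fat", lam)
                  + m * basis.at("mu_mel", lam))
        assert got == pytest.approx(manual)
        assert got >= 0

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            TissueComposition(so2=1.2, water=0.0, fat=0.0)


class TestScattering:
    def test_reference_wavelength_returns_amplitude(self):
        p = ScatteringModelParams(a=20.0, f_ray=0.3, b_mie=1.0, lam0=500.0)
        mu_sp, _ = compute_scattering(p, 0.9, 500.0)
        assert mu_sp == pytest.approx(20.0)

    def test_pure_rayleigh_quartic_falloff(self):
        p = ScatteringModelParams(a=16.0, f_ray=1.0, b_mie=2.0, lam0=500.0)
        mu_sp, _ = compute_scattering(p, 0.0, 1000.0)
        assert mu_sp == pytest.approx(1.0)  # a / 2^4

    def test_reduced_to_full_scattering(self):
        p = ScatteringModelParams(a=5.0, f_ray=0.0, b_mie=0.0)
        mu_sp, mu_s = compute_scattering(p, 0.9, 500.0)
        assert mu_sp == pytest.approx(5.0)
        assert mu_s == pytest.approx(50.0)

    def test_unit_anisotropy_rejected(self):
        p = ScatteringModelParams(a=5.0, f_ray=0.0, b_mie=0.0)
        with pytest.raises(ValueError):
            compute_scattering(p, 1.0, 500.0)


class TestRefractiveIndex:
    @pytest.mark.parametrize("mat,expected", [
        (Material.BONE, 1.55),
        (Material.THYROID, 1.40),
        (Material.TUMOUR, 1.39),
        (Material.AIR, 1.0),
    ])
    def test_constant_materials(self, mat, expected):
        for lam in (500.0, 750.0, 1200.0):
            assert refractive_index(mat, lam) == pytest.approx(expected)

    @pytest.mark.parametrize("mat", [Material.ADIPOSE, Material.SKIN,
                                     Material.MUSCLE])
    def test_dispersive_materials_plausible_and_decreasing(self, mat):
        n500 = refractive_index(mat, 500.0)
        n1200 = refractive_index(mat, 1200.0)
        assert 1.3 < n1200 < n500 < 1.5

    def test_unknown_material_rejected(self):
        with pytest.raises(ValueError):
            refractive_index("kryptonite")


class TestTumourContrast:
    def test_contrast_factors(self):
        wl = WAVELENGTH_NM
        thy = MaterialOptics(np.full_like(wl, 1.0), np.full_like(wl, 100.0),
                             np.full_like(wl, 0.9), np.full_like(wl, 1.40))
        tum = apply_tumour_contrast(thy)
        assert np.allclose(tum.mu_a, 1.44)   # +44%
        assert np.allclose(tum.mu_s, 70.0)   # -30%
        assert np.allclose(tum.n, 1.39)
        assert np.allclose(tum.g, 0.9)


class TestVariabilityPerturbation:
    def test_adipose_up_factors(self, default_optics):
        up = perturb_parameters(default_optics, "up")
        a0 = default_optics.materials[Material.ADIPOSE]
        a1 = up.materials[Material.ADIPOSE]
        assert np.allclose(a1.mu_a, a0.mu_a * 1.099)
        assert np.allclose(a1.mu_s, a0.mu_s * 1.089)
        assert np.allclose(a1.n, a0.n * 1.006)
        assert np.allclose(a1.g, a0.g)

    def test_thyroid_down_factors(self, default_optics):
        down = perturb_parameters(default_optics, "down")
        t0 = default_optics.materials[Material.THYROID]
        t1 = down.materials[Material.THYROID]
        assert np.allclose(t1.mu_a, t0.mu_a * 0.942)
        assert np.allclose(t1.mu_s, t0.mu_s * 0.970)
        assert np.allclose(t1.n, t0.n * 0.980)
        assert np.allclose(t1.g, t0.g * 0.9785)

    def test_skin_and_bone_unperturbed(self, default_optics):
        up = perturb_parameters(default_optics, "up")
        for mat in (Material.SKIN, Material.BONE):
            assert np.array_equal(up.materials[mat].mu_a,
                                  default_optics.materials[mat].mu_a)
            assert np.array_equal(up.materials[mat].n,
                                  default_optics.materials[mat].n)

    def test_none_is_identity(self, default_optics):
        same = perturb_parameters(default_optics, "none")
        for mat, mo in default_optics.materials.items():
            for f in ("mu_a", "mu_s", "g", "n"):
                assert np.array_equal(getattr(same.materials[mat], f),
                                      getattr(mo, f))

    def test_up_then_inverse_recovers_baseline(self, default_optics):
        from cherenkovmrt.optics import VARIABILITY_PCT

        up = perturb_parameters(default_optics, "up")
        for mat, (pa, ps, pn, pg) in VARIABILITY_PCT.items():
            mo = up.materials[mat]
            mo.mu_a /= 1 + pa / 100
            mo.mu_s /= 1 + ps / 100
            mo.n /= 1 + pn / 100
            mo.g /= 1 + pg / 100
            base = default_optics.materials[mat]
            assert np.allclose(mo.mu_a, base.mu_a, rtol=1e-12)
            assert np.allclose(mo.g, base.g, rtol=1e-12)

    def test_perturbed_anisotropy_above_one_rejected(self, default_optics):
        bad = default_optics.copy()
        bad.materials[Material.THYROID].g[:] = 0.99
        with pytest.raises(ValueError):
            perturb_parameters(bad, "up")


class TestDefaultTable:
    def test_spectra_positive_and_finite(self, default_optics):
        for mat, mo in default_optics.materials.items():
            for f in ("mu_a", "mu_s", "g", "n"):
                arr = getattr(mo, f)
                assert np.all(np.isfinite(arr)), (mat, f)
                assert np.all(arr >= 0)
            if mat != Material.AIR:
                assert np.all(mo.n >= 1.0)
            assert np.all(mo.g < 1.0)

    def test_reduced_scattering_identity(self, default_optics):
        for mo in default_optics.materials.values():
            assert np.allclose(mo.mu_s_prime, mo.mu_s * (1 - mo.g))

    @pytest.mark.parametrize("mat", [Material.SKIN, Material.ADIPOSE,
                                     Material.MUSCLE, Material.THYROID,
                                     Material.TUMOUR])
    def test_soft_tissue_absorption_has_nir_window(self, default_optics, mat):
        """Every soft tissue's mu_a dips inside the 650-900 nm NIR window."""
        wl = default_optics.wavelengths
        mu_a = default_optics.materials[mat].mu_a
        inside = (wl > 650) & (wl < 900)
        assert mu_a[inside].min() < mu_a[wl == 650][0]
        assert mu_a[inside].min() < mu_a[wl == 900][0]

    def test_csv_roundtrip(self, tmp_path, default_optics):
        default_optics.to_csv(tmp_path)
        back = OpticalPropertyTable.from_csv(tmp_path)
        for mat, mo in default_optics.materials.items():
            assert np.allclose(back.materials[mat].mu_a, mo.mu_a)
            assert np.allclose(back.materials[mat].n, mo.n)

    def test_thyroid_n_override_shifts_tumour_proportionally(self):
        t = build_optical_table(thyroid_n=1.428)
        assert t.n_ref(Material.THYROID) == pytest.approx(1.428)
        assert t.n_ref(Material.TUMOUR) == pytest.approx(1.39 * 1.428 / 1.40)
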