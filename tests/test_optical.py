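"""Optical photon transport: phase function, Fresnel boundaries, free paths
and fate accounting, with the compiled and numpy engines cross-checked."""

import numpy as np
import pytest

from cherenkovmrt.materials import Material
from cherenkovmrt.nuclear import isotropic_directions
from cherenkovmrt.photons import (OpticalTransport, fresnel_interface,
                                  fresnel_reflectance,
                                  henyey_greenstein_cosines, propagate_photon,
                                  sample_scatter_direction)
from cherenkovmrt.transport import PhotonBatch
from conftest import make_box_phantom, make_slab_table


def pencil_batch(n, y0=1e-6, wavelength=800.0):
    pos = np.tile([0.0, y0, 0.0], (n, 1))
    d = np.tile([0.0, 1.0, 0.0], (n, 1))
    return PhotonBatch(pos, d, np.full(n, wavelength), pos.copy())


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_mean_cosine_equals_g(self, g, rng):
        n = 300_000
        c = henyey_greenstein_cosines(g, n, rng)
        se = c.std() / np.sqrt(n)
        assert abs(c.mean() - g) < 3 * se

    def test_forward_peaked_limit(self, rng):
        c = henyey_greenstein_cosines(0.999, 50_000, rng)
        assert c.mean() > 0.99

    def test_isotropic_limit_uniform_cosine(self, rng):
        from scipy import stats

        c = henyey_greenstein_cosines(0.0, 100_000, rng)
        _, p = stats.kstest(c, stats.uniform(loc=-1, scale=2).cdf)
        assert p > 0.001

    def test_scatter_direction_unit_norm(self, rng):
        d = sample_scatter_direction(0.9, np.array([0.0, 0.0, 1.0]), rng)
        assert np.isclose(np.linalg.norm(d), 1.0)

    def test_invalid_g_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_scatter_direction(1.0, np.array([0.0, 0.0, 1.0]), rng)


class TestFresnel:
    def test_normal_incidence_closed_form(self):
        assert fresnel_reflectance(1.4, 1.0, 1.0) == pytest.approx(
            (0.4 / 2.4) ** 2)

    def test_matched_media_no_reflection(self, rng):
        refl, d = fresnel_interface(1.4, 1.4, np.array([0.0, 0.0, 1.0]),
                                    np.array([0.0, 0.0, 1.0]), rng)
        assert not refl
        assert np.allclose(d, [0.0, 0.0, 1.0])

    def test_total_internal_reflection(self, rng):
        # incidence beyond arcsin(n2/n1) always reflects
        theta = np.arcsin(1.0 / 1.4) + 0.1
        inc = np.array([np.sin(theta), 0.0, np.cos(theta)])
        nrm = np.array([0.0, 0.0, 1.0])
        assert fresnel_reflectance(1.4, 1.0, np.cos(theta)) == 1.0
        for _ in range(20):
            refl, d = fresnel_interface(1.4, 1.0, inc, nrm, rng)
            assert refl
            assert d[2] == pytest.approx(-inc[2])

    def test_snell_refraction_angle(self, rng):
        n1, n2 = 1.0, 1.5
        theta_i = 0.5
        inc = np.array([np.sin(theta_i), 0.0, np.cos(theta_i)])
        nrm = np.array([0.0, 0.0, 1.0])
        while True:
            refl, d = fresnel_interface(n1, n2, inc, nrm, rng)
            if not refl:
                break
        sin_t = np.linalg.norm(np.cross(d, nrm))
        assert n2 * sin_t == pytest.approx(n1 * np.sin(theta_i))


@pytest.mark.parametrize("engine", ["numba", "numpy"])
class TestPropagation:
    def test_free_medium_straight_line_exit(self, engine, rng):
        """Matched-index, non-interacting medium: exits are the exact
        geometric projection of the launch ray."""
        ph = make_box_phantom(n=30, voxel_mm=2.0)
        ph.origin = np.array([-30.0, 0.0, -30.0])
        table = make_slab_table(0.0, 0.0, 0.9, 1.0)
        eng = OpticalTransport(ph, table, engine=engine)
        rec = eng.propagate(pencil_batch(200), rng)
        assert len(rec) == 200
        assert np.all(rec.positions[:, 1] == 60.0)
        assert np.all(rec.positions[:, 0] == 0.0)
        assert np.all(rec.positions[:, 2] == 0.0)

    def test_absorbing_medium_beer_lambert(self, engine, rng):
        """Survival over depth d equals exp(-mu_a d) in a pure absorber."""
        ph = make_box_phantom(n=30, voxel_mm=2.0)
        ph.origin = np.array([-30.0, 0.0, -30.0])
        table = make_slab_table(mu_a_cm=0.5, mu_s_cm=0.0, g=0.0, n=1.0)
        eng = OpticalTransport(ph, table, engine=engine)
        n = 50_000
        rec = eng.propagate(pencil_batch(n), rng)
        expect = np.exp(-0.05 * 60.0)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(len(rec) / n - expect) < 3 * se

    def test_photon_fate_conservation_exact(self, engine, rng):
        ph = make_box_phantom(n=20, voxel_mm=2.0)
        table = make_slab_table(mu_a_cm=1.0, mu_s_cm=50.0, g=0.9, n=1.4)
        eng = OpticalTransport(ph, table, engine=engine)
        n = 10_000
        pos = np.zeros((n, 3))
        batch = PhotonBatch(pos, isotropic_directions(n, rng),
                            np.full(n, 800.0), pos.copy())
        rec = eng.propagate(batch, rng)
        assert eng.n_absorbed + eng.n_exited == n
        assert eng.n_exited == len(rec)

    def test_wavelength_preserved_through_transport(self, engine, rng):
        ph = make_box_phantom(n=20, voxel_mm=2.0)
        table = make_slab_table(mu_a_cm=0.1, mu_s_cm=5.0, g=0.5, n=1.0)
        eng = OpticalTransport(ph, table, engine=engine)
        n = 5000
        pos = np.zeros((n, 3))
        wl = rng.uniform(500, 1200, n)
        batch = PhotonBatch(pos, isotropic_directions(n, rng), wl, pos.copy())
        rec = eng.propagate(batch, rng)
        assert len(rec) > 0
        assert np.all((rec.wavelengths >= 500) & (rec.wavelengths <= 1200))


def test_engines_agree_statistically(rng):
    """Compiled kernel and numpy engine give the same escape fraction."""
    ph = make_box_phantom(n=20, voxel_mm=2.0)
    table = make_slab_table(mu_a_cm=0.5, mu_s_cm=20.0, g=0.9, n=1.4)
    n = 20_000
    pos = np.zeros((n, 3))
    batch = PhotonBatch(pos, isotropic_directions(n, rng),
                        np.full(n, 800.0), pos.copy())
    frac = {}
    for engine in ("numba", "numpy"):
        eng = OpticalTransport(ph, table, engine=engine)
        eng.propagate(batch, np.random.default_rng(5))
        frac[engine] = eng.n_exited / n
    p = (frac["numba"] + frac["numpy"]) / 2
    se = np.sqrt(2 * p * (1 - p) / n)
    assert abs(frac["numba"] - frac["numpy"]) < 3 * se


def test_single_photon_wrapper(rng):
    ph = make_box_phantom(n=10, voxel_mm=2.0)
    table = make_slab_table(0.0, 0.0, 0.9, 1.0)
    fate, rec = propagate_photon([0.0, 0.0, 0.0], [0.0, 1.0, 0.0], 700.0,
                                 ph, table, rng)
    assert fate == "exited"
    assert len(rec) == 1


def test_index_mismatch_boundary_reflects_some_photons(rng):
    """A tissue-air boundary with n = 1.4 reflects ~2.8% at normal
    incidence, so slightly fewer photons exit than launch."""
    ph = make_box_phantom(n=10, voxel_mm=2.0)
    ph.origin = np.array([-10.0, 0.0, -10.0])
    table = make_slab_table(0.0, 0.0, 0.0, 1.4)
    eng = OpticalTransport(ph, table, engine="numba")
    n = 100_000
    rec = eng.propagate(pencil_batch(n), rng)
    # every photon eventually exits (no absorption), possibly after
    # internal reflections
    assert eng.n_exited == n
    straight = (rec.exit_axis == 1) & (rec.exit_sign == 1)
    r = (0.4 / 2.4) ** 2
    se = np.sqrt(r * (1 - r) / n)
    assert abs((1 - straight.mean()) - r) < 4 * se + r * r
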