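"""Particle transport: Cherenkov closed forms, electron range and energy
bookkeeping, gamma attenuation and Compton kinematics."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from cherenkovmrt.materials import Material
from cherenkovmrt.nuclear import SourceConfig, isotropic_directions, \
    sample_decay_batch
from cherenkovmrt.transport import (TransportEngine, cherenkov_threshold,
                                    cherenkov_yield, compton_edge,
                                    klein_nishina_mu,
                                    sample_cherenkov_wavelengths,
                                    simulate_decays, total_stopping_power)
from conftest import make_box_phantom


class TestCherenkovClosedForms:
    def test_threshold_at_biological_tissue_index(self):
        assert cherenkov_threshold(1.415) == pytest.approx(0.211, abs=5e-4)

    def test_threshold_at_thyroid_index(self):
        assert cherenkov_threshold(1.40) == pytest.approx(0.219, abs=5e-4)

    def test_threshold_limits(self):
        assert cherenkov_threshold(1e6) == pytest.approx(0.0, abs=1e-6)
        assert np.isinf(cherenkov_threshold(1.0))
        assert np.isinf(cherenkov_threshold(0.9))

    def test_yield_closed_form(self):
        # wavelength-integrated Frank-Tamm at beta=1, n=1.4, 500-1200 nm
        assert cherenkov_yield(1.0, 1.4) == pytest.approx(262.0, abs=0.5)

    def test_yield_vanishes_at_threshold(self):
        assert cherenkov_yield(1.0 / 1.4, 1.4) == 0.0
        assert cherenkov_yield(0.5, 1.4) == 0.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            cherenkov_yield(1.0, 1.4, 900.0, 600.0)

    def test_wavelength_sampling_follows_inverse_square(self, rng):
        lam = sample_cherenkov_wavelengths(100_000, rng)
        assert lam.min() >= 500.0 and lam.max() <= 1200.0

        def cdf(x):
            return (1 / 500.0 - 1 / x) / (1 / 500.0 - 1 / 1200.0)

        _, p = stats.kstest(lam, cdf)
        assert p > 0.001


class TestElectronTransport:
    def test_energy_ledger_conservation(self, rng):
        ph = make_box_phantom()
        eng = TransportEngine(ph, collect="count")
        n = 5000
        pos = rng.uniform(-10, 10, (n, 3))
        eng.transport_electrons(pos, isotropic_directions(n, rng),
                                np.full(n, 0.606), rng)
        led = eng.ledger()
        assert led["balance"] == pytest.approx(0.0,
                                               abs=1e-6 * led["initial_mev"])

    def test_csda_range_matches_quadrature_oracle(self, rng):
        """Mean condensed-history path length vs the 1/S quadrature range,
        which also sits at the few-mm beta-range scale in tissue."""
        oracle_g_cm2, _ = quad(lambda e: 1.0 / total_stopping_power(e),
                               0.010, 0.606, limit=200)
        ph = make_box_phantom(n=40, voxel_mm=2.0, density=1.0)
        eng = TransportEngine(ph, collect="none")
        n = 3000
        pos = np.zeros((n, 3))
        eng.transport_electrons(pos, isotropic_directions(n, rng),
                                np.full(n, 0.606), rng)
        mean_path_mm = eng.result.electron_path_mm / n
        assert mean_path_mm == pytest.approx(oracle_g_cm2 * 10.0, rel=0.02)
        assert 2.0 < mean_path_mm < 3.0

    def test_below_threshold_no_cherenkov(self, rng):
        ph = make_box_phantom()
        eng = TransportEngine(ph, collect="count",
                              n_override={Material.THYROID: 1.415})
        n = 2000
        eng.transport_electrons(np.zeros((n, 3)),
                                isotropic_directions(n, rng),
                                np.full(n, 0.15), rng)
        assert eng.result.n_cherenkov == 0

    def test_per_decay_dose_independent_of_event_count(self):
        ph = make_box_phantom()
        src = SourceConfig(uptake={"all": 1.0})
        totals = []
        for n, seed in ((20_000, 1), (40_000, 2)):
            r = simulate_decays(ph, src, n, np.random.default_rng(seed),
                                collect="none", include_gammas=False)
            totals.append(r.ledger["deposited_mev"] / n)
        assert totals[0] == pytest.approx(totals[1], rel=0.01)

    def test_emission_count_increases_with_refractive_index(self):
        ph = make_box_phantom()
        src = SourceConfig(uptake={"all": 1.0})
        counts = []
        for i, n_med in enumerate((1.36, 1.40, 1.44)):
            r = simulate_decays(ph, src, 60_000, np.random.default_rng(10),
                                collect="count", include_gammas=False,
                                n_override={Material.THYROID: n_med})
            counts.append(r.emission_counts.sum() / r.n_events)
        assert counts[0] < counts[1] < counts[2]

    def test_emission_directions_isotropic(self, rng):
        ph = make_box_phantom()
        src = SourceConfig(uptake={"all": 1.0})
        r = simulate_decays(ph, src, 20_000, rng, collect="full",
                            include_gammas=False)
        d = r.photons.directions
        se = np.sqrt(1.0 / 3.0 / len(d))
        assert np.all(np.abs(d.mean(axis=0)) < 3 * se)

    def test_beta_emission_confined_to_tumour_range(self, ptc_phantom, rng):
        """Beta-channel Cherenkov births stay within the ~2.5 mm beta range
        (3 mm margin) of the tumour when all uptake is in the tumour."""
        from scipy import ndimage

        src = SourceConfig(uptake={"tumour": 1.0})
        r = simulate_decays(ptc_phantom, src, 30_000, rng, collect="full",
                            include_gammas=False)
        tum = ptc_phantom.voi_masks["tumour"]
        near = ndimage.distance_transform_edt(
            ~tum, sampling=ptc_phantom.spacing) <= 3.0
        idx = ptc_phantom.world_to_index(r.photons.positions)
        idx = np.clip(idx, 0, np.array(ptc_phantom.shape) - 1)
        frac = (near | tum)[idx[:, 0], idx[:, 1], idx[:, 2]].mean()
        assert frac >= 0.95


class TestGammaTransport:
    def test_attenuation_coefficient_scale(self):
        # Compton-dominated linear attenuation of soft tissue at 0.364 MeV
        assert 0.09 < klein_nishina_mu(0.364, 1.0) < 0.13

    def test_interaction_free_survival_beer_lambert(self, rng):
        """P(no interaction within depth d) = exp(-mu d) for a pencil beam."""
        ph = make_box_phantom(n=40, voxel_mm=2.0, density=1.0)
        eng = TransportEngine(ph, collect="none")
        n = 100_000
        pos = np.tile([0.0, -39.9, 0.0], (n, 1))
        d = np.tile([0.0, 1.0, 0.0], (n, 1))
        info = eng.transport_gammas(pos, d, np.full(n, 0.364), rng,
                                    follow_electrons=False)
        depth_mm = 79.9
        expect = np.exp(-klein_nishina_mu(0.364, 1.0) * depth_mm / 10.0)
        frac = 1.0 - info.interacted.mean()
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < 3 * se

    def test_compton_electrons_bounded_by_edge(self, rng):
        ph = make_box_phantom()
        eng = TransportEngine(ph, collect="none")
        n = 50_000
        info = eng.transport_gammas(np.zeros((n, 3)),
                                    isotropic_directions(n, rng),
                                    np.full(n, 0.364), rng,
                                    follow_electrons=False)
        _, _, t_el = info.secondaries
        assert t_el.max() <= compton_edge(0.364) + 1e-12
        assert compton_edge(0.364) == pytest.approx(0.2139, abs=2e-4)

    def test_secondaries_from_364_line_make_no_cherenkov_in_thyroid(self, rng):
        """Compton edge (0.214 MeV) sits below the n=1.40 threshold
        (0.219 MeV), so 0.364 MeV gammas alone yield no Cherenkov light."""
        ph = make_box_phantom()
        eng = TransportEngine(ph, collect="count")  # thyroid n = 1.40
        n = 30_000
        eng.transport_gammas(np.zeros((n, 3)), isotropic_directions(n, rng),
                             np.full(n, 0.364), rng)
        assert eng.result.n_cherenkov == 0

    def test_gamma_ledger_conservation(self, rng):
        ph = make_box_phantom()
        eng = TransportEngine(ph, collect="none")
        n = 20_000
        eng.transport_gammas(np.zeros((n, 3)), isotropic_directions(n, rng),
                             np.full(n, 0.637), rng)
        led = eng.ledger()
        assert led["balance"] == pytest.approx(0.0,
                                               abs=1e-6 * led["initial_mev"])


def test_full_decay_simulation_ledger(ptc_phantom, rng):
    src = SourceConfig(uptake={"tumour": 1.0})
    r = simulate_decays(ptc_phantom, src, 20_000, rng, collect="count")
    led = r.ledger
    assert led["balance"] == pytest.approx(0.0, abs=1e-6 * led["initial_mev"])
    assert np.all(r.dose.energy_mev >= 0)
    assert np.all(r.dose.dose_gy() >= 0)
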