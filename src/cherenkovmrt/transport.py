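"""Electron and gamma transport with voxel dose scoring and Cherenkov
photon generation.

Electrons follow a class-I condensed-history scheme: continuous slowing down
along the collisional+radiative stopping power (analytic Berger-Seltzer
formula, water-equivalent composition, density-scaled per voxel), Gaussian
(Highland) multiple-scattering angular diffusion, and step lengths capped at
min(0.1 x residual CSDA range, half the smallest voxel dimension).  Energy
below the 10 keV cutoff is deposited locally; radiative losses are deposited
locally as well (bremsstrahlung photons are not tracked).

Cherenkov photons are generated per step from the wavelength-integrated
Frank-Tamm yield

    dN/dx = (2 pi alpha) z^2 (1 - 1/(beta^2 n^2)) (1/lam1 - 1/lam2),

evaluated at the step's mean beta and the voxel material's reference
refractive index, with Poisson-fluctuated counts, 1/lam^2-distributed
wavelengths and isotropic directions.

Gammas undergo Compton scattering only (Klein-Nishina total and differential
cross-sections, water electron density, density-scaled, Woodcock
delta-tracking through the heterogeneous grid); photons degraded below
50 keV are absorbed locally, emulating photoelectric capture.  Compton
electrons are handed to the electron transport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import Material, REFRACTIVE_INDEX_REF
from .phantom import VoxelPhantom

__all__ = [
    "MEC2",
    "cherenkov_threshold",
    "cherenkov_yield",
    "sample_cherenkov_wavelengths",
    "collision_stopping_power",
    "total_stopping_power",
    "csda_range",
    "klein_nishina_mu",
    "compton_edge",
    "DoseGrid",
    "PhotonBatch",
    "TransportEngine",
    "simulate_decays",
    "SimulationResult",
]

MEC2 = 0.511  # MeV
_ALPHA = 1.0 / 137.036
_ZA_WATER = 0.5551  # Z/A
_I_EXC = 75e-6  # MeV, mean excitation energy of water
_X0_WATER = 36.08  # g/cm^2, radiation length
_Z_EFF = 7.42
_NE_WATER = 3.343e23  # electrons per gram
_RE2 = 7.940787e-26  # classical electron radius squared, cm^2
_E_CUT = 0.010  # MeV, electron transport cutoff
_GAMMA_CUT = 0.050  # MeV, photon cutoff (local absorption below)


# ---------------------------------------------------------------------------
# Cherenkov closed forms
# ---------------------------------------------------------------------------

def cherenkov_threshold(n) -> float:
    """Electron kinetic-energy threshold (MeV) for Cherenkov emission.

    E_th = mec^2 (1/sqrt(1 - 1/n^2) - 1).  For n <= 1 no emission is
    possible at any energy and +inf is returned.
    """
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n > 1.0,
                       MEC2 * (1.0 / np.sqrt(1.0 - 1.0 / n**2) - 1.0),
                       np.inf)
    return float(out) if out.ndim == 0 else out


def cherenkov_yield(beta, n, lam1_nm: float = 500.0, lam2_nm: float = 1200.0):
    """Cherenkov photons per cm of electron path in [lam1, lam2].

    Analytic wavelength integral of the Frank-Tamm formula for unit charge;
    clamped to zero below threshold (beta * n <= 1).
    """
    if not lam1_nm < lam2_nm:
        raise ValueError("requires lam1 < lam2")
    beta = np.asarray(beta, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = 1.0 - 1.0 / (beta**2 * n**2)
    inv_lam = (1.0 / lam1_nm - 1.0 / lam2_nm) * 1e7  # 1/cm
    out = 2.0 * np.pi * _ALPHA * np.clip(factor, 0.0, None) * inv_lam
    return float(out) if out.ndim == 0 else out


def sample_cherenkov_wavelengths(k: int, rng: np.random.Generator,
                                 lam1_nm: float = 500.0,
                                 lam2_nm: float = 1200.0) -> np.ndarray:
    """Sample k wavelengths (nm) from the 1/lam^2 Frank-Tamm density."""
    u = rng.uniform(size=k)
    return 1.0 / (1.0 / lam1_nm - u * (1.0 / lam1_nm - 1.0 / lam2_nm))


# ---------------------------------------------------------------------------
# Electron stopping power and CSDA range (water-equivalent, density-scaled)
# ---------------------------------------------------------------------------

def collision_stopping_power(e_mev):
    """Collision mass stopping power of water (MeV cm^2/g), Berger-Seltzer."""
    e = np.asarray(e_mev, dtype=float)
    tau = e / MEC2
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / gamma**2
    term = np.log(tau**2 * (tau + 2.0) / (2.0 * (_I_EXC / MEC2) ** 2))
    f = (1.0 - beta2
         + (tau**2 / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) / gamma**2)
    return 0.153536 / beta2 * _ZA_WATER * (term + f)


def total_stopping_power(e_mev):
    """Collision plus approximate radiative stopping power (MeV cm^2/g)."""
    s_col = collision_stopping_power(e_mev)
    return s_col * (1.0 + _Z_EFF * np.asarray(e_mev, dtype=float) / 800.0)


# CSDA range table: cumulative integral of 1/S from 1 keV upward.
_E_GRID = np.geomspace(1e-3, 3.0, 3000)
_S_GRID = total_stopping_power(_E_GRID)
_R_GRID = np.concatenate([[0.0], np.cumsum(
    (1.0 / _S_GRID[1:] + 1.0 / _S_GRID[:-1]) / 2.0 * np.diff(_E_GRID))])


def csda_range(e_mev):
    """CSDA range in water (g/cm^2), measured from the 1 keV table floor."""
    return np.interp(e_mev, _E_GRID, _R_GRID)


def _energy_from_range(r):
    return np.interp(r, _R_GRID, _E_GRID)


# ---------------------------------------------------------------------------
# Klein-Nishina
# ---------------------------------------------------------------------------

def _kn_total_cross_section(e_mev):
    k = np.asarray(e_mev, dtype=float) / MEC2
    t = 1.0 + 2.0 * k
    ln_t = np.log(t)
    sigma = (2.0 * np.pi * _RE2
             * ((1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - ln_t / k)
                + ln_t / (2.0 * k) - (1.0 + 3.0 * k) / t**2))
    return sigma


def klein_nishina_mu(e_mev, density_g_cm3=1.0):
    """Compton linear attenuation coefficient (cm^-1), water-like medium."""
    return _NE_WATER * _kn_total_cross_section(e_mev) * np.asarray(
        density_g_cm3, dtype=float)


def compton_edge(e_mev):
    """Maximum Compton electron energy 2E^2/(mec^2 + 2E) (MeV)."""
    e = np.asarray(e_mev, dtype=float)
    out = 2.0 * e**2 / (MEC2 + 2.0 * e)
    return float(out) if out.ndim == 0 else out


def _sample_compton(e_mev: np.ndarray, rng: np.random.Generator):
    """Sample scattered-photon energy fraction eps and cos(theta) per photon
    (Butcher-Messel composition-rejection for the Klein-Nishina density)."""
    k = e_mev / MEC2
    eps_min = 1.0 / (1.0 + 2.0 * k)
    a1 = np.log(1.0 / eps_min)
    a2 = (1.0 - eps_min**2) / 2.0
    n = e_mev.size
    eps = np.empty(n)
    cos_t = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        u1, u2, u3 = rng.uniform(size=(3, m))
        em = eps_min[todo]
        use_log = u1 < a1[todo] / (a1[todo] + a2[todo])
        cand = np.where(use_log, em * np.exp(a1[todo] * u2),
                        np.sqrt(em**2 + (1.0 - em**2) * u2))
        t = (1.0 - cand) / (k[todo] * cand)
        sin2 = t * (2.0 - t)
        accept = u3 <= 1.0 - cand * sin2 / (1.0 + cand**2)
        idx = np.flatnonzero(todo)[accept]
        eps[idx] = cand[accept]
        cos_t[idx] = 1.0 - t[accept]
        todo[idx] = False
    return eps, cos_t


# ---------------------------------------------------------------------------
# Direction rotation (shared with the optical engine)
# ---------------------------------------------------------------------------

def rotate_directions(d: np.ndarray, cos_t: np.ndarray,
                      phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors d by polar angle arccos(cos_t), azimuth phi."""
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    ux, uy, uz = d[:, 0], d[:, 1], d[:, 2]
    cp, sp = np.cos(phi), np.sin(phi)
    near_pole = np.abs(uz) > 0.99999
    denom = np.sqrt(np.clip(1.0 - uz**2, 1e-12, None))
    vx = sin_t * (ux * uz * cp - uy * sp) / denom + ux * cos_t
    vy = sin_t * (uy * uz * cp + ux * sp) / denom + uy * cos_t
    vz = -sin_t * cp * denom + uz * cos_t
    px = sin_t * cp
    py = sin_t * sp * np.sign(uz)
    pz = cos_t * np.sign(uz)
    out = np.where(near_pole[:, None],
                   np.column_stack([px, py, pz]),
                   np.column_stack([vx, vy, vz]))
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    return out / norm


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class DoseGrid:
    """Per-voxel deposited energy with conversion to absorbed dose."""

    energy_mev: np.ndarray  # deposited energy per voxel
    phantom: VoxelPhantom

    def voxel_mass_g(self) -> np.ndarray:
        return self.phantom.density * self.phantom.voxel_volume_cm3

    def dose_gy(self) -> np.ndarray:
        """Absorbed dose (Gy) = deposited energy / voxel mass."""
        mev_to_j = 1.602176634e-13
        with np.errstate(divide="ignore", invalid="ignore"):
            d = self.energy_mev * mev_to_j / (self.voxel_mass_g() * 1e-3)
        return np.nan_to_num(d)


@dataclass
class PhotonBatch:
    """Cherenkov photons awaiting optical transport."""

    positions: np.ndarray  # (k, 3) mm
    directions: np.ndarray  # (k, 3)
    wavelengths: np.ndarray  # (k,) nm
    birth_positions: np.ndarray  # (k, 3) mm (equal to positions at birth)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def empty(cls) -> "PhotonBatch":
        z3 = np.zeros((0, 3))
        return cls(z3, z3.copy(), np.zeros(0), z3.copy())

    @classmethod
    def concatenate(cls, batches) -> "PhotonBatch":
        batches = [b for b in batches if len(b)]
        if not batches:
            return cls.empty()
        return cls(*[np.concatenate([getattr(b, f) for b in batches])
                     for f in ("positions", "directions", "wavelengths",
                               "birth_positions")])


@dataclass
class TransportResult:
    deposited_mev: float = 0.0
    escaped_mev: float = 0.0
    initial_mev: float = 0.0
    n_cherenkov: int = 0
    electron_path_mm: float = 0.0  # summed condensed-history step lengths


@dataclass
class GammaTransportInfo:
    """Per-photon bookkeeping of one gamma transport call."""

    interacted: np.ndarray  # bool per source photon: >=1 Compton scatter
    secondaries: tuple | None  # (pos, dir, energy) if not auto-transported


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class TransportEngine:
    """Vectorized particle transport over one voxel phantom.

    ``collect`` controls Cherenkov output: 'full' stores every photon (for
    subsequent optical transport), 'count' stores only per-voxel birth
    counts, 'none' skips generation entirely (dose-only runs).
    ``n_override`` replaces the per-material reference refractive indices
    (e.g. a homogeneous-medium index scan).
    """

    CHUNK = 200_000

    def __init__(self, phantom: VoxelPhantom, optics_table=None,
                 lam_range=(500.0, 1200.0), collect: str = "full",
                 n_override: dict | None = None,
                 photon_keep_fraction: float = 1.0):
        self.phantom = phantom
        self.lam1, self.lam2 = lam_range
        if collect not in ("full", "count", "none"):
            raise ValueError("collect must be 'full', 'count' or 'none'")
        self.collect = collect
        self.keep = float(photon_keep_fraction)

        nmat = max(int(m) for m in Material) + 1
        self.n_ref = np.ones(nmat)
        for mat in Material:
            if optics_table is not None and mat in optics_table.materials:
                self.n_ref[int(mat)] = optics_table.n_ref(mat)
            else:
                self.n_ref[int(mat)] = REFRACTIVE_INDEX_REF[mat]
        if n_override:
            for mat, val in n_override.items():
                self.n_ref[int(mat)] = val

        self.dose_energy = np.zeros(phantom.shape)
        self.emission_counts = np.zeros(phantom.shape)
        self.result = TransportResult()
        self._photon_parts: list[PhotonBatch] = []
        self._half_voxel = 0.5 * float(np.min(phantom.spacing))
        self._rho_flat = phantom.density.reshape(-1)
        self._lab_flat = phantom.labels.reshape(-1)
        self._rho_max = float(phantom.density.max())

    # -- electrons ----------------------------------------------------------

    def transport_electrons(self, pos, direction, energy,
                            rng: np.random.Generator):
        """Transport a batch of electrons; scores dose and Cherenkov."""
        pos = np.array(pos, dtype=float)
        d = np.array(direction, dtype=float)
        e = np.array(energy, dtype=float)
        for lo in range(0, e.size, self.CHUNK):
            self._electron_chunk(pos[lo:lo + self.CHUNK],
                                 d[lo:lo + self.CHUNK],
                                 e[lo:lo + self.CHUNK], rng)

    def _voxel_flat(self, pos):
        ph = self.phantom
        idx = np.floor((pos - ph.origin) / ph.spacing).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.array(ph.shape)), axis=1)
        flat = np.zeros(pos.shape[0], dtype=np.int64)
        ii = idx[inside]
        flat[inside] = ((ii[:, 0] * ph.shape[1]) + ii[:, 1]) * ph.shape[2] + ii[:, 2]
        return flat, inside

    def _electron_chunk(self, pos, d, e, rng):
        self.result.initial_mev += float(e.sum())
        lam_int = (1.0 / self.lam1 - 1.0 / self.lam2) * 1e7  # 1/cm
        deposited = 0.0
        escaped = 0.0
        alive = e > 0
        while alive.any():
            p = pos[alive]
            u = d[alive]
            en = e[alive]
            flat, inside = self._voxel_flat(p)
            if not inside.all():
                escaped += float(en[~inside].sum())
                keep = np.flatnonzero(alive)[~inside]
                alive[keep] = False
                p, u, en, flat = p[inside], u[inside], en[inside], flat[inside]
                if p.shape[0] == 0:
                    break
            rho = self._rho_flat[flat]
            mat = self._lab_flat[flat]
            n_here = self.n_ref[mat]

            r_mass = csda_range(en)  # g/cm^2
            r_mm = r_mass / rho * 10.0
            ds = np.minimum(0.1 * r_mm, self._half_voxel)  # mm
            r_new = r_mass - ds * rho / 10.0
            e_new = _energy_from_range(np.clip(r_new, 0.0, None))
            dies = e_new <= _E_CUT
            e_new = np.where(dies, 0.0, e_new)
            dep = en - e_new
            np.add.at(self.dose_energy.reshape(-1), flat, dep)
            deposited += float(dep.sum())
            self.result.electron_path_mm += float(ds[~dies].sum())

            # Cherenkov generation at the step's mean energy
            if self.collect != "none":
                e_mid = 0.5 * (en + e_new)
                gamma = 1.0 + e_mid / MEC2
                beta = np.sqrt(1.0 - 1.0 / gamma**2)
                with np.errstate(divide="ignore"):
                    factor = 1.0 - 1.0 / (beta**2 * n_here**2)
                y_mm = (2.0 * np.pi * _ALPHA * np.clip(factor, 0.0, None)
                        * lam_int / 10.0) * self.keep
                counts = rng.poisson(y_mm * ds)
                if counts.any():
                    np.add.at(self.emission_counts.reshape(-1), flat, counts)
                    self.result.n_cherenkov += int(counts.sum())
                    if self.collect == "full":
                        rep = np.repeat(np.arange(p.shape[0]), counts)
                        frac = rng.uniform(size=rep.size)
                        ph_pos = p[rep] + frac[:, None] * ds[rep, None] * u[rep]
                        from .nuclear import isotropic_directions
                        ph_dir = isotropic_directions(rep.size, rng)
                        ph_wl = sample_cherenkov_wavelengths(
                            rep.size, rng, self.lam1, self.lam2)
                        self._photon_parts.append(
                            PhotonBatch(ph_pos, ph_dir, ph_wl, ph_pos.copy()))

            # Highland multiple-scattering diffusion
            x_rad = ds * rho / 10.0 / _X0_WATER
            gam_s = 1.0 + en / MEC2
            beta_s = np.sqrt(1.0 - 1.0 / gam_s**2)
            p_mom = np.sqrt(en * (en + 2.0 * MEC2))
            theta0 = (13.6e-3 / np.maximum(beta_s * p_mom, 1e-6)
                      * np.sqrt(np.clip(x_rad, 1e-12, None))
                      * np.maximum(1.0 + 0.038 * np.log(np.clip(x_rad, 1e-12, None)),
                                   0.25))
            theta = theta0 * np.sqrt(-2.0 * np.log(rng.uniform(size=theta0.size)))
            phi = rng.uniform(0.0, 2.0 * np.pi, theta0.size)
            new_pos = p + ds[:, None] * u
            new_dir = rotate_directions(u, np.cos(theta), phi)

            live_idx = np.flatnonzero(alive)
            pos[live_idx] = new_pos
            d[live_idx] = new_dir
            e[live_idx] = e_new
            alive[live_idx[dies]] = False
        self.result.deposited_mev += deposited
        self.result.escaped_mev += escaped

    # -- gammas -------------------------------------------------------------

    def transport_gammas(self, pos, direction, energy,
                         rng: np.random.Generator,
                         follow_electrons: bool = True):
        """Transport gamma photons (Woodcock tracking, Compton-only).

        Secondary Compton electrons are transported immediately unless
        ``follow_electrons`` is False, in which case they are returned.
        """
        pos = np.array(pos, dtype=float)
        d = np.array(direction, dtype=float)
        e = np.array(energy, dtype=float)
        self.result.initial_mev += float(e.sum())
        sec = {"pos": [], "dir": [], "e": []}
        interacted = np.zeros(e.size, dtype=bool)
        alive = e > _GAMMA_CUT
        if (~alive).any():
            # below-cutoff source photons deposit locally
            flat, inside = self._voxel_flat(pos[~alive])
            dep = e[~alive]
            np.add.at(self.dose_energy.reshape(-1), flat[inside], dep[inside])
            self.result.deposited_mev += float(dep[inside].sum())
            self.result.escaped_mev += float(dep[~inside].sum())
        while alive.any():
            idx = np.flatnonzero(alive)
            p, u, en = pos[idx], d[idx], e[idx]
            mu_mass = _NE_WATER * _kn_total_cross_section(en)  # cm^2/g
            mu_max = mu_mass * self._rho_max / 10.0  # per mm
            step = -np.log(rng.uniform(size=idx.size)) / mu_max
            p = p + step[:, None] * u
            flat, inside = self._voxel_flat(p)
            esc = ~inside
            if esc.any():
                self.result.escaped_mev += float(en[esc].sum())
                alive[idx[esc]] = False
            pos[idx] = p
            live = inside
            if not live.any():
                continue
            sub = idx[live]
            rho_here = self._rho_flat[flat[live]]
            real = rng.uniform(size=sub.size) < (mu_mass[live] * rho_here / 10.0
                                                 / mu_max[live])
            hit = sub[real]
            if hit.size == 0:
                continue
            interacted[hit] = True
            eh = e[hit]
            eps, cos_t = _sample_compton(eh, rng)
            e_scat = eps * eh
            t_el = eh - e_scat
            # secondary electrons (isotropic; sub-voxel ranges)
            sec["pos"].append(pos[hit].copy())
            from .nuclear import isotropic_directions
            sec["dir"].append(isotropic_directions(hit.size, rng))
            sec["e"].append(t_el)
            # scattered photon
            phi = rng.uniform(0.0, 2.0 * np.pi, hit.size)
            d[hit] = rotate_directions(d[hit], cos_t, phi)
            e[hit] = e_scat
            absorbed = e_scat <= _GAMMA_CUT
            if absorbed.any():
                ah = hit[absorbed]
                flat_a, inside_a = self._voxel_flat(pos[ah])
                np.add.at(self.dose_energy.reshape(-1), flat_a[inside_a],
                          e[ah][inside_a])
                self.result.deposited_mev += float(e[ah][inside_a].sum())
                alive[ah] = False
        secondaries = None
        if sec["e"]:
            s_pos = np.concatenate(sec["pos"])
            s_dir = np.concatenate(sec["dir"])
            s_e = np.concatenate(sec["e"])
            # transfer the energy out of the gamma ledger into the electron one
            if follow_electrons:
                self.result.initial_mev -= float(s_e.sum())
                self.transport_electrons(s_pos, s_dir, s_e, rng)
            else:
                secondaries = (s_pos, s_dir, s_e)
        return GammaTransportInfo(interacted, secondaries)

    # -- outputs ------------------------------------------------------------

    def photons(self) -> PhotonBatch:
        return PhotonBatch.concatenate(self._photon_parts)

    def dose(self) -> DoseGrid:
        return DoseGrid(self.dose_energy, self.phantom)

    def ledger(self) -> dict:
        r = self.result
        return {
            "initial_mev": r.initial_mev,
            "deposited_mev": r.deposited_mev,
            "escaped_mev": r.escaped_mev,
            "balance": r.deposited_mev + r.escaped_mev - r.initial_mev,
        }


# ---------------------------------------------------------------------------
# Decay-level driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Per-decay Monte Carlo outputs of the radiation-transport stage."""

    n_events: int
    dose: DoseGrid
    emission_counts: np.ndarray  # Cherenkov births per voxel
    photons: PhotonBatch
    ledger: dict
    photon_keep_fraction: float = 1.0


def simulate_decays(phantom: VoxelPhantom, source_config, n_events: int,
                    rng: np.random.Generator, optics_table=None,
                    collect: str = "full", include_gammas: bool = True,
                    n_override: dict | None = None,
                    photon_keep_fraction: float = 1.0,
                    batch: int = 100_000) -> SimulationResult:
    """Simulate n_events disintegrations and score dose and Cherenkov light.

    ``photon_keep_fraction`` thins the stored photon batch (birth counts and
    dose are unaffected); downstream surface intensities must be divided by
    it to recover per-decay units.
    """
    from .nuclear import sample_decay_batch

    engine = TransportEngine(phantom, optics_table=optics_table,
                             collect=collect, n_override=n_override,
                             photon_keep_fraction=photon_keep_fraction)
    done = 0
    while done < n_events:
        n = min(batch, n_events - done)
        ev = sample_decay_batch(source_config, phantom, n, rng)
        engine.transport_electrons(ev.positions, ev.beta_directions,
                                   ev.beta_energies, rng)
        if include_gammas and ev.gamma_energies.size:
            engine.transport_gammas(ev.gamma_positions, ev.gamma_directions,
                                    ev.gamma_energies, rng)
        done += n
    return SimulationResult(
        n_events=n_events,
        dose=engine.dose(),
        emission_counts=engine.emission_counts,
        photons=engine.photons(),
        ledger=engine.ledger(),
        photon_keep_fraction=photon_keep_fraction,
    )
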