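"""I-131 disintegration source.

Each event is one disintegration: a beta electron with energy drawn from the
allowed-transition Fermi spectrum of a randomly chosen branch, plus gamma
photons emitted independently per line with their per-decay intensities.
Emission positions are uniform within the uptake-weighted source VOIs and
all directions are isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import datafiles
from .phantom import VoxelPhantom

__all__ = [
    "SourceConfig",
    "DecayEvent",
    "DecayBatch",
    "BetaSpectrumSampler",
    "sample_decay_event",
    "sample_decay_batch",
    "isotropic_directions",
]

_ALPHA = 1.0 / 137.036
_MEC2 = 0.511  # MeV
_Z_DAUGHTER = 54  # Xe


def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors uniform on the sphere."""
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def fermi_beta_density(e_mev, endpoint_mev: float, z: int = _Z_DAUGHTER):
    """Unnormalised allowed-shape beta spectrum p*W*(Q-E)^2*F(Z,W).

    F is the nonrelativistic Coulomb (Fermi) correction
    2*pi*eta / (1 - exp(-2*pi*eta)) with eta = alpha*Z*W/p for electrons.
    Zero outside (0, endpoint).
    """
    e = np.asarray(e_mev, dtype=float)
    w = 1.0 + e / _MEC2  # total energy, mec^2 units
    p = np.sqrt(np.clip(w**2 - 1.0, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = _ALPHA * z * w / p
        fermi = 2.0 * np.pi * eta / (1.0 - np.exp(-2.0 * np.pi * eta))
    dens = p * w * (endpoint_mev - e) ** 2 * fermi
    return np.where((e > 0) & (e < endpoint_mev), np.nan_to_num(dens), 0.0)


class BetaSpectrumSampler:
    """Inverse-CDF sampler for a multi-branch allowed beta spectrum."""

    def __init__(self, endpoints, intensities, n_grid: int = 4000):
        self.endpoints = np.asarray(endpoints, dtype=float)
        self.intensities = np.asarray(intensities, dtype=float)
        if np.any(self.endpoints <= 0):
            raise ValueError("branch endpoints must be > 0")
        self.intensities = self.intensities / self.intensities.sum()
        self._grids, self._cdfs = [], []
        for q in self.endpoints:
            e = np.linspace(1e-6, q - 1e-9, n_grid)
            d = fermi_beta_density(e, q)
            cdf = np.concatenate([[0.0], np.cumsum((d[1:] + d[:-1]) / 2.0
                                                   * np.diff(e))])
            self._grids.append(e)
            self._cdfs.append(cdf / cdf[-1])

    def density(self, e_mev):
        """Normalised mixture density (1/MeV) of the implemented spectrum."""
        e = np.asarray(e_mev, dtype=float)
        out = np.zeros_like(e)
        for q, w in zip(self.endpoints, self.intensities):
            d = fermi_beta_density(e, q)
            grid = np.linspace(1e-6, q - 1e-9, 8000)
            norm = np.trapezoid(fermi_beta_density(grid, q), grid)
            out = out + w * d / norm
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        branch = rng.choice(len(self.endpoints), size=n, p=self.intensities)
        u = rng.uniform(size=n)
        out = np.empty(n)
        for i in range(len(self.endpoints)):
            sel = branch == i
            out[sel] = np.interp(u[sel], self._cdfs[i], self._grids[i])
        return out


@dataclass
class SourceConfig:
    """Uptake split over VOIs plus beta branch and gamma line tables."""

    uptake: dict[str, float] = field(default_factory=lambda: {"tumour": 1.0})
    beta_endpoints: np.ndarray = None
    beta_intensities: np.ndarray = None
    gamma_energies: np.ndarray = None
    gamma_intensities: np.ndarray = None

    def __post_init__(self):
        if self.beta_endpoints is None:
            self.beta_endpoints, self.beta_intensities = datafiles.load_beta_branches()
        if self.gamma_energies is None:
            self.gamma_energies, self.gamma_intensities = datafiles.load_gamma_lines()
        total = sum(self.uptake.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"uptake fractions sum to {total}, expected 1")
        self._sampler = BetaSpectrumSampler(self.beta_endpoints,
                                            self.beta_intensities)

    @property
    def beta_sampler(self) -> BetaSpectrumSampler:
        return self._sampler


@dataclass
class DecayEvent:
    """One disintegration: beta particle plus a list of gamma photons."""

    position: np.ndarray  # mm
    beta_energy: float  # MeV
    beta_direction: np.ndarray
    gammas: list  # [(energy MeV, direction), ...]


@dataclass
class DecayBatch:
    """A vectorized batch of disintegrations."""

    positions: np.ndarray  # (n, 3) mm
    beta_energies: np.ndarray  # (n,) MeV
    beta_directions: np.ndarray  # (n, 3)
    gamma_energies: np.ndarray  # (m,) MeV, flattened over events
    gamma_positions: np.ndarray  # (m, 3) mm
    gamma_directions: np.ndarray  # (m, 3)
    voi_choice: np.ndarray  # (n,) index into the uptake VOI list
    voi_names: list

    def __len__(self) -> int:
        return self.positions.shape[0]


def _sample_positions_in_mask(mask: np.ndarray, phantom: VoxelPhantom,
                              n: int, rng: np.random.Generator) -> np.ndarray:
    flat = np.flatnonzero(mask)
    if flat.size == 0:
        raise ValueError("source VOI mask is empty")
    pick = rng.integers(0, flat.size, n)
    idx = np.column_stack(np.unravel_index(flat[pick], mask.shape))
    offset = rng.uniform(size=(n, 3))
    return phantom.origin + (idx + offset) * phantom.spacing


def sample_decay_batch(config: SourceConfig, phantom: VoxelPhantom,
                       n: int, rng: np.random.Generator) -> DecayBatch:
    """Sample n disintegrations (positions, beta particles, gamma photons)."""
    names = list(config.uptake.keys())
    fractions = np.array([config.uptake[k] for k in names])
    choice = rng.choice(len(names), size=n, p=fractions)
    positions = np.empty((n, 3))
    for i, name in enumerate(names):
        sel = choice == i
        if sel.any():
            positions[sel] = _sample_positions_in_mask(
                phantom.voi_masks[name], phantom, int(sel.sum()), rng)

    beta_e = config.beta_sampler.sample(n, rng)
    beta_dir = isotropic_directions(n, rng)

    emit = rng.uniform(size=(n, config.gamma_energies.size)) < config.gamma_intensities
    ev_idx, line_idx = np.nonzero(emit)
    gamma_e = config.gamma_energies[line_idx]
    gamma_pos = positions[ev_idx]
    gamma_dir = isotropic_directions(ev_idx.size, rng)

    return DecayBatch(positions, beta_e, beta_dir, gamma_e, gamma_pos,
                      gamma_dir, choice, names)


def sample_decay_event(config: SourceConfig, phantom: VoxelPhantom,
                       rng: np.random.Generator) -> DecayEvent:
    """Sample a single disintegration (convenience wrapper)."""
    b = sample_decay_batch(config, phantom, 1, rng)
    gammas = [(float(e), d) for e, d in zip(b.gamma_energies, b.gamma_directions)]
    return DecayEvent(b.positions[0], float(b.beta_energies[0]),
                      b.beta_directions[0], gammas)
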