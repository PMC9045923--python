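"""Optical Monte Carlo: Cherenkov photon propagation to the surface.

Analog (unweighted) photon transport through the voxelized optical medium:
free paths are exponential in the local total interaction coefficient
mu_t = mu_a + mu_s with remaining-optical-depth bookkeeping across voxel
boundaries (no resampling bias in heterogeneous media); at an interaction
the photon is absorbed with probability mu_a/mu_t, otherwise scattered into
a Henyey-Greenstein direction; Fresnel reflection/refraction (unpolarized)
is applied at every voxel boundary where the material refractive index
changes, including total internal reflection.  Photons crossing the outer
grid boundary are scored with their exit position, direction, wavelength
and birth position; the ambient medium is air (n = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


from .phantom import VoxelPhantom
from .transport import PhotonBatch

__all__ = [
    "sample_scatter_direction",
    "henyey_greenstein_cosines",
    "fresnel_reflectance",
    "fresnel_interface",
    "ExitRecords",
    "SurfaceLightMap",
    "OpticalTransport",
    "propagate_photon",
]


def henyey_greenstein_cosines(g, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n scattering-angle cosines from the Henyey-Greenstein density."""
    g = np.broadcast_to(np.asarray(g, dtype=float), (n,))
    u = rng.uniform(size=n)
    iso = np.abs(g) < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (1.0 - g**2) / (1.0 - g + 2.0 * g * u)
        cos_t = (1.0 + g**2 - frac**2) / (2.0 * g)
    return np.clip(np.where(iso, 1.0 - 2.0 * u, cos_t), -1.0, 1.0)


def sample_scatter_direction(g: float, incoming: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """One Henyey-Greenstein scatter of a unit direction vector."""
    from .transport import rotate_directions

    if not abs(g) < 1.0:
        raise ValueError("requires |g| < 1")
    cos_t = henyey_greenstein_cosines(g, 1, rng)
    phi = rng.uniform(0.0, 2.0 * np.pi, 1)
    return rotate_directions(np.atleast_2d(incoming).astype(float),
                             cos_t, phi)[0]


def fresnel_reflectance(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance; 1.0 beyond the critical angle."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    cos_i = np.clip(np.asarray(cos_i, dtype=float), 0.0, 1.0)
    sin2_t = (n1 / n2) ** 2 * (1.0 - cos_i**2)
    tir = sin2_t > 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
    rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
    rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    out = np.where(tir, 1.0, (rs + rp) / 2.0)
    return float(out) if out.ndim == 0 else out


def fresnel_interface(n1: float, n2: float, incident: np.ndarray,
                      normal: np.ndarray, rng: np.random.Generator):
    """Stochastic reflect-or-refract decision at an index interface.

    ``normal`` points from medium 1 into medium 2.  Returns
    (reflected: bool, new_direction).
    """
    d = np.asarray(incident, dtype=float)
    nrm = np.asarray(normal, dtype=float)
    cos_i = float(np.dot(d, nrm))
    if cos_i < 0:
        raise ValueError("incident direction must point into medium 2")
    r = fresnel_reflectance(n1, n2, cos_i)
    if rng.uniform() < r:
        return True, d - 2.0 * cos_i * nrm
    ratio = n1 / n2
    sin2_t = ratio**2 * (1.0 - cos_i**2)
    cos_t = np.sqrt(1.0 - sin2_t)
    new = ratio * d + (cos_t - ratio * cos_i) * nrm
    return False, new / np.linalg.norm(new)


@dataclass
class ExitRecords:
    """Surface-exit records of scored photons."""

    positions: np.ndarray  # (k, 3) mm, exit point on the grid boundary
    directions: np.ndarray  # (k, 3), refracted outgoing direction
    wavelengths: np.ndarray  # (k,) nm
    birth_positions: np.ndarray  # (k, 3) mm
    exit_axis: np.ndarray  # (k,) 0/1/2, boundary axis crossed
    exit_sign: np.ndarray  # (k,) -1 or +1, outward side along that axis

    def __len__(self) -> int:
        return self.positions.shape[0]

    def in_band(self, band) -> np.ndarray:
        """Boolean mask of records in the half-open band [lo, hi) nm."""
        lo, hi = band
        if not lo < hi:
            raise ValueError("empty spectral band")
        return (self.wavelengths >= lo) & (self.wavelengths < hi)

    def anterior(self) -> np.ndarray:
        """Mask of photons exiting through the anterior face (y = min)."""
        return (self.exit_axis == 1) & (self.exit_sign == -1)

    def subset(self, mask: np.ndarray) -> "ExitRecords":
        return ExitRecords(self.positions[mask], self.directions[mask],
                           self.wavelengths[mask], self.birth_positions[mask],
                           self.exit_axis[mask], self.exit_sign[mask])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "exit_x_mm": self.positions[:, 0],
            "exit_y_mm": self.positions[:, 1],
            "exit_z_mm": self.positions[:, 2],
            "wavelength_nm": self.wavelengths,
            "birth_x_mm": self.birth_positions[:, 0],
            "birth_y_mm": self.birth_positions[:, 1],
            "birth_z_mm": self.birth_positions[:, 2],
            "exit_axis": self.exit_axis,
            "exit_sign": self.exit_sign,
        })


@dataclass
class SurfaceLightMap:
    """2D exit-photon count map on the anterior bounding plane (x, z)."""

    counts: np.ndarray  # (nx_bins, nz_bins)
    x_edges: np.ndarray
    z_edges: np.ndarray
    band: tuple

    @classmethod
    def from_records(cls, records: ExitRecords, phantom: VoxelPhantom,
                     band=(500.0, 1200.0 + 1e-9), bin_mm: float = 1.0,
                     anterior_only: bool = True) -> "SurfaceLightMap":
        mask = records.in_band(band)
        if anterior_only:
            mask &= records.anterior()
        r = records.subset(mask)
        x0 = phantom.origin[0]
        x1 = x0 + phantom.shape[0] * phantom.spacing[0]
        z0 = phantom.origin[2]
        z1 = z0 + phantom.shape[2] * phantom.spacing[2]
        x_edges = np.arange(x0, x1 + bin_mm, bin_mm)
        z_edges = np.arange(z0, z1 + bin_mm, bin_mm)
        counts, _, _ = np.histogram2d(r.positions[:, 0], r.positions[:, 2],
                                      bins=[x_edges, z_edges])
        return cls(counts, x_edges, z_edges, band)


class OpticalTransport:
    """Analog photon transport over one voxel phantom.

    Two interchangeable backends implement the same physics: a compiled
    per-photon kernel (default, fast) and a vectorized numpy engine kept as
    a readable reference; ``engine`` selects 'numba', 'numpy' or 'auto'.
    """

    MAX_EVENTS = 500_000

    def __init__(self, phantom: VoxelPhantom, optics_table,
                 engine: str = "auto"):
        from ._optical_kernel import HAVE_NUMBA

        if engine == "auto":
            engine = "numba" if HAVE_NUMBA else "numpy"
        if engine not in ("numba", "numpy"):
            raise ValueError("engine must be 'auto', 'numba' or 'numpy'")
        self.engine = engine
        self.phantom = phantom
        MA, MS, G, N = optics_table.as_arrays()
        self.mu_a = MA * 0.1  # per mm
        self.mu_s = MS * 0.1
        self.g = G
        self.n = N
        self.wl0 = float(optics_table.wavelengths[0])
        self.nwl = optics_table.wavelengths.size
        self.n_absorbed = 0
        self.n_exited = 0

    def _wl_index(self, wavelengths):
        return np.clip(np.rint(wavelengths - self.wl0).astype(np.int64),
                       0, self.nwl - 1)

    def propagate(self, photons: PhotonBatch,
                  rng: np.random.Generator) -> ExitRecords:
        """Propagate a photon batch; returns the surface-exit records."""
        if self.engine == "numba":
            return self._propagate_kernel(photons, rng)
        return self._propagate_numpy(photons, rng)

    def _propagate_kernel(self, photons: PhotonBatch,
                          rng: np.random.Generator) -> ExitRecords:
        from ._optical_kernel import propagate_kernel

        ph = self.phantom
        n_ph = len(photons)
        if n_ph == 0:
            z3 = np.zeros((0, 3))
            return ExitRecords(z3, z3.copy(), np.zeros(0), z3.copy(),
                               np.zeros(0, dtype=np.int64),
                               np.zeros(0, dtype=np.int8))
        seed = int(rng.integers(0, 2**31 - 1))
        wli = self._wl_index(photons.wavelengths)
        status, e_pos, e_dir, e_axis, e_sign = propagate_kernel(
            np.ascontiguousarray(photons.positions, dtype=np.float64),
            np.ascontiguousarray(photons.directions, dtype=np.float64),
            wli, ph.labels, self.mu_a, self.mu_s, self.g, self.n,
            ph.origin.astype(np.float64), ph.spacing.astype(np.float64), seed)
        exited = status == 1
        self.n_exited += int(exited.sum())
        self.n_absorbed += int((~exited).sum())
        return ExitRecords(e_pos[exited], e_dir[exited],
                           photons.wavelengths[exited],
                           photons.birth_positions[exited],
                           e_axis[exited].astype(np.int64), e_sign[exited])

    def _propagate_numpy(self, photons: PhotonBatch,
                         rng: np.random.Generator) -> ExitRecords:
        from .transport import rotate_directions

        ph = self.phantom
        shape = np.array(ph.shape)
        n_ph = len(photons)
        pos = photons.positions.copy()
        d = photons.directions.copy()
        wl = photons.wavelengths.copy()
        birth = photons.birth_positions.copy()
        wli = self._wl_index(wl)
        idx = np.floor((pos - ph.origin) / ph.spacing).astype(np.int64)
        idx = np.clip(idx, 0, shape - 1)
        alive = np.ones(n_ph, dtype=bool)
        tau = rng.exponential(size=n_ph)

        out = {k: [] for k in ("pos", "dir", "wl", "birth", "axis", "sign")}
        labels = ph.labels
        spacing = ph.spacing
        origin = ph.origin
        n_events = 0
        while alive.any():
            n_events += 1
            if n_events > self.MAX_EVENTS:
                raise RuntimeError("optical transport exceeded event budget")
            ai = np.flatnonzero(alive)
            p = pos[ai]
            u = d[ai]
            ix = idx[ai]
            w = wli[ai]
            mat = labels[ix[:, 0], ix[:, 1], ix[:, 2]].astype(np.int64)
            mu_a = self.mu_a[mat, w]
            mu_s = self.mu_s[mat, w]
            mu_t = mu_a + mu_s
            n1 = self.n[mat, w]

            lo = origin + ix * spacing
            hi = lo + spacing
            with np.errstate(divide="ignore", invalid="ignore"):
                t_pos = (hi - p) / u
                t_neg = (lo - p) / u
            t_axis = np.where(u > 1e-12, t_pos,
                              np.where(u < -1e-12, t_neg, np.inf))
            t_axis = np.clip(t_axis, 0.0, None)
            axis = np.argmin(t_axis, axis=1)
            t_b = t_axis[np.arange(t_axis.shape[0]), axis]

            with np.errstate(divide="ignore"):
                s_int = np.where(mu_t > 0, tau[ai] / np.where(mu_t > 0, mu_t, 1.0),
                                 np.inf)
            interact = s_int <= t_b

            # --- interactions -------------------------------------------------
            if interact.any():
                ii = ai[interact]
                pos[ii] = p[interact] + s_int[interact, None] * u[interact]
                absorb = (rng.uniform(size=ii.size)
                          < mu_a[interact] / mu_t[interact])
                dead = ii[absorb]
                alive[dead] = False
                self.n_absorbed += dead.size
                scat = ii[~absorb]
                if scat.size:
                    gg = self.g[mat[interact][~absorb], w[interact][~absorb]]
                    cos_t = henyey_greenstein_cosines(gg, scat.size, rng)
                    phi = rng.uniform(0.0, 2.0 * np.pi, scat.size)
                    d[scat] = rotate_directions(d[scat], cos_t, phi)
                    tau[scat] = rng.exponential(size=scat.size)

            # --- boundary crossings -------------------------------------------
            cross = ~interact
            if not cross.any():
                continue
            ci = ai[cross]
            axc = axis[cross]
            tb = t_b[cross]
            pos[ci] = p[cross] + tb[:, None] * u[cross]
            tau[ci] = np.maximum(tau[ci] - mu_t[cross] * tb, 0.0)
            sgn = np.sign(d[ci, axc]).astype(np.int64)
            nxt = idx[ci].copy()
            nxt[np.arange(ci.size), axc] += sgn
            outside = (nxt[np.arange(ci.size), axc] < 0) | (
                nxt[np.arange(ci.size), axc] >= shape[axc])
            n2 = np.ones(ci.size)
            inb = ~outside
            if inb.any():
                mat2 = labels[nxt[inb, 0], nxt[inb, 1], nxt[inb, 2]].astype(np.int64)
                n2[inb] = self.n[mat2, wli[ci][inb]]
            n1c = n1[cross]
            cos_i = np.abs(d[ci, axc])
            refl_prob = np.where(np.abs(n1c - n2) > 1e-12,
                                 fresnel_reflectance(n1c, n2, cos_i), 0.0)
            reflect = rng.uniform(size=ci.size) < refl_prob
            # reflection: flip the crossing component, stay in the voxel
            ri = ci[reflect]
            if ri.size:
                d[ri, axc[reflect]] *= -1.0
            # transmission: Snell-bend where n differs, then advance
            tr = ~reflect
            if tr.any():
                ti = ci[tr]
                axt = axc[tr]
                bend = np.abs(n1c[tr] - n2[tr]) > 1e-12
                if bend.any():
                    bi = ti[bend]
                    axb = axt[bend]
                    ratio = n1c[tr][bend] / n2[tr][bend]
                    ci_b = cos_i[tr][bend]
                    sin2t = ratio**2 * (1.0 - ci_b**2)
                    cost = np.sqrt(np.clip(1.0 - sin2t, 0.0, None))
                    nd = d[bi] * ratio[:, None]
                    nd[np.arange(bi.size), axb] = (np.sign(d[bi, axb])
                                                   * cost)
                    nd /= np.linalg.norm(nd, axis=1, keepdims=True)
                    d[bi] = nd
                ex = outside[tr]
                if ex.any():
                    ei = ti[ex]
                    out["pos"].append(pos[ei].copy())
                    out["dir"].append(d[ei].copy())
                    out["wl"].append(wl[ei].copy())
                    out["birth"].append(birth[ei].copy())
                    out["axis"].append(axt[ex].copy())
                    out["sign"].append(np.sign(d[ei, axt[ex]]).astype(np.int8))
                    alive[ei] = False
                    self.n_exited += ei.size
                stay = ~ex
                if stay.any():
                    si = ti[stay]
                    idx[si] = nxt[tr][stay]

        if out["pos"]:
            return ExitRecords(
                np.concatenate(out["pos"]), np.concatenate(out["dir"]),
                np.concatenate(out["wl"]), np.concatenate(out["birth"]),
                np.concatenate(out["axis"]), np.concatenate(out["sign"]))
        z3 = np.zeros((0, 3))
        return ExitRecords(z3, z3.copy(), np.zeros(0), z3.copy(),
                           np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int8))


def propagate_photon(photon_position, direction, wavelength_nm,
                     phantom: VoxelPhantom, optics_table,
                     rng: np.random.Generator):
    """Propagate a single photon; returns ('absorbed', None) or
    ('exited', ExitRecords-of-one)."""
    batch = PhotonBatch(
        np.atleast_2d(photon_position).astype(float),
        np.atleast_2d(direction).astype(float),
        np.atleast_1d(float(wavelength_nm)),
        np.atleast_2d(photon_position).astype(float),
    )
    engine = OpticalTransport(phantom, optics_table)
    rec = engine.propagate(batch, rng)
    if len(rec):
        return "exited", rec
    return "absorbed", None
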