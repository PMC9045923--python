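"""Numba kernel for analog optical photon transport.

Scalar per-photon implementation of exactly the physics in
``photons.OpticalTransport``: exponential free paths with remaining
optical-depth bookkeeping across voxel boundaries, absorb-or-scatter
interactions, Henyey-Greenstein phase function, unpolarized Fresnel
reflection/refraction at refractive-index boundaries, exit scoring at the
grid boundary.  Kept separate so the pure-numpy engine remains available as
a reference implementation.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speed dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _rotate(ux, uy, uz, cos_t, phi):
    sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 0.0))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        sgn = 1.0 if uz >= 0 else -1.0
        vx = sin_t * cp
        vy = sin_t * sp * sgn
        vz = cos_t * sgn
    else:
        den = math.sqrt(max(1.0 - uz * uz, 1e-12))
        vx = sin_t * (ux * uz * cp - uy * sp) / den + ux * cos_t
        vy = sin_t * (uy * uz * cp + ux * sp) / den + uy * cos_t
        vz = -sin_t * cp * den + uz * cos_t
    norm = math.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


@njit(cache=True)
def _fresnel_r(n1, n2, cos_i):
    sin2_t = (n1 / n2) ** 2 * (1.0 - cos_i * cos_i)
    if sin2_t > 1.0:
        return 1.0
    cos_t = math.sqrt(max(1.0 - sin2_t, 0.0))
    rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
    rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    return 0.5 * (rs + rp)


@njit(cache=True)
def propagate_kernel(pos, direction, wl_idx, labels, MA, MS, G, N,
                     origin, spacing, seed):
    """Propagate photons; returns (status, exit_pos, exit_dir, axis, sign).

    status: 0 = absorbed, 1 = exited.  MA/MS are per-mm coefficients indexed
    (material, wavelength).
    """
    np.random.seed(seed)
    nph = pos.shape[0]
    nx, ny, nz = labels.shape
    status = np.zeros(nph, dtype=np.int8)
    e_pos = np.zeros((nph, 3))
    e_dir = np.zeros((nph, 3))
    e_axis = np.zeros(nph, dtype=np.int8)
    e_sign = np.zeros(nph, dtype=np.int8)

    for i in range(nph):
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        ux, uy, uz = direction[i, 0], direction[i, 1], direction[i, 2]
        w = wl_idx[i]
        ix = int((px - origin[0]) / spacing[0])
        iy = int((py - origin[1]) / spacing[1])
        iz = int((pz - origin[2]) / spacing[2])
        if ix < 0:
            ix = 0
        if iy < 0:
            iy = 0
        if iz < 0:
            iz = 0
        if ix > nx - 1:
            ix = nx - 1
        if iy > ny - 1:
            iy = ny - 1
        if iz > nz - 1:
            iz = nz - 1
        tau = -math.log(np.random.random())
        alive = True
        for _ in range(2_000_000):
            if not alive:
                break
            mat = labels[ix, iy, iz]
            mu_a = MA[mat, w]
            mu_s = MS[mat, w]
            mu_t = mu_a + mu_s

            # distance to the nearest voxel face along the direction
            t_b = 1e30
            axis = 0
            if ux > 1e-12:
                t = (origin[0] + (ix + 1) * spacing[0] - px) / ux
                if t < t_b:
                    t_b = t
                    axis = 0
            elif ux < -1e-12:
                t = (origin[0] + ix * spacing[0] - px) / ux
                if t < t_b:
                    t_b = t
                    axis = 0
            if uy > 1e-12:
                t = (origin[1] + (iy + 1) * spacing[1] - py) / uy
                if t < t_b:
                    t_b = t
                    axis = 1
            elif uy < -1e-12:
                t = (origin[1] + iy * spacing[1] - py) / uy
                if t < t_b:
                    t_b = t
                    axis = 1
            if uz > 1e-12:
                t = (origin[2] + (iz + 1) * spacing[2] - pz) / uz
                if t < t_b:
                    t_b = t
                    axis = 2
            elif uz < -1e-12:
                t = (origin[2] + iz * spacing[2] - pz) / uz
                if t < t_b:
                    t_b = t
                    axis = 2
            if t_b < 0.0:
                t_b = 0.0

            if mu_t > 0.0:
                s_int = tau / mu_t
            else:
                s_int = 1e30

            if s_int <= t_b:
                # interaction
                px += s_int * ux
                py += s_int * uy
                pz += s_int * uz
                if np.random.random() < mu_a / mu_t:
                    alive = False  # absorbed
                    break
                g = G[mat, w]
                u_r = np.random.random()
                if abs(g) < 1e-8:
                    cos_t = 1.0 - 2.0 * u_r
                else:
                    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u_r)
                    cos_t = (1.0 + g * g - frac * frac) / (2.0 * g)
                    if cos_t > 1.0:
                        cos_t = 1.0
                    elif cos_t < -1.0:
                        cos_t = -1.0
                phi = 2.0 * math.pi * np.random.random()
                ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi)
                tau = -math.log(np.random.random())
                continue

            # boundary crossing
            px += t_b * ux
            py += t_b * uy
            pz += t_b * uz
            tau -= mu_t * t_b
            if tau < 0.0:
                tau = 0.0
            if axis == 0:
                comp = ux
            elif axis == 1:
                comp = uy
            else:
                comp = uz
            sgn = 1 if comp > 0 else -1
            jx, jy, jz = ix, iy, iz
            if axis == 0:
                jx += sgn
            elif axis == 1:
                jy += sgn
            else:
                jz += sgn
            outside = jx < 0 or jx >= nx or jy < 0 or jy >= ny \
                or jz < 0 or jz >= nz
            n1 = N[mat, w]
            if outside:
                n2 = 1.0
            else:
                n2 = N[labels[jx, jy, jz], w]
            if abs(n1 - n2) > 1e-12:
                cos_i = abs(comp)
                if np.random.random() < _fresnel_r(n1, n2, cos_i):
                    # reflect: flip the crossing component
                    if axis == 0:
                        ux = -ux
                    elif axis == 1:
                        uy = -uy
                    else:
                        uz = -uz
                    continue
                # refract (Snell bend in the face plane)
                ratio = n1 / n2
                sin2_t = ratio * ratio * (1.0 - cos_i * cos_i)
                cos_t = math.sqrt(max(1.0 - sin2_t, 0.0))
                ux *= ratio
                uy *= ratio
                uz *= ratio
                if axis == 0:
                    ux = cos_t if comp > 0 else -cos_t
                elif axis == 1:
                    uy = cos_t if comp > 0 else -cos_t
                else:
                    uz = cos_t if comp > 0 else -cos_t
                norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
            if outside:
                status[i] = 1
                e_pos[i, 0] = px
                e_pos[i, 1] = py
                e_pos[i, 2] = pz
                e_dir[i, 0] = ux
                e_dir[i, 1] = uy
                e_dir[i, 2] = uz
                e_axis[i] = axis
                e_sign[i] = sgn
                alive = False
                break
            ix, iy, iz = jx, jy, jz
    return status, e_pos, e_dir, e_axis, e_sign
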