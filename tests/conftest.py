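"""Shared fixtures: homogeneous box phantoms, slab optics tables, and a
coarse papillary-carcinoma neck phantom."""

from __future__ import annotations

import numpy as np
import pytest

from cherenkovmrt.materials import Material
from cherenkovmrt.optics import MaterialOptics, OpticalPropertyTable
from cherenkovmrt.phantom import PhantomConfig, VoxelPhantom, build_neck_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_box_phantom(n=40, voxel_mm=2.0, material=Material.THYROID,
                     density=1.05) -> VoxelPhantom:
    """Homogeneous cube phantom with an 'all' source mask."""
    labels = np.full((n, n, n), int(material), dtype=np.int8)
    ph = VoxelPhantom(
        spacing=np.array([voxel_mm] * 3),
        origin=-np.array([n * voxel_mm / 2.0] * 3),
        labels=labels,
        density=np.full((n, n, n), density),
        voi_masks={},
    )
    ph.voi_masks["all"] = np.ones((n, n, n), dtype=bool)
    return ph


def make_slab_table(mu_a_cm=0.3, mu_s_cm=10.0, g=0.9, n=1.4,
                    material=Material.THYROID) -> OpticalPropertyTable:
    """Single-material optical table with spectrally flat properties."""
    t = OpticalPropertyTable()
    wl = t.wavelengths
    t.materials[material] = MaterialOptics(
        np.full_like(wl, float(mu_a_cm)), np.full_like(wl, float(mu_s_cm)),
        np.full_like(wl, float(g)), np.full_like(wl, float(n)))
    t.materials[Material.AIR] = MaterialOptics(
        np.zeros_like(wl), np.zeros_like(wl), np.zeros_like(wl),
        np.ones_like(wl))
    return t


@pytest.fixture
def box_phantom():
    return make_box_phantom()


@pytest.fixture(scope="session")
def ptc_phantom():
    """Coarse (2 mm) papillary thyroid carcinoma neck phantom."""
    cfg = PhantomConfig.for_treatment("ptc", voxel_mm=(2.0, 2.0, 2.0))
    return build_neck_phantom(cfg)


@pytest.fixture(scope="session")
def default_optics():
    from cherenkovmrt.optics import build_optical_table

    return build_optical_table()
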