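"""Spectrally resolved tissue optical properties.

Absorption is a chromophore mixture,

    mu_a(lam) = SO2*mu_HbO2 + (1-SO2)*mu_Hb + W*mu_water + F*mu_fat + M*mu_mel,

scattering follows the Rayleigh + Mie decomposition of the reduced
scattering coefficient,

    mu_s'(lam) = a * [f_Ray (lam/lam0)^-4 + (1 - f_Ray) (lam/lam0)^-b_Mie],
    mu_s      = mu_s' / (1 - g),

with lam0 = 500 nm, and refractive indices are material-specific: constants
for bone (1.55), thyroid (1.40) and tumour (1.39), Sellmeier-form dispersion
for adipose, Cauchy-form dispersion for skin, and a bundled table for muscle.
Tumour properties are the thyroid's with +44% absorption, -30% scattering,
n = 1.39 and g = 0.9.  Inter-patient variability enters as simultaneous
up/down scaling of every perturbable material's mu_a, mu_s, n and g.

All properties live on a common 1 nm wavelength grid spanning 500-1200 nm;
knot tables are linearly interpolated onto it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import datafiles
from .materials import Material

__all__ = [
    "WAVELENGTH_NM",
    "ChromophoreBasis",
    "TissueComposition",
    "ScatteringModelParams",
    "OpticalPropertyTable",
    "compute_mu_a",
    "compute_scattering",
    "refractive_index",
    "apply_tumour_contrast",
    "perturb_parameters",
    "build_optical_table",
    "melanin_absorption",
]

LAMBDA_MIN, LAMBDA_MAX = 500.0, 1200.0
#: Common wavelength grid (1 nm resolution).
WAVELENGTH_NM = np.arange(LAMBDA_MIN, LAMBDA_MAX + 1.0)

#: Table of inter-patient variability percentages (mu_a, mu_s, n, g) applied
#: simultaneously up or down; skin and bone are held fixed.
VARIABILITY_PCT: dict[Material, tuple[float, float, float, float]] = {
    Material.ADIPOSE: (9.9, 8.9, 0.6, 0.0),
    Material.MUSCLE: (9.9, 8.9, 1.1, 0.0),
    Material.THYROID: (5.8, 3.0, 2.0, 2.15),
    Material.TUMOUR: (6.6, 4.6, 2.0, 0.0),
}


def melanin_absorption(lam):
    """Melanosome interior absorption, mu_a = 1.70e12 * lam^-3.48 cm^-1."""
    return 1.70e12 * np.asarray(lam, dtype=float) ** -3.48


def _check_range(lam):
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < LAMBDA_MIN) or np.any(lam > LAMBDA_MAX):
        raise ValueError(f"wavelength outside {LAMBDA_MIN:.0f}-{LAMBDA_MAX:.0f} nm")
    return lam


@dataclass
class ChromophoreBasis:
    """Chromophore absorption spectra (cm^-1) on a common wavelength grid."""

    wavelengths: np.ndarray
    mu_hbo2: np.ndarray
    mu_hb: np.ndarray
    mu_water: np.ndarray
    mu_fat: np.ndarray
    mu_mel: np.ndarray

    @classmethod
    def default(cls) -> "ChromophoreBasis":
        knots = datafiles.load_chromophores()
        wl = WAVELENGTH_NM
        interp = lambda col: np.interp(wl, knots["wavelength_nm"], knots[col])
        return cls(
            wavelengths=wl,
            mu_hbo2=interp("mu_hbo2"),
            mu_hb=interp("mu_hb"),
            mu_water=interp("mu_water"),
            mu_fat=interp("mu_fat"),
            mu_mel=melanin_absorption(wl),
        )

    def at(self, name: str, lam):
        lam = _check_range(lam)
        return np.interp(lam, self.wavelengths, getattr(self, name))


@dataclass(frozen=True)
class TissueComposition:
    """Fractional chromophore composition of a tissue."""

    so2: float
    water: float
    fat: float
    melanin: float = 0.0

    def __post_init__(self):
        for name in ("so2", "water", "fat", "melanin"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ScatteringModelParams:
    """Rayleigh/Mie reduced-scattering model parameters."""

    a: float  # cm^-1, reduced scattering at lam0
    f_ray: float
    b_mie: float
    lam0: float = 500.0

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("scattering amplitude a must be >= 0")
        if not 0.0 <= self.f_ray <= 1.0:
            raise ValueError("f_ray outside [0, 1]")


def compute_mu_a(comp: TissueComposition, basis: ChromophoreBasis, lam):
    """Absorption coefficient (cm^-1) of a tissue at wavelength(s) lam (nm)."""
    lam = _check_range(lam)
    return (comp.so2 * basis.at("mu_hbo2", lam)
            + (1.0 - comp.so2) * basis.at("mu_hb", lam)
            + comp.water * basis.at("mu_water", lam)
            + comp.fat * basis.at("mu_fat", lam)
            + comp.melanin * basis.at("mu_mel", lam))


def compute_scattering(params: ScatteringModelParams, g, lam):
    """Reduced and full scattering coefficients (mu_s', mu_s) in cm^-1."""
    g = np.asarray(g, dtype=float)
    if np.any(g >= 1.0):
        raise ValueError("invalid anisotropy: g must be < 1")
    lam = np.asarray(lam, dtype=float)
    x = lam / params.lam0
    mu_s_prime = params.a * (params.f_ray * x**-4
                             + (1.0 - params.f_ray) * x**-params.b_mie)
    return mu_s_prime, mu_s_prime / (1.0 - g)


# Sellmeier coefficients for adipose (single-term) and Cauchy coefficients
# for skin; both give n in the 500-1200 nm range.
_ADIPOSE_SELLMEIER_B1 = 1.1236
_ADIPOSE_SELLMEIER_C1 = 10000.0  # nm^2
_SKIN_CAUCHY = (1.3696, 3916.8, 2.5588e8)  # A + B/lam^2 + C/lam^4


def refractive_index(material: Material | str, lam=750.0):
    """Refractive index of a material at wavelength lam (nm)."""
    if isinstance(material, str):
        try:
            material = Material[material.upper()]
        except KeyError:
            raise ValueError(f"unknown material {material!r}") from None
    lam = np.asarray(lam, dtype=float)
    if material == Material.AIR:
        return np.broadcast_to(np.float64(1.0), lam.shape).copy() if lam.ndim else 1.0
    if material == Material.BONE:
        return np.full_like(lam, 1.55) if lam.ndim else 1.55
    if material == Material.THYROID:
        return np.full_like(lam, 1.40) if lam.ndim else 1.40
    if material == Material.TUMOUR:
        return np.full_like(lam, 1.39) if lam.ndim else 1.39
    if material == Material.ADIPOSE:
        n2 = 1.0 + _ADIPOSE_SELLMEIER_B1 * lam**2 / (lam**2 - _ADIPOSE_SELLMEIER_C1)
        return np.sqrt(n2)
    if material == Material.SKIN:
        A, B, C = _SKIN_CAUCHY
        return A + B / lam**2 + C / lam**4
    if material == Material.MUSCLE:
        t = datafiles.load_muscle_n()
        return np.interp(lam, t["wavelength_nm"], t["n"])
    raise ValueError(f"unknown material {material!r}")


@dataclass
class MaterialOptics:
    """Optical properties of one material on the common wavelength grid."""

    mu_a: np.ndarray  # cm^-1
    mu_s: np.ndarray  # cm^-1
    g: np.ndarray
    n: np.ndarray

    def copy(self) -> "MaterialOptics":
        return MaterialOptics(self.mu_a.copy(), self.mu_s.copy(),
                              self.g.copy(), self.n.copy())

    @property
    def mu_s_prime(self) -> np.ndarray:
        return self.mu_s * (1.0 - self.g)


@dataclass
class OpticalPropertyTable:
    """Per-material optical properties on the common wavelength grid."""

    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTH_NM.copy())
    materials: dict[Material, MaterialOptics] = field(default_factory=dict)
    variant: str = "baseline"

    def copy(self) -> "OpticalPropertyTable":
        return OpticalPropertyTable(
            self.wavelengths.copy(),
            {m: mo.copy() for m, mo in self.materials.items()},
            self.variant,
        )

    def n_ref(self, material: Material, lam: float = 750.0) -> float:
        mo = self.materials[Material(material)]
        return float(np.interp(lam, self.wavelengths, mo.n))

    def as_arrays(self):
        """Stack properties as (n_materials, n_wavelengths) arrays indexed by
        Material value; used by the transport engines for O(1) lookup."""
        nmat = max(int(m) for m in Material) + 1
        nwl = self.wavelengths.size
        MA = np.zeros((nmat, nwl))
        MS = np.zeros((nmat, nwl))
        G = np.zeros((nmat, nwl))
        N = np.ones((nmat, nwl))
        for mat, mo in self.materials.items():
            MA[int(mat)] = mo.mu_a
            MS[int(mat)] = mo.mu_s
            G[int(mat)] = mo.g
            N[int(mat)] = mo.n
        return MA, MS, G, N

    # -- delimited-text I/O -------------------------------------------------

    def to_csv(self, directory):
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for mat, mo in self.materials.items():
            out = np.column_stack([self.wavelengths, mo.mu_a, mo.mu_s, mo.g, mo.n])
            np.savetxt(
                directory / f"optics_{mat.name.lower()}.csv", out,
                delimiter=",", header="wavelength_nm,mu_a,mu_s,g,n", comments="")

    @classmethod
    def from_csv(cls, directory) -> "OpticalPropertyTable":
        from pathlib import Path

        directory = Path(directory)
        table = cls()
        for f in sorted(directory.glob("optics_*.csv")):
            mat = Material[f.stem[len("optics_"):].upper()]
            arr = np.genfromtxt(f, delimiter=",", names=True)
            table.wavelengths = arr["wavelength_nm"]
            table.materials[mat] = MaterialOptics(
                arr["mu_a"], arr["mu_s"], arr["g"], arr["n"])
        return table


def apply_tumour_contrast(thyroid: MaterialOptics) -> MaterialOptics:
    """Tumour optical properties from the healthy thyroid's.

    Absorption +44%, scattering -30%, refractive index 1.39, anisotropy 0.9.
    """
    return MaterialOptics(
        mu_a=thyroid.mu_a * 1.44,
        mu_s=thyroid.mu_s * 0.70,
        g=np.full_like(thyroid.g, 0.9),
        n=np.full_like(thyroid.n, 1.39),
    )


def perturb_parameters(table: OpticalPropertyTable,
                       direction: str) -> OpticalPropertyTable:
    """Apply the inter-patient variability perturbation to a property table.

    ``direction`` is 'up', 'down' or 'none'.  Every perturbable material's
    mu_a, mu_s, n and g are scaled simultaneously by (1 +/- pct/100); skin
    and bone are left unperturbed; 'none' returns an identical copy.
    """
    if direction not in ("up", "down", "none"):
        raise ValueError(f"direction must be 'up', 'down' or 'none', got {direction!r}")
    out = table.copy()
    if direction == "none":
        return out
    sign = 1.0 if direction == "up" else -1.0
    for mat, (p_mua, p_mus, p_n, p_g) in VARIABILITY_PCT.items():
        if mat not in out.materials:
            continue
        mo = out.materials[mat]
        mo.mu_a *= 1.0 + sign * p_mua / 100.0
        mo.mu_s *= 1.0 + sign * p_mus / 100.0
        mo.n *= 1.0 + sign * p_n / 100.0
        mo.g *= 1.0 + sign * p_g / 100.0
        if np.any(mo.g >= 1.0):
            raise ValueError(f"perturbed anisotropy >= 1 for {mat.name}")
    out.variant = direction
    return out


def build_optical_table(variant: str = "baseline",
                        thyroid_n: float | None = None) -> OpticalPropertyTable:
    """Construct the default per-material optical property table.

    ``variant`` selects 'baseline' or the inter-patient 'up'/'down'
    perturbations.  ``thyroid_n`` overrides the thyroid (and tumour, shifted
    by the same factor) refractive index, for sensitivity studies.
    """
    basis = ChromophoreBasis.default()
    comps = datafiles.load_tissue_compositions()
    wl = WAVELENGTH_NM
    table = OpticalPropertyTable()

    for name in ("skin", "adipose", "muscle", "bone"):
        c = comps[name]
        comp = TissueComposition(c["so2"], c["w"], c["f"], c["m"])
        sp = ScatteringModelParams(c["a_cm"], c["f_ray"], c["b_mie"])
        g = np.full_like(wl, c["g"])
        mu_a = compute_mu_a(comp, basis, wl)
        _, mu_s = compute_scattering(sp, g, wl)
        n = np.asarray(refractive_index(Material[name.upper()], wl), dtype=float)
        table.materials[Material[name.upper()]] = MaterialOptics(mu_a, mu_s, g, n)

    thy = datafiles.load_thyroid_optics()
    g_thy = np.full_like(wl, 0.9)
    mu_a_thy = np.interp(wl, thy["wavelength_nm"], thy["mu_a"])
    mu_sp_thy = np.interp(wl, thy["wavelength_nm"], thy["mu_s_prime"])
    n_thy_val = 1.40 if thyroid_n is None else float(thyroid_n)
    thy_opt = MaterialOptics(mu_a_thy, mu_sp_thy / (1.0 - g_thy),
                             g_thy, np.full_like(wl, n_thy_val))
    table.materials[Material.THYROID] = thy_opt

    tum = apply_tumour_contrast(thy_opt)
    if thyroid_n is not None:
        tum.n = np.full_like(wl, 1.39 * thyroid_n / 1.40)
    table.materials[Material.TUMOUR] = tum

    table.materials[Material.AIR] = MaterialOptics(
        np.zeros_like(wl), np.zeros_like(wl), np.zeros_like(wl), np.ones_like(wl))

    if variant != "baseline":
        table = perturb_parameters(table, variant)
        table.variant = variant
    return table
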