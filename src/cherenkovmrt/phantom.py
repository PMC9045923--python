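"""Synthetic voxelized neck phantoms and Hounsfield-unit conversion.

The phantom emulates the anterior neck anatomy relevant to thyroid
radionuclide therapy: a layered slab (skin / adipose / muscle / soft tissue)
with two ellipsoidal thyroid lobes flanking an air-filled trachea, and, for
carcinoma treatments, a spheroidal tumour embedded in one lobe.  Geometry is
voxelized on a regular grid; coordinates are in millimetres, 0-based voxel
indices, voxel-centre convention, axis order (x, y, z) with y pointing from
the anterior surface into the body and z the trans-axial stacking direction.

Clinical volumes are supported through ``phantom_from_hu`` (an HU volume plus
a scanner calibration curve) and an optional DICOM CT reader.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .materials import Material, NOMINAL_DENSITY, density_to_material

__all__ = [
    "HUCalibration",
    "TumourSpec",
    "PhantomConfig",
    "VoxelPhantom",
    "hu_to_density",
    "build_neck_phantom",
    "set_tumour_contrast",
    "phantom_from_hu",
    "measure_layer_thicknesses",
    "default_hu_calibration",
    "read_ct_directory",
]


# ---------------------------------------------------------------------------
# HU calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HUCalibration:
    """Piecewise-linear scanner calibration: Hounsfield number -> density.

    ``hu`` must be strictly increasing; ``density`` (g/cm^3) non-negative and
    non-decreasing.  Evaluation clamps at the calibration endpoints.
    """

    hu: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        hu = np.asarray(self.hu, dtype=float)
        rho = np.asarray(self.density, dtype=float)
        if hu.size == 0:
            raise ValueError("empty HU calibration")
        if hu.shape != rho.shape or hu.ndim != 1:
            raise ValueError("hu and density must be 1-D arrays of equal length")
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU breakpoints must be strictly increasing")
        if np.any(rho < 0) or np.any(np.diff(rho) < 0):
            raise ValueError("density must be non-negative and non-decreasing")
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "density", rho)

    def __call__(self, hu):
        return hu_to_density(hu, self)


def hu_to_density(hu, cal: HUCalibration):
    """Convert Hounsfield numbers to mass density (g/cm^3).

    Piecewise-linear interpolation between calibration breakpoints, clamped
    at the endpoints.  Accepts scalars or arrays.
    """
    return np.interp(hu, cal.hu, cal.density)


def default_hu_calibration() -> HUCalibration:
    """A generic piecewise-linear CT calibration curve.

    The exact scanner curve used clinically is site-specific; this generic
    curve maps air to ~0.0012 g/cm^3, water to 1.0 and dense bone to 2.2.
    """
    from .datafiles import load_hu_calibration

    hu, rho = load_hu_calibration()
    return HUCalibration(hu, rho)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TumourSpec:
    """Oblate tumour spheroid: equatorial plane x-z, polar axis y.

    The maximum diameter is the equatorial diameter; the polar semi-axis is
    solved from the volume.  A valid oblate/prolate spheroid exists only when
    the volume does not exceed that of the sphere of the maximum diameter.
    """

    max_diameter_cm: float = 1.2
    volume_cm3: float = 0.85
    centre_mm: tuple[float, float, float] | None = None  # default: lobe centre

    @property
    def equatorial_radius_mm(self) -> float:
        return 10.0 * self.max_diameter_cm / 2.0

    @property
    def polar_radius_mm(self) -> float:
        a_cm = self.max_diameter_cm / 2.0
        c_cm = 3.0 * self.volume_cm3 / (4.0 * np.pi * a_cm**2)
        return 10.0 * c_cm

    def validate(self):
        a = self.max_diameter_cm / 2.0
        v_sphere = 4.0 / 3.0 * np.pi * a**3
        if not 0 < self.volume_cm3 <= v_sphere + 1e-12:
            raise ValueError(
                f"tumour volume {self.volume_cm3} cm^3 incompatible with max "
                f"diameter {self.max_diameter_cm} cm (sphere volume {v_sphere:.3f})"
            )


# Layer thicknesses (skin, adipose, muscle, thyroid) in mm along the line
# from the VOI centre to the anterior surface, per treatment.
DEFAULT_LAYERS = {
    "hyperthyroidism": (2.0, 4.0, 10.0, 8.0),
    "ptc": (2.0, 10.0, 4.0, 4.0),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry configuration for the synthetic neck phantom."""

    treatment: str = "ptc"
    skin_mm: float = 2.0
    adipose_mm: float = 10.0
    muscle_mm: float = 4.0
    thyroid_layer_mm: float = 4.0
    thyroid_volume_cm3: float = 9.5
    tumour: TumourSpec | None = field(default_factory=TumourSpec)
    voxel_mm: tuple[float, float, float] = (0.98, 0.98, 1.25)
    extent_mm: tuple[float, float, float] = (90.0, 60.0, 70.0)
    trachea_radius_mm: float = 6.0
    lobe_axial_ratio: float = 2.0  # az / ax of each lobe ellipsoid
    thyroid_hu: float = 55.0

    @classmethod
    def for_treatment(cls, treatment: str, **overrides) -> "PhantomConfig":
        """Preset layer thicknesses for 'hyperthyroidism' or 'ptc'."""
        if treatment not in DEFAULT_LAYERS:
            raise ValueError(f"unknown treatment {treatment!r}")
        s, a, m, t = DEFAULT_LAYERS[treatment]
        kw = dict(
            treatment=treatment,
            skin_mm=s,
            adipose_mm=a,
            muscle_mm=m,
            thyroid_layer_mm=t,
        )
        if treatment == "hyperthyroidism":
            kw["tumour"] = None
        kw.update(overrides)
        return cls(**kw)

    def validate(self):
        for name in ("skin_mm", "adipose_mm", "muscle_mm", "thyroid_layer_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tumour is not None:
            self.tumour.validate()


# ---------------------------------------------------------------------------
# Voxel phantom container
# ---------------------------------------------------------------------------

@dataclass
class VoxelPhantom:
    """A voxel grid of material labels and densities with named VOI masks."""

    spacing: np.ndarray  # mm per axis, shape (3,)
    origin: np.ndarray  # mm, world coordinate of the grid corner (voxel 0 face)
    labels: np.ndarray  # int8, Material values, shape (nx, ny, nz)
    density: np.ndarray  # g/cm^3, float64
    voi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) * 1e-3  # mm^3 -> cm^3

    def mask_volume_cm3(self, name: str) -> float:
        return float(self.voi_masks[name].sum()) * self.voxel_volume_cm3

    def voxel_centres(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def world_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Map world positions (…, 3) mm to integer voxel indices."""
        return np.floor((pos - self.origin) / self.spacing).astype(np.int64)

    def contains(self, pos: np.ndarray) -> np.ndarray:
        idx = (pos - self.origin) / self.spacing
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=-1)

    # -- volumetric I/O (NIfTI) ---------------------------------------------

    def _affine(self) -> np.ndarray:
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, directory: str | Path) -> None:
        """Write labels, density and masks as NIfTI volumes into a directory."""
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        aff = self._affine()
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff),
                 directory / "labels.nii")
        nib.save(nib.Nifti1Image(self.density.astype(np.float64), aff),
                 directory / "density.nii")
        for name, mask in self.voi_masks.items():
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff),
                     directory / f"mask_{name}.nii")

    @classmethod
    def load(cls, directory: str | Path) -> "VoxelPhantom":
        import nibabel as nib

        directory = Path(directory)
        lab_img = nib.load(str(directory / "labels.nii"))
        den_img = nib.load(str(directory / "density.nii"))
        aff = lab_img.affine
        spacing = np.diag(aff)[:3].copy()
        origin = aff[:3, 3].copy()
        masks = {}
        for f in sorted(directory.glob("mask_*.nii")):
            name = f.stem[len("mask_"):]
            masks[name] = np.asarray(nib.load(str(f)).dataobj).astype(bool)
        return cls(
            spacing=spacing,
            origin=origin,
            labels=np.asarray(lab_img.dataobj).astype(np.int8),
            density=np.asarray(den_img.dataobj).astype(np.float64),
            voi_masks=masks,
        )


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _lobe_semiaxes(config: PhantomConfig):
    """Semi-axes (ax, ay, az) mm of each thyroid lobe and tumour fit check.

    The lobe anterior-posterior semi-axis follows the configured thyroid
    layer thickness (full chord = thickness); it is enlarged when needed to
    contain the tumour spheroid (the printed carcinoma layer thickness is
    thinner than the tumour, so strict containment forces a thicker lobe).
    """
    v_half_mm3 = config.thyroid_volume_cm3 / 2.0 * 1e3
    ay = config.thyroid_layer_mm / 2.0
    margin = 1.0
    if config.tumour is not None:
        ay = max(ay, config.tumour.polar_radius_mm + margin)
    if ay <= 0:
        return None
    prod = 3.0 * v_half_mm3 / (4.0 * np.pi * ay)  # ax * az
    ax = np.sqrt(prod / config.lobe_axial_ratio)
    az = config.lobe_axial_ratio * ax
    if config.tumour is not None:
        a_t = config.tumour.equatorial_radius_mm
        if ax < a_t + margin:
            ax = a_t + margin
            az = prod / ax
        if az < a_t + margin:
            raise ValueError("tumour does not fit inside one thyroid lobe")
    return ax, ay, az


def build_neck_phantom(config: PhantomConfig,
                       cal: HUCalibration | None = None) -> VoxelPhantom:
    """Build the voxelized neck phantom from a geometry configuration.

    Deterministic: no randomness enters the construction.  Layers are stacked
    along +y from the anterior surface at y = 0; the two thyroid lobes sit
    immediately behind the muscle layer, flanking the tracheal air cylinder
    which runs along z.  The tumour (if any) is an oblate spheroid centred in
    the +x lobe, labelled and given CT contrast (41% of the thyroid HU).
    """
    config.validate()
    spacing = np.asarray(config.voxel_mm, dtype=float)
    extent = np.asarray(config.extent_mm, dtype=float)
    shape = np.maximum(np.ceil(extent / spacing).astype(int), 1)
    origin = np.array([-shape[0] * spacing[0] / 2.0, 0.0,
                       -shape[2] * spacing[2] / 2.0])

    labels = np.full(shape, int(Material.THYROID), dtype=np.int8)
    masks: dict[str, np.ndarray] = {}

    t_skin = config.skin_mm
    t_adip = t_skin + config.adipose_mm
    t_musc = t_adip + config.muscle_mm
    lobes = _lobe_semiaxes(config)

    if t_musc == 0 and lobes is None:
        # empty geometry: an all-air phantom
        labels[:] = int(Material.AIR)
        density = np.full(shape, NOMINAL_DENSITY[Material.AIR])
        return VoxelPhantom(spacing, origin, labels, density, masks)

    x = origin[0] + (np.arange(shape[0]) + 0.5) * spacing[0]
    y = origin[1] + (np.arange(shape[1]) + 0.5) * spacing[1]
    z = origin[2] + (np.arange(shape[2]) + 0.5) * spacing[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    labels[Y < t_skin] = int(Material.SKIN)
    labels[(Y >= t_skin) & (Y < t_adip)] = int(Material.ADIPOSE)
    labels[(Y >= t_adip) & (Y < t_musc)] = int(Material.MUSCLE)

    if lobes is not None:
        ax, ay, az = lobes
        y_c = t_musc + ay
        x_off = config.trachea_radius_mm + 1.0 + ax
        lobe_r = ((X - x_off) / ax) ** 2 + ((Y - y_c) / ay) ** 2 + (Z / az) ** 2 <= 1.0
        lobe_l = ((X + x_off) / ax) ** 2 + ((Y - y_c) / ay) ** 2 + (Z / az) ** 2 <= 1.0
        # keep lobes clear of the anterior layers
        behind = Y >= t_musc
        lobe_r &= behind
        lobe_l &= behind
        thyroid = lobe_r | lobe_l
        masks["lobe_right"] = lobe_r
        masks["lobe_left"] = lobe_l

        trachea = (X**2 + (Y - y_c) ** 2 <= config.trachea_radius_mm**2) & behind
        trachea &= ~thyroid
        labels[trachea] = int(Material.AIR)

        if config.tumour is not None:
            tum = config.tumour
            centre = tum.centre_mm
            if centre is None:
                centre = (x_off, y_c, 0.0)
            a_t = tum.equatorial_radius_mm
            c_t = tum.polar_radius_mm
            tmask = (((X - centre[0]) / a_t) ** 2
                     + ((Y - centre[1]) / c_t) ** 2
                     + ((Z - centre[2]) / a_t) ** 2) <= 1.0
            thyroid |= tmask  # tumour contoured within the thyroid volume
            masks["tumour"] = tmask
            masks["thyroid_only"] = thyroid & ~tmask
        masks["thyroid"] = thyroid

    density = np.empty(shape, dtype=np.float64)
    for mat in Material:
        density[labels == int(mat)] = NOMINAL_DENSITY[mat]

    phantom = VoxelPhantom(spacing, origin, labels, density, masks)
    if config.tumour is not None and "tumour" in masks:
        set_tumour_contrast(phantom, config.thyroid_hu,
                            cal or default_hu_calibration())
    return phantom


def set_tumour_contrast(phantom: VoxelPhantom, thyroid_hu: float,
                        cal: HUCalibration | None = None) -> VoxelPhantom:
    """Assign tumour contrast: HU set to 41% of the thyroid HU.

    Tumour voxels take HU = 0.41 * thyroid_hu, converted to density through
    the calibration curve, and are relabelled ``Material.TUMOUR``.  All other
    voxels are untouched.  Modifies the phantom in place and returns it.
    """
    if "tumour" not in phantom.voi_masks or not phantom.voi_masks["tumour"].any():
        raise ValueError("phantom has no tumour mask")
    cal = cal or default_hu_calibration()
    tumour_hu = 0.41 * thyroid_hu
    mask = phantom.voi_masks["tumour"]
    phantom.labels[mask] = int(Material.TUMOUR)
    phantom.density[mask] = hu_to_density(tumour_hu, cal)
    return phantom


def phantom_from_hu(hu: np.ndarray, cal: HUCalibration,
                    spacing, origin=(0.0, 0.0, 0.0),
                    skin_shell_mm: float = 2.0) -> VoxelPhantom:
    """Build a phantom from an HU volume via density conversion.

    Densities come from the calibration curve; materials from the density
    bands; the outermost ``skin_shell_mm`` of non-air tissue is relabelled
    skin (HU cannot separate skin from generic soft tissue).
    """
    density = hu_to_density(np.asarray(hu, dtype=float), cal)
    labels = density_to_material(density).astype(np.int8)
    spacing = np.asarray(spacing, dtype=float)

    tissue = labels != int(Material.AIR)
    if skin_shell_mm > 0 and tissue.any() and not tissue.all():
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(tissue, sampling=spacing)
        shell = tissue & (dist <= skin_shell_mm)
        labels[shell] = int(Material.SKIN)
    return VoxelPhantom(spacing, np.asarray(origin, dtype=float),
                        labels, density, {})


def measure_layer_thicknesses(phantom: VoxelPhantom, x_mm: float, z_mm: float,
                              step_mm: float = 0.05):
    """Thicknesses of consecutive material layers along a +y line.

    Marches from the anterior surface (y at the grid front face) into the
    body at lateral position (x, z) and returns the ordered list of
    (name, thickness_mm) for each contiguous run.  The soft-tissue material
    doubles as the thyroid gland, so runs of that label are split by the
    'thyroid' VOI mask: inside the mask the run is named 'thyroid', outside
    'soft_tissue'.
    """
    y0 = phantom.origin[1]
    ny = phantom.shape[1]
    y_max = y0 + ny * phantom.spacing[1]
    ys = np.arange(y0 + step_mm / 2.0, y_max, step_mm)
    pos = np.stack([np.full_like(ys, x_mm), ys, np.full_like(ys, z_mm)], axis=-1)
    idx = phantom.world_to_index(pos)
    ok = phantom.contains(pos)
    labs = phantom.labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    thy = phantom.voi_masks.get("thyroid")
    in_thy = (thy[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
              if thy is not None else np.zeros(ok.sum(), dtype=bool))
    runs: list[tuple[str, float]] = []
    for lab, inside in zip(labs, in_thy):
        mat = Material(int(lab))
        if mat == Material.THYROID:
            name = "thyroid" if inside else "soft_tissue"
        else:
            name = mat.name.lower()
        if runs and runs[-1][0] == name:
            runs[-1] = (name, runs[-1][1] + step_mm)
        else:
            runs.append((name, step_mm))
    return runs


def read_ct_directory(path: str | Path, cal: HUCalibration,
                      skin_shell_mm: float = 2.0) -> VoxelPhantom:
    """Read a directory of DICOM CT slices into a phantom (optional path).

    Requires ``pydicom``.  Slices are sorted by ImagePositionPatient along
    the slice axis; rescale slope/intercept are applied to obtain HU.
    """
    import pydicom

    path = Path(path)
    slices = [pydicom.dcmread(str(f)) for f in sorted(path.glob("*.dcm"))]
    if not slices:
        raise FileNotFoundError(f"no DICOM files under {path}")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    hu = np.stack(
        [s.pixel_array * float(s.RescaleSlope) + float(s.RescaleIntercept)
         for s in slices],
        axis=-1,
    ).transpose(1, 0, 2)  # (row, col, slice) -> (x, y, z)-ish ordering
    dz = (abs(float(slices[1].ImagePositionPatient[2])
              - float(slices[0].ImagePositionPatient[2]))
          if len(slices) > 1 else float(getattr(slices[0], "SliceThickness", 1.0)))
    px = [float(v) for v in slices[0].PixelSpacing]
    spacing = (px[1], px[0], dz)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return phantom_from_hu(hu, cal, spacing, origin, skin_shell_mm)
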