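"""Material labels, nominal densities and the density→material rule.

The voxel model distinguishes seven materials: air, skin, adipose, muscle,
soft tissue (used for the thyroid gland), tumour and bone.  CT imaging cannot
separate skin from generic soft tissue by Hounsfield number alone, so skin is
assigned geometrically (the outermost ~2 mm tissue shell) rather than by
density band.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = [
    "Material",
    "NOMINAL_DENSITY",
    "REFRACTIVE_INDEX_REF",
    "density_to_material",
]


class Material(IntEnum):
    AIR = 0
    SKIN = 1
    ADIPOSE = 2
    MUSCLE = 3
    THYROID = 4  # soft tissue / thyroid gland
    TUMOUR = 5
    BONE = 6


#: Nominal mass densities (g/cm^3) used when building synthetic phantoms.
NOMINAL_DENSITY: dict[Material, float] = {
    Material.AIR: 1.21e-3,
    Material.SKIN: 1.09,
    Material.ADIPOSE: 0.95,
    Material.MUSCLE: 1.07,
    Material.THYROID: 1.05,
    Material.TUMOUR: 1.03,
    Material.BONE: 1.92,
}

#: Reference refractive index per material, used for Cherenkov generation
#: (evaluated at 750 nm for the dispersive tissues; dispersion of n is
#: neglected for light transport of the emitted photons).
REFRACTIVE_INDEX_REF: dict[Material, float] = {
    Material.AIR: 1.0,
    Material.SKIN: 1.3774,
    Material.ADIPOSE: 1.4664,
    Material.MUSCLE: 1.3800,
    Material.THYROID: 1.40,
    Material.TUMOUR: 1.39,
    Material.BONE: 1.55,
}

# Density bands (g/cm^3), half-open [lower, upper), lower-inclusive.  The
# bands are exhaustive over density >= 0 so the mapping never fails:
#   air      [0, 0.05)
#   adipose  [0.05, 0.97)
#   soft     [0.97, 1.06)
#   muscle   [1.06, 1.20)
#   bone     [1.20, inf)
_BAND_EDGES = np.array([0.05, 0.97, 1.06, 1.20])
_BAND_LABELS = np.array(
    [Material.AIR, Material.ADIPOSE, Material.THYROID, Material.MUSCLE, Material.BONE],
    dtype=np.int8,
)


def density_to_material(density):
    """Map mass density (g/cm^3) to a material label via half-open bands.

    Accepts scalars or arrays.  Skin and tumour are never returned: skin is a
    geometric assignment and the tumour label is set by the contouring step.
    """
    density = np.asarray(density)
    if np.any(density < 0):
        raise ValueError("density must be non-negative")
    idx = np.searchsorted(_BAND_EDGES, density, side="right")
    out = _BAND_LABELS[idx]
    if out.ndim == 0:
        return Material(int(out))
    return out
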