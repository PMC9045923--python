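"""Post-processing: filtering, surface measurements, dose-light calibration
and the dose-uncertainty table.

The dosimetry idea: absorbed dose in the treatment volume and Cherenkov
light intensity at the surface are both linear in the administered activity,
so a through-origin calibration line (Gy per surface photon count) converts
a surface-light measurement into a dose estimate.  The uncertainty table
quantifies the error committed when the baseline calibration is applied to
a patient whose tissue optics or radioisotope uptake differ from baseline,
for each measurement area (total surface vs 25 x 25 mm hot-spot window) and
spectral band (broadband vs the 700-800 nm NIR analysis band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "threshold_filter",
    "find_hot_spot",
    "band_integrate",
    "origin_fraction",
    "CalibrationCurve",
    "fit_calibration",
    "estimate_dose",
    "uncertainty_table",
    "SPECTRAL_BANDS",
    "HOT_SPOT_WINDOW_MM",
]

#: Reporting bands (nm, half-open [lo, hi)); the broadband interval is
#: closed at the top so the full simulated range is included.
SPECTRAL_BANDS = {
    "500-600": (500.0, 600.0),
    "600-900": (600.0, 900.0),
    "900-1200": (900.0, 1200.0 + 1e-9),
    "700-800": (700.0, 800.0),
    "500-1200": (500.0, 1200.0 + 1e-9),
    "600-1200": (600.0, 1200.0 + 1e-9),
}

HOT_SPOT_WINDOW_MM = 25.0


def threshold_filter(map_values: np.ndarray, voi_mask: np.ndarray,
                     fraction: float = 0.01) -> np.ndarray:
    """Zero map entries below ``fraction`` of the VOI-mean signal.

    Entries strictly less than fraction * mean(map over voi_mask) are set to
    zero; all others (including exact boundary values) are kept.
    """
    if not np.any(voi_mask):
        raise ValueError("empty VOI mask")
    out = np.array(map_values, dtype=float)
    cut = fraction * out[voi_mask].mean()
    out[out < cut] = 0.0
    return out


def find_hot_spot(surface_map, window_mm: float = HOT_SPOT_WINDOW_MM):
    """Locate the square window maximizing the enclosed intensity sum.

    ``surface_map`` is a SurfaceLightMap or a bare 2D array (then bins are
    taken as 1 mm).  Returns ((centre_x_mm, centre_z_mm), window_sum,
    (row, col) of the window's lower corner).  Ties break toward the
    smallest row-major index.
    """
    counts = getattr(surface_map, "counts", surface_map)
    if hasattr(surface_map, "x_edges"):
        bx = float(surface_map.x_edges[1] - surface_map.x_edges[0])
        bz = float(surface_map.z_edges[1] - surface_map.z_edges[0])
        x0 = float(surface_map.x_edges[0])
        z0 = float(surface_map.z_edges[0])
    else:
        bx = bz = 1.0
        x0 = z0 = 0.0
    wx = max(int(round(window_mm / bx)), 1)
    wz = max(int(round(window_mm / bz)), 1)
    if wx > counts.shape[0] or wz > counts.shape[1]:
        raise ValueError("hot-spot window larger than the surface map")
    # exact integer-count window sums via a summed-area table
    sat = np.zeros((counts.shape[0] + 1, counts.shape[1] + 1))
    sat[1:, 1:] = np.cumsum(np.cumsum(counts, axis=0), axis=1)
    sums = (sat[wx:, wz:] - sat[:-wx, wz:] - sat[wx:, :-wz] + sat[:-wx, :-wz])
    flat = int(np.argmax(sums))  # first occurrence = smallest row-major index
    r, c = np.unravel_index(flat, sums.shape)
    centre = (x0 + (r + wx / 2.0) * bx, z0 + (c + wz / 2.0) * bz)
    return centre, float(sums[r, c]), (int(r), int(c))


def _area_mask(records, area, phantom=None, window_mm=HOT_SPOT_WINDOW_MM):
    if area == "total":
        return np.ones(len(records), dtype=bool)
    if area == "hot_spot":
        if phantom is None:
            raise ValueError("hot_spot area needs the phantom for binning")
        from .photons import SurfaceLightMap

        smap = SurfaceLightMap.from_records(records, phantom,
                                            band=SPECTRAL_BANDS["500-1200"])
        (cx, cz), _, _ = find_hot_spot(smap, window_mm)
        half = window_mm / 2.0
        m = records.anterior()
        m &= np.abs(records.positions[:, 0] - cx) <= half
        m &= np.abs(records.positions[:, 2] - cz) <= half
        return m
    raise ValueError(f"unknown area {area!r}")


def band_integrate(records, band, area: str = "total", phantom=None) -> float:
    """Total exit-photon count in a spectral band over a measurement area.

    ``band`` is an (lo, hi) nm pair or a named key of SPECTRAL_BANDS;
    ``area`` is 'total' (all scored exits) or 'hot_spot' (the 25 x 25 mm
    max-intensity anterior window).
    """
    band = SPECTRAL_BANDS.get(band, band)
    mask = records.in_band(band) & _area_mask(records, area, phantom)
    return float(mask.sum())


def origin_fraction(records, band, voi_mask: np.ndarray, phantom,
                    area: str = "total") -> float:
    """Fraction of band/area exit photons whose birth lies inside a VOI."""
    band = SPECTRAL_BANDS.get(band, band)
    mask = records.in_band(band) & _area_mask(records, area, phantom)
    if mask.sum() == 0:
        return np.nan
    birth = records.birth_positions[mask]
    idx = phantom.world_to_index(birth)
    shape = np.array(phantom.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    inside = np.zeros(mask.sum(), dtype=bool)
    inside[ok] = voi_mask[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return float(inside.mean())


@dataclass
class CalibrationCurve:
    """Through-origin dose-light calibration: dose = slope * intensity."""

    slope: float  # Gy per photon count
    r_squared: float
    residual_norm: float
    area: str
    band: tuple
    intercept_diagnostic: float = 0.0  # free-intercept fit, for diagnostics


def fit_calibration(doses, intensities, area: str = "total",
                    band=(500.0, 1200.0)) -> CalibrationCurve:
    """Least-squares dose-vs-light slope constrained through the origin."""
    d = np.asarray(doses, dtype=float)
    light = np.asarray(intensities, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two activity points")
    if np.all(light == 0):
        raise ValueError("all-zero light intensities")
    slope = float(d @ light / (light @ light))
    resid = d - slope * light
    ss_tot = float(((d - d.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    icept = float(np.polyfit(light, d, 1)[1]) if d.size > 2 else 0.0
    return CalibrationCurve(slope, r2, float(np.linalg.norm(resid)),
                            area, tuple(band), icept)


def estimate_dose(intensity: float, curve: CalibrationCurve) -> float:
    return curve.slope * float(intensity)


def uncertainty_table(baseline: dict, perturbed: dict[str, dict],
                      areas=("total", "hot_spot"),
                      bands=("500-1200", "700-800")):
    """Dose-estimation error table across perturbations.

    ``baseline`` and each perturbed entry are measurement dicts with keys
    'dose' (true mean treatment-volume dose, Gy) and 'light' (a mapping
    (area, band) -> surface intensity).  The baseline calibration slope
    dose/light is applied to each perturbed run's light; the error is
    (estimate - truth)/truth in percent.  Returns a pandas DataFrame with
    one row per (area, band) and one column per perturbation.
    """
    import pandas as pd

    rows = []
    for area in areas:
        for band in bands:
            light0 = baseline["light"][(area, band)]
            if light0 == 0:
                raise ValueError(f"baseline light is zero for {(area, band)}")
            slope = baseline["dose"] / light0
            row = {"area": area, "band": band}
            for name, run in perturbed.items():
                est = slope * run["light"][(area, band)]
                truth = run["dose"]
                row[name] = 100.0 * (est - truth) / truth
            rows.append(row)
    return pd.DataFrame(rows).set_index(["area", "band"])
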