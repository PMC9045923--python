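"""Loaders for the bundled delimited-text data tables."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np


def _read_csv(name: str) -> np.ndarray:
    import io

    text = resources.files("cherenkovmrt.data").joinpath(name).read_text()
    body = "\n".join(line for line in text.splitlines()
                     if line.strip() and not line.lstrip().startswith("#"))
    return np.genfromtxt(io.StringIO(body), delimiter=",", names=True)


@lru_cache(maxsize=None)
def load_chromophores():
    """Knot table: wavelength, mu_hbo2, mu_hb, mu_water, mu_fat (cm^-1)."""
    return _read_csv("chromophores.csv")


@lru_cache(maxsize=None)
def load_tissue_compositions() -> dict[str, dict[str, float]]:
    rows = {}
    with resources.files("cherenkovmrt.data").joinpath(
            "tissue_compositions.csv").open("r") as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if header is None:
                header = parts
                continue
            rows[parts[0]] = {k: float(v) for k, v in zip(header[1:], parts[1:])}
    return rows


@lru_cache(maxsize=None)
def load_thyroid_optics():
    return _read_csv("thyroid_optics.csv")


@lru_cache(maxsize=None)
def load_muscle_n():
    return _read_csv("muscle_refractive_index.csv")


@lru_cache(maxsize=None)
def load_hu_calibration():
    t = _read_csv("hu_calibration.csv")
    return t["hu"], t["density"]


@lru_cache(maxsize=None)
def load_beta_branches():
    t = _read_csv("i131_beta_branches.csv")
    intensity = t["intensity"] / t["intensity"].sum()
    return t["endpoint_mev"], intensity


@lru_cache(maxsize=None)
def load_gamma_lines():
    t = _read_csv("i131_gamma_lines.csv")
    return t["energy_mev"], t["intensity"]
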