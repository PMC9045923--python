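"""Biphasic radiopharmaceutical biokinetics and absolute scaling.

The time-activity curve of the treatment volume follows the biphasic
uptake/elimination model

    A(t) = eta * A0 * (2^(-t/Teff) - 2^(-t/Ta)),

with administered activity A0 (MBq), average intake fraction eta, effective
clearance half-time Teff (h) and uptake half-time Ta (h), Teff > Ta.  Dose is
scaled by the total number of disintegrations (t in (0, inf)); surface-light
measurements by the number of disintegrations inside a 20-minute window
starting just after the activity peak (24 h for hyperthyroidism, 25 h for
papillary thyroid carcinoma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BiokineticParams",
    "activity_at",
    "disintegrations_between",
    "peak_time",
    "default_biokinetics",
    "MEASUREMENT_START_H",
    "MEASUREMENT_WINDOW_H",
]

LN2 = np.log(2.0)

#: Start of the 20-minute light-measurement window (hours after intake).
MEASUREMENT_START_H = {"hyperthyroidism": 24.0, "ptc": 25.0}
MEASUREMENT_WINDOW_H = 20.0 / 60.0


@dataclass(frozen=True)
class BiokineticParams:
    a0_mbq: float
    eta: float
    teff_h: float
    ta_h: float

    def __post_init__(self):
        if self.a0_mbq <= 0:
            raise ValueError("A0 must be > 0")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if not self.teff_h > self.ta_h > 0:
            raise ValueError("requires Teff > Ta > 0")


def default_biokinetics(treatment: str, a0_mbq: float) -> BiokineticParams:
    """Default treatment-specific parameters."""
    if treatment == "hyperthyroidism":
        return BiokineticParams(a0_mbq, 0.30, 111.4, 4.5)
    if treatment == "ptc":
        return BiokineticParams(a0_mbq, 0.054, 68.0, 6.5)
    raise ValueError(f"unknown treatment {treatment!r}")


def activity_at(t_h, p: BiokineticParams):
    """Activity (MBq) in the treatment volume at time t (hours)."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = p.eta * p.a0_mbq * (2.0 ** (-t / p.teff_h) - 2.0 ** (-t / p.ta_h))
    return float(out) if np.isscalar(t_h) else out


def _antiderivative(t, p: BiokineticParams):
    # integral of A(t) dt in MBq*h; -T*2^(-t/T)/ln2 terms
    return (p.eta * p.a0_mbq / LN2
            * (-p.teff_h * 2.0 ** (-t / p.teff_h) + p.ta_h * 2.0 ** (-t / p.ta_h)))


def disintegrations_between(t1_h: float, t2_h: float, p: BiokineticParams) -> float:
    """Number of disintegrations between t1 and t2 (hours; t2 may be inf).

    Closed-form integral of the biphasic activity, converted from MBq*h to
    decays (x 3600 s/h x 1e6 decays per MBq*s).  Over (0, inf) this equals
    eta * A0 * (Teff - Ta) / ln 2 in MBq*h.
    """
    if not 0 <= t1_h <= t2_h:
        raise ValueError("requires 0 <= t1 <= t2")
    upper = (p.eta * p.a0_mbq / LN2 * 0.0 if np.isinf(t2_h)
             else _antiderivative(t2_h, p))
    mbq_h = upper - _antiderivative(t1_h, p)
    return float(mbq_h) * 3600.0 * 1e6


def peak_time(p: BiokineticParams) -> float:
    """Time (hours) of maximum activity: the closed-form argmax."""
    return float(np.log(p.teff_h / p.ta_h)
                 / (LN2 * (1.0 / p.ta_h - 1.0 / p.teff_h)))


def light_window_decays(p: BiokineticParams, treatment: str) -> float:
    """Disintegrations in the treatment's 20-minute measurement window."""
    t1 = MEASUREMENT_START_H[treatment]
    return disintegrations_between(t1, t1 + MEASUREMENT_WINDOW_H, p)


def total_decays(p: BiokineticParams) -> float:
    """Total disintegrations over (0, inf) (used for absolute dose)."""
    return disintegrations_between(0.0, np.inf, p)
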