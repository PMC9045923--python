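"""Biphasic time-activity model and disintegration counts.

A(t) = eta * A0 * (2^(-t/Teff) - 2^(-t/Ta)): uptake with half-time Ta,
clearance with effective half-time Teff.  Dose scales with the total
disintegration count; surface-light measurements with the count inside a
20-minute window starting just after the activity peak.
"""

import numpy as np

from cherenkovmrt import activity_at, default_biokinetics, peak_time
from cherenkovmrt.biokinetics import light_window_decays, total_decays

for treatment, a0 in (("hyperthyroidism", 400.0), ("ptc", 700.0)):
    p = default_biokinetics(treatment, a0)
    t_peak = peak_time(p)
    start = {"hyperthyroidism": 24.0, "ptc": 25.0}[treatment]
    print(f"\n{treatment} (A0 = {a0:.0f} MBq, eta = {p.eta:.3f}, "
          f"Teff = {p.teff_h} h, Ta = {p.ta_h} h)")
    print(f"  activity peak at {t_peak:5.1f} h "
          f"(measurement starts at {start:.0f} h, just after the peak)")
    print(f"  A(peak) = {activity_at(t_peak, p):6.1f} MBq, "
          f"A(start) = {activity_at(start, p):6.1f} MBq")
    print(f"  total disintegrations (dose):        {total_decays(p):.3e}")
    print(f"  20-min window disintegrations (light): "
          f"{light_window_decays(p, treatment):.3e}")

# Both counts are proportional to A0, which is why dose and measured light
# are exactly linear in the administered activity.
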