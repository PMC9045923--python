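"""Build the synthetic neck phantoms and inspect their geometry.

The voxel phantom stacks skin / adipose / muscle layers in front of two
ellipsoidal thyroid lobes flanking an air-filled trachea; the carcinoma
variant embeds a 0.85 cm^3 oblate tumour spheroid in the right lobe and
gives it CT contrast (41% of the thyroid Hounsfield number).
"""

from cherenkovmrt import PhantomConfig, build_neck_phantom
from cherenkovmrt.phantom import _lobe_semiaxes, measure_layer_thicknesses

for treatment in ("hyperthyroidism", "ptc"):
    cfg = PhantomConfig.for_treatment(treatment, voxel_mm=(1.0, 1.0, 1.0))
    ph = build_neck_phantom(cfg)
    print(f"\n{treatment}: grid {ph.shape}, voxel "
          f"{tuple(float(s) for s in ph.spacing)} mm")
    for name in sorted(ph.voi_masks):
        print(f"  {name:12s} {ph.mask_volume_cm3(name):6.2f} cm^3")
    ax, _, _ = _lobe_semiaxes(cfg)
    x_lobe = cfg.trachea_radius_mm + 1.0 + ax  # line through the right lobe
    runs = measure_layer_thicknesses(ph, x_lobe, 0.0)
    layers = ", ".join(f"{n} {t:.0f} mm" for n, t in runs[:5])
    print(f"  tissues along the anterior line: {layers}")
    # for the carcinoma phantom the line dives through a thin thyroid shell
    # straight into the tumour that the lobe encapsulates

# The thicknesses are the tissue the Cherenkov light must cross to reach the
# surface; the tumour volume fixes the treatment-volume dose denominator.
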