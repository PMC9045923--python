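# Methods

This note documents the models, parameter choices and numerical decisions
behind `cherenkovmrt`, in the order the pipeline executes them.

## Scope and intent

The package is a desk-scale re-creation of a simulation study of Cherenkov
light in I-131 therapy of the thyroid: it trades Geant4-class physics
fidelity for a transparent, fully testable chain whose every stage exposes a
closed form or an independent oracle. It is meant for method exploration —
dose–light calibration, variability analysis, measurement design — not for
clinical dose calculation.

## Synthetic neck phantom

Clinical CT + structure sets for this application are private, so the
phantom module generates a voxelized stand-in with the same gross structure:

- Axis convention: x lateral, y anterior→posterior (y = 0 is the skin
  surface), z cranio-caudal; millimetres everywhere; voxel-centre
  convention with 0-based indices. Default voxel 0.98 × 0.98 × 1.25 mm
  (CT-like); tests and the bundled studies use 2 mm isotropic voxels for
  speed — stated sizes are package defaults, chosen so a full study runs on
  one CPU in minutes.
- Layers along +y: skin, adipose, muscle with configurable thicknesses
  (presets 2/4/10 mm for hyperthyroidism, 2/10/4 mm for papillary
  carcinoma), then generic soft tissue.
- Thyroid: two ellipsoidal lobes (axial semi-axis = 2× lateral by default)
  flanking a 6 mm-radius tracheal air cylinder, total gland volume 9.5 cm³
  by default — an anatomically plausible adult gland; the thyroid-layer
  thickness parameter sets the lobes' anterior-posterior chord.
- Tumour (carcinoma preset): an oblate spheroid, equatorial diameter
  1.2 cm, polar radius solved from the 0.85 cm³ volume (a valid spheroid
  exists only below the 1.2 cm-sphere volume; violating configs are
  rejected). Its Hounsfield number is set to 41% of the thyroid's and
  converted to density through the calibration curve. Because a 1.2 cm
  tumour cannot fit inside a lobe whose chord is the printed 4 mm, the
  carcinoma lobes are thickened to the minimum that contains the tumour
  (1 mm margin); the thyroid VOI is defined as lobes ∪ tumour so the
  containment invariant holds by construction.
- Materials are assigned geometrically when building synthetic phantoms and
  by half-open density bands when importing HU volumes (air < 0.05,
  adipose < 0.97, soft tissue < 1.06, muscle < 1.20, bone ≥ 1.20 g/cm³,
  lower-inclusive); skin is the outermost 2 mm tissue shell, since CT
  density cannot separate skin from soft tissue.
- A generic piecewise-linear HU→density curve ships as a fixture; real
  studies should supply the scanner's own curve.

What the generator does *not* emulate: real gland/lobe asymmetry, nodular
heterogeneity, the spine and other bony anatomy, curved skin. Tests passing
on this phantom show the chain is self-consistent under a plausible neck
geometry; geometry-sensitive outputs (notably cross-organ dose ratios and
surface-light origin splits) will differ on real patients.

## Tissue optics

All properties live on a 1 nm grid over 500–1200 nm (knot tables are
linearly interpolated).

- Absorption mixes chromophores:
  `μa = SO2·μHbO2 + (1−SO2)·μHb + W·μa,H2O + F·μa,fat + M·μa,mel`.
  The mixing rule carries no explicit blood-volume fraction, so the bundled
  hemoglobin basis spectra are *effective in-tissue* coefficients:
  whole-blood absorption pre-multiplied by a nominal 2% blood volume
  fraction (documented in the data file). Consequence: all chromophore-based
  tissues share one nominal blood content; per-tissue differences enter only
  through SO2, W, F, M.
- The chromophore spectra, per-tissue compositions, scattering parameters
  (a, fRay, bMie with λ0 = 500 nm), thyroid μa/μs′ table and muscle n(λ)
  table are approximate landmark reconstructions of the standard
  literature compilations, shipped as versioned CSV files labelled
  synthetic/approximate. Tests assert structural properties (positivity,
  the NIR absorption window, the μs′ = μs(1−g) identity), not literature
  values.
- Refractive indices: bone 1.55 and thyroid 1.40 (constants), tumour 1.39,
  adipose one-term Sellmeier, skin Cauchy, muscle a bundled table, air 1.0.
  Dispersion is neglected for photon transport of emitted light; the
  particle-transport stage uses each material's index at 750 nm for
  Cherenkov generation.
- Tumour optics = thyroid × 1.44 (absorption) and × 0.70 (scattering),
  g = 0.9, n = 1.39.
- Inter-patient variability: simultaneous up or down scaling of μa, μs, n
  and g per material (adipose ±9.9/±8.9/±0.6/0%, muscle ±9.9/±8.9/±1.1/0%,
  thyroid ±5.8/±3.0/±2.0/±2.15%, tumour ±6.6/±4.6/±2.0/0%); skin and bone
  are held fixed. A perturbation pushing g to 1 or beyond is rejected.

## I-131 source

Each event is one disintegration. A compact branch table (endpoints 0.247,
0.334, 0.606, 0.807 MeV; the 0.606 MeV branch carries ~90%) drives an
allowed-shape Fermi spectrum `p·W·(Q−E)²·F(Z=54,W)` with the
nonrelativistic Coulomb factor, sampled by inverse CDF on a 4000-point grid
per branch. Gamma lines (0.284, 0.364, 0.637, 0.723 MeV) are emitted
independently per decay with their per-decay intensities. Positions are
voxel-uniform inside the uptake-weighted VOIs; all directions isotropic.
Conversion electrons, X-rays and decay daughters are out of scope.

## Electron transport and Cherenkov generation

Class-I condensed history: continuous slowing down along an analytic
Berger–Seltzer collision stopping power (water composition Z/A = 0.5551,
I = 75 eV) with a ZE/800 radiative surcharge, density-scaled per voxel.
Energy/step bookkeeping goes through a precomputed range table (1/S
integrated on a 3000-point log grid), so the summed step lengths reproduce
the CSDA range by construction; a test checks the transported mean path
against an independent quadrature to 2% and against the expected few-mm
beta range in tissue. Steps are capped at min(0.1 × residual CSDA range,
half the smallest voxel); angular diffusion uses the Highland formula with
the water radiation length (36.08 g/cm²); electrons below 10 keV (and all
radiative losses) deposit locally; bremsstrahlung photons are not tracked.
Energy is conserved exactly: deposited + escaped = injected, per run.

Cherenkov photons per step follow the analytic wavelength integral of the
Frank–Tamm yield at the step's mean β and the voxel material's reference
index, with Poisson-fluctuated counts, wavelengths drawn from the 1/λ²
inverse CDF on 500–1200 nm, birth positions uniform along the step, and
isotropic directions (ensemble-level isotropy of the emission, a documented
simplification of the emission cone).

## Gamma transport

Compton-only: the total Klein–Nishina cross-section times the water
electron density (3.343 × 10²³ e/g, density-scaled) gives the attenuation
coefficient — about 0.11 cm⁻¹ at 0.364 MeV in unit-density tissue. Free
paths use Woodcock delta-tracking through the heterogeneous grid (unbiased,
no boundary bookkeeping); scattered-photon energies and angles come from
the Butcher–Messel composition-rejection sampler. Photons degraded below
50 keV are absorbed on the spot (photoelectric surrogate). Compton
electrons are handed to the electron transport with isotropic directions —
their CSDA range (≤ 0.5 mm at the energies involved) is below the voxel
scale, so the direction approximation does not move dose at map resolution;
scattered photon directions use exact kinematics. A structural consequence
worth noting: the Compton edge of the 0.364 MeV line (0.214 MeV) lies below
the n = 1.40 Cherenkov threshold (0.219 MeV), so that line produces no
Cherenkov light in thyroid-index tissue; near-surface light comes from the
minor hard lines and from higher-index adipose.

## Optical transport

Analog (unweighted) Monte Carlo, chosen so photon fates partition exactly
(absorbed + exited = launched) and conservation is testable; variance is
bought with photon count. Free paths are exponential in the local
μt = μa + μs with remaining-optical-depth bookkeeping across voxel
boundaries (no resampling bias in heterogeneous media); interactions absorb
with probability μa/μt or scatter through the Henyey–Greenstein phase
function (the field's standard one-parameter model for the compiled g
values); every voxel boundary where the material index changes applies
unpolarized Fresnel reflection/refraction with total internal reflection;
crossing the outer grid boundary scores the photon's exit position,
refracted direction, wavelength and birth position (ambient air, n = 1;
no camera model — all exit directions count). Exit side is recorded so
lateral/posterior exits are never silently lost; surface maps default to
the anterior face on a 1 mm grid.

Two backends implement identical physics: a compiled per-photon numba
kernel (default) and a vectorized numpy reference engine; a statistical
cross-check test compares their escape fractions. The pipeline can split
each born photon into k independent optical histories
(`optical_oversample`), an unbiased variance reducer for surface
statistics; intensities are divided by k.

## Biokinetics and absolute scaling

`A(t) = ηA0(2^(−t/Teff) − 2^(−t/Ta))` with defaults η = 30%,
Teff = 111.4 h, Ta = 4.5 h (hyperthyroidism) and η = 5.4%, Teff = 68 h,
Ta = 6.5 h (carcinoma). Disintegration counts are closed-form integrals
(verified against adaptive quadrature to 1e-9 relative): the total over
(0, ∞) scales per-decay dose to Gy; the 20-minute window starting at 24 h
(hyperthyroidism) or 25 h (carcinoma) — just after the analytic activity
peaks at 21.7 h and 24.3 h respectively — scales per-decay light to
measured counts. Scaling is post hoc on one per-decay Monte Carlo run,
which makes dose and light exactly linear in A0 by construction.

## Analysis

- Threshold filter: entries strictly below 1% of the map's mean over the
  treatment volume are zeroed (boundary values kept), applied per element
  of whichever map is filtered.
- Hot spot: the 25 × 25 mm window maximizing the enclosed anterior-surface
  intensity, found on an exact integer summed-area table; ties break to the
  smallest row-major index.
- Bands are half-open [lo, hi) in nm (500–600, 600–900, 900–1200, plus the
  700–800 nm analysis band); the broadband interval closes at 1200 nm so
  the three display bands partition it exactly.
- Calibration fits are least-squares through the origin (zero activity
  means zero dose and zero light) — slope Σ(D·L)/Σ(L²); a free-intercept
  fit is kept as a diagnostic only. Dose-estimation error is
  (estimate − truth)/truth; the "truth" for the uncertainty table is the
  mean absolute dose over the tumour mask. "Total surface" means all scored
  exits; the hot-spot window is re-located per measurement.
- The uncertainty study runs the baseline (100% tumour uptake, baseline
  optics) plus optics-up, optics-down, and 90/10 and 75/25 uptake splits
  (the gland share distributed over the whole 9.5 cm³ gland), all with a
  common master seed so the decay stage is shared (common random numbers).

## Reproducibility

A master seed spawns per-stage child seeds (`numpy` SeedSequence);
transport chunk sizes are fixed constants so results do not depend on
batching; the compiled optical kernel is seeded from the optical-stage
child stream. Every pipeline output directory carries a `run.yaml` sidecar
with the full configuration, its hash, the seed and the energy ledger, and
a test reruns a config reconstructed from the sidecar to bitwise-identical
outputs.

## Known limitations

- Electron physics is class-I (no energy-loss straggling, no delta rays,
  no explicit bremsstrahlung transport); gamma physics is Compton-only with
  a water-equivalent cross-section for all tissues; expect percent-level
  dose-shape differences against a full-physics code.
- The optical property tables are approximate reconstructions; quantities
  that depend exponentially on NIR attenuation — above all the fraction of
  surface light originating in the treatment volume, and with it the
  relative robustness of hot-spot/NIR measurements under optics
  perturbations — are sensitive to those magnitudes and to the synthetic
  anatomy, and at desk-scale photon counts the optics-perturbation error
  differences between measurement cells are within Monte Carlo noise.
  The corresponding acceptance checks document this rather than hide it.
- The thyroid/tumour cross-dose ratio depends on how much of the beta
  energy escaping the tumour is caught by surrounding gland tissue; with
  the tumour fully encapsulated by the enlarged lobe this lands near the
  upper edge of the expected "about 3%" scale.
- No camera, solid-angle, quantum-efficiency or time-resolved modelling;
  no polarization, fluorescence or optical tomography.
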