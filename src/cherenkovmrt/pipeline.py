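"""End-to-end pipeline: phantom -> optics -> decay -> transport -> optical
transport -> biokinetic scaling -> analysis, with reproducible seeding and
artifact output.

One Monte Carlo run produces per-decay quantities (dose per disintegration,
Cherenkov photons per disintegration); absolute quantities follow by
multiplying with the biokinetic disintegration counts: the total number of
disintegrations over (0, inf) for dose, and the 20-minute measurement-window
count for surface light.  Scaling is applied post hoc, so dose and light are
exactly linear in the administered activity by construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import biokinetics as bk
from .analysis import SPECTRAL_BANDS, band_integrate
from .nuclear import SourceConfig
from .optics import build_optical_table
from .phantom import PhantomConfig, VoxelPhantom, build_neck_phantom
from .photons import ExitRecords, OpticalTransport, SurfaceLightMap
from .transport import PhotonBatch, SimulationResult, simulate_decays


def PhotonBatchSplit(batch: PhotonBatch, k: int) -> PhotonBatch:
    """Repeat each photon k times (optical-stage splitting)."""
    return PhotonBatch(
        np.repeat(batch.positions, k, axis=0),
        np.repeat(batch.directions, k, axis=0),
        np.repeat(batch.wavelengths, k),
        np.repeat(batch.birth_positions, k, axis=0),
    )

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "run_uncertainty_study", "calibration_points"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one simulation run."""

    treatment: str = "ptc"
    activity_mbq: float = 700.0
    uptake: dict = field(default_factory=lambda: {"tumour": 1.0})
    optics_variant: str = "baseline"  # baseline | up | down
    n_events: int = 100_000
    seed: int = 0
    thyroid_n: float | None = None  # override thyroid/tumour refractive index
    voxel_mm: tuple = (2.0, 2.0, 2.0)
    extent_mm: tuple = (90.0, 60.0, 70.0)
    photon_keep_fraction: float = 1.0
    optical_oversample: int = 1  # photon splitting for surface statistics
    include_gammas: bool = True
    bands: tuple = ("500-1200", "700-800")
    areas: tuple = ("total", "hot_spot")
    out_dir: str | None = None

    def __post_init__(self):
        if self.n_events < 1:
            raise ValueError("event count must be >= 1")
        if self.treatment not in ("hyperthyroidism", "ptc"):
            raise ValueError(f"unknown treatment {self.treatment!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["uptake"] = dict(self.uptake)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: RunConfig
    phantom: VoxelPhantom
    sim: SimulationResult
    exit_records: ExitRecords
    dose_per_decay_gy: np.ndarray
    dose_abs_gy: np.ndarray
    mean_treatment_dose_gy: float
    light: dict  # (area, band) -> absolute window photon count
    total_decays: float
    window_decays: float
    provenance: dict

    def treatment_mask(self) -> np.ndarray:
        name = "tumour" if self.config.treatment == "ptc" else "thyroid"
        return self.phantom.voi_masks[name]

    def rescale_activity(self, new_activity_mbq: float) -> "PipelineResult":
        """Absolute outputs for a different administered activity (exact
        post-hoc scaling; the per-decay run is shared)."""
        ratio = new_activity_mbq / self.config.activity_mbq
        new = dataclasses.replace(self)
        new.config = dataclasses.replace(self.config,
                                         activity_mbq=new_activity_mbq)
        new.dose_abs_gy = self.dose_abs_gy * ratio
        new.mean_treatment_dose_gy = self.mean_treatment_dose_gy * ratio
        new.light = {k: v * ratio for k, v in self.light.items()}
        new.total_decays = self.total_decays * ratio
        new.window_decays = self.window_decays * ratio
        return new


def _light_measurements(records, phantom, areas, bands,
                        per_photon_weight: float) -> dict:
    out = {}
    for area in areas:
        for band in bands:
            counts = band_integrate(records, band, area=area, phantom=phantom)
            out[(area, band)] = counts * per_photon_weight
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all pipeline stages for one run configuration."""
    ss = np.random.SeedSequence(config.seed)
    s_transport, s_optical = ss.spawn(2)
    rng_t = np.random.default_rng(s_transport)
    rng_o = np.random.default_rng(s_optical)

    pconf = PhantomConfig.for_treatment(config.treatment,
                                        voxel_mm=tuple(config.voxel_mm),
                                        extent_mm=tuple(config.extent_mm))
    phantom = build_neck_phantom(pconf)
    optics = build_optical_table(config.optics_variant,
                                 thyroid_n=config.thyroid_n)
    source = SourceConfig(uptake=dict(config.uptake))

    sim = simulate_decays(
        phantom, source, config.n_events, rng_t, optics_table=optics,
        collect="full", include_gammas=config.include_gammas,
        photon_keep_fraction=config.photon_keep_fraction)

    batch = sim.photons
    k = max(int(config.optical_oversample), 1)
    if k > 1:
        # photon splitting: k independent optical histories per born photon
        # (unbiased for surface means; divide intensities by k)
        batch = PhotonBatchSplit(batch, k)
    records = OpticalTransport(phantom, optics).propagate(batch, rng_o)

    params = bk.default_biokinetics(config.treatment, config.activity_mbq)
    n_total = bk.total_decays(params)
    n_window = bk.light_window_decays(params, config.treatment)

    dose_per_decay = sim.dose.dose_gy() / config.n_events
    dose_abs = dose_per_decay * n_total
    tv_name = "tumour" if config.treatment == "ptc" else "thyroid"
    mean_dose = float(dose_abs[phantom.voi_masks[tv_name]].mean())

    weight = n_window / (config.n_events * config.photon_keep_fraction * k)
    light = _light_measurements(records, phantom, config.areas, config.bands,
                                weight)

    result = PipelineResult(
        config=config,
        phantom=phantom,
        sim=sim,
        exit_records=records,
        dose_per_decay_gy=dose_per_decay,
        dose_abs_gy=dose_abs,
        mean_treatment_dose_gy=mean_dose,
        light=light,
        total_decays=n_total,
        window_decays=n_window,
        provenance={
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_events": config.n_events,
            "energy_ledger": sim.ledger,
            "n_cherenkov": int(sim.emission_counts.sum()),
            "n_surface": len(records),
        },
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    import nibabel as nib
    import yaml

    out_dir.mkdir(parents=True, exist_ok=True)
    ph = result.phantom
    aff = ph._affine()
    nib.save(nib.Nifti1Image(result.dose_per_decay_gy, aff),
             out_dir / "dose_per_decay.nii")
    nib.save(nib.Nifti1Image(result.dose_abs_gy, aff),
             out_dir / "dose_absolute.nii")
    nib.save(nib.Nifti1Image(result.sim.emission_counts, aff),
             out_dir / "cherenkov_emission.nii")
    ph.save(out_dir / "phantom")
    for name in ("500-600", "600-900", "900-1200", "500-1200"):
        smap = SurfaceLightMap.from_records(result.exit_records, ph,
                                            band=SPECTRAL_BANDS[name])
        np.savetxt(out_dir / f"surface_{name}nm.csv", smap.counts,
                   delimiter=",")
    result.exit_records.to_dataframe().to_csv(
        out_dir / "exit_records.csv", index=False)
    with open(out_dir / "run.yaml", "w") as fh:
        yaml.safe_dump(_clean(result.provenance), fh)


def _clean(obj):
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def calibration_points(result: PipelineResult, activities, area: str,
                       band: str):
    """(doses, intensities) across administered activities from one run."""
    doses, lights = [], []
    for a in activities:
        r = result.rescale_activity(a)
        doses.append(r.mean_treatment_dose_gy)
        lights.append(r.light[(area, band)])
    return np.array(doses), np.array(lights)


def run_uncertainty_study(base: RunConfig,
                          uptake_splits=((0.9, 0.1), (0.75, 0.25))):
    """Baseline + perturbed pipeline runs for the dose-uncertainty table.

    Returns (results dict, measurement dicts) where the measurement dicts
    feed ``analysis.uncertainty_table``: the baseline is 100% tumour uptake
    with baseline optics; perturbations are the optics up/down variants and
    the partial-uptake splits.
    """
    results = {"baseline": run_pipeline(base)}
    for variant in ("up", "down"):
        cfg = dataclasses.replace(base, optics_variant=variant)
        results[f"optics_{variant}"] = run_pipeline(cfg)
    for tum, thy in uptake_splits:
        cfg = dataclasses.replace(
            base, uptake={"tumour": tum, "thyroid": thy})
        results[f"uptake_{int(tum * 100)}"] = run_pipeline(cfg)
    meas = {}
    for name, res in results.items():
        mask = res.phantom.voi_masks["tumour"]
        meas[name] = {
            "dose": float(res.dose_abs_gy[mask].mean()),
            "light": res.light,
        }
    return results, meas
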