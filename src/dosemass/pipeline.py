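"""End-to-end orchestration: phantom/cohort generation or file loading,
per-patient dosimetry + expansion analysis, and cohort aggregation."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import __version__
from .dosimetry import compute_dmh, compute_dvh, metrics, resample_to_grid
from .errors import DosemassError, MissingStructureError, ParameterError
from .io_formats.density import default_density_table, read_density_csv, write_density_csv
from .io_formats.metaimage import read_mha, write_mha
from .io_formats.raster import rasterize
from .io_formats.structures import read_structures_json, write_structures_json
from .io_formats.types import DensityTable, Mask, StructureSet, VoxelGrid
from .io_formats.density import hu_to_density
from .phantom import CohortDistribution, PatientPair, PhantomParams, generate_cohort, generate_pair
from .registration import expansion_metrics, merge_dvf, register_deformable, split_tissue
from .stats import CohortResult, PatientMetrics, build_summary, correlation_table_flat

log = logging.getLogger(__name__)

DEFAULT_LUNG_LEVELS = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0)
DEFAULT_HEART_LEVELS = (20.0, 40.0)


@dataclass
class RegistrationConfig:
    enabled: bool = True
    stages: int = 6
    finest_control_spacing_mm: float = 20.0
    max_iterations: int = 60
    merge_band_voxels: int = 3


@dataclass
class RunConfig:
    """Single configuration for a full run (one input mode only)."""

    mode: str = "synthetic"  # "synthetic" | "files"
    n_patients: int = 31
    seed: int = 0
    data_dir: Optional[str] = None  # files mode: directory with manifest.json
    density_table_path: Optional[str] = None
    lung_dose_levels: Sequence[float] = DEFAULT_LUNG_LEVELS
    heart_dose_levels: Sequence[float] = DEFAULT_HEART_LEVELS
    bin_width_gy: float = 0.1
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    phantom_overrides: Dict[str, object] = field(default_factory=dict)
    adverse_fraction: float = 4.0 / 31.0
    output_dir: str = "dosemass_out"

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ParameterError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files" and not self.data_dir:
            raise ParameterError("files mode requires data_dir")
        levels = list(self.lung_dose_levels)
        if any(l <= 0 for l in levels) or sorted(levels) != levels:
            raise ParameterError("dose levels must be positive and sorted")
        if isinstance(self.registration, dict):
            self.registration = RegistrationConfig(**self.registration)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["lung_dose_levels"] = list(self.lung_dose_levels)
        out["heart_dose_levels"] = list(self.heart_dose_levels)
        return out

    def density_table(self) -> DensityTable:
        if self.density_table_path:
            return read_density_csv(self.density_table_path)
        return default_density_table()

    def base_phantom_params(self) -> PhantomParams:
        return PhantomParams(**self.phantom_overrides) if self.phantom_overrides else PhantomParams()


def _level_key(prefix: str, level: float, suffix: str) -> str:
    lv = int(level) if float(level).is_integer() else level
    return f"{prefix}{lv}_{suffix}"


def _structure_scalars(dose, mask, density, levels) -> Dict[str, float]:
    m = metrics(dose, mask, density=density, dose_levels=levels)
    out = {
        "dmean_dvh_gy": m.dmean_volume,
        "dmean_dmh_gy": m.dmean_mass,
        "volume_cm3": m.volume_cm3,
        "mass_g": m.mass_g,
        "mean_density_g_cm3": m.mean_density_g_cm3,
    }
    for level in levels:
        out[_level_key("v", level, "rel_pct")] = m.vx_rel[level]
        out[_level_key("v", level, "abs_cm3")] = m.vx_abs[level]
        if m.mass_g is not None:
            out[_level_key("m", level, "rel_pct")] = m.mx_rel[level]
            out[_level_key("m", level, "abs_g")] = m.mx_abs[level]
    return out


def run_patient(
    pair: PatientPair | dict,
    config: RunConfig,
    patient_id: str = "patient",
    adverse: bool = False,
) -> PatientMetrics:
    """Full per-patient analysis: DVH/DMH metrics, anatomy, lung expansion.

    ``pair`` is either a phantom :class:`PatientPair` or a dict
    ``{"fb"/"dibh": {"ct", "structures", "dose"}}`` of loaded objects.
    """
    table = config.density_table()
    phases = {}
    for phase in ("fb", "dibh"):
        if isinstance(pair, PatientPair):
            ph = getattr(pair, phase)
            ct, structures, dose = ph.ct, ph.structures, ph.dose
        else:
            ct, structures, dose = (pair[phase][k] for k in ("ct", "structures", "dose"))
        missing = [n for n in ("left_lung", "heart", "ptv", "body") if n not in structures]
        if missing:
            raise MissingStructureError(missing)
        if not ct.same_geometry(dose):
            dose = resample_to_grid(dose, ct)
        density = hu_to_density(ct, table)
        masks = {name: rasterize(structures, name, ct) for name in ("left_lung", "heart", "ptv")}
        phases[phase] = {"ct": ct, "dose": dose, "density": density, "masks": masks}

    dose_metrics: Dict[str, Dict[str, Dict[str, float]]] = {}
    levels = [float(l) for l in config.lung_dose_levels]
    heart_levels = [float(l) for l in config.heart_dose_levels]
    for phase, ph in phases.items():
        dose_metrics[phase] = {
            "left_lung": _structure_scalars(ph["dose"], ph["masks"]["left_lung"], ph["density"], levels),
            "heart": _structure_scalars(ph["dose"], ph["masks"]["heart"], None, heart_levels),
            "ptv": {"volume_cm3": ph["masks"]["ptv"].volume_cm3},
        }

    lung_fb = dose_metrics["fb"]["left_lung"]
    lung_dibh = dose_metrics["dibh"]["left_lung"]
    anatomy = {
        "ptv_volume_fb_cm3": dose_metrics["fb"]["ptv"]["volume_cm3"],
        "lung_volume_fb_cm3": lung_fb["volume_cm3"],
        "lung_volume_dibh_cm3": lung_dibh["volume_cm3"],
        "delta_lung_volume_pct": (lung_dibh["volume_cm3"] - lung_fb["volume_cm3"])
        * 100.0
        / lung_fb["volume_cm3"],
        "lung_mass_fb_g": lung_fb["mass_g"],
        "lung_density_fb_g_cm3": lung_fb["mean_density_g_cm3"],
    }

    expansion: Dict[str, dict] = {}
    if config.registration.enabled:
        expansion = _expansion_analysis(phases, config)

    return PatientMetrics(
        patient_id=patient_id,
        dose_metrics=dose_metrics,
        anatomy=anatomy,
        expansion=expansion,
        adverse=adverse,
    )


def _expansion_analysis(phases: dict, config: RunConfig) -> Dict[str, dict]:
    """Three-step workflow: tissue split, paired registration, merged field."""
    reg = config.registration
    fb, dibh = phases["fb"], phases["dibh"]
    lung_mask_fb = fb["masks"]["left_lung"]
    fb_lung, fb_nonlung = split_tissue(fb["ct"], lung_mask_fb)
    dibh_lung, dibh_nonlung = split_tissue(dibh["ct"], dibh["masks"]["left_lung"])
    kwargs = dict(
        stages=reg.stages,
        max_iterations=reg.max_iterations,
    )
    from .registration import default_schedule, intensity_match

    schedule = default_schedule(reg.stages, reg.finest_control_spacing_mm)
    # MSE cannot absorb the systematic lung intensity drop between phases,
    # so the moving lung image is rescaled to the fixed lung's tissue level
    rescale = intensity_match(fb_lung, lung_mask_fb, dibh_lung, dibh["masks"]["left_lung"])
    lung_dvf = register_deformable(
        fb_lung, dibh_lung, grid_schedule=schedule, moving_rescale=rescale, **kwargs
    )
    nonlung_dvf = register_deformable(fb_nonlung, dibh_nonlung, grid_schedule=schedule, **kwargs)
    merged = merge_dvf(lung_dvf, nonlung_dvf, lung_mask_fb, band_voxels=reg.merge_band_voxels)

    v20_mask = Mask(
        lung_mask_fb.values & (fb["dose"].values >= 20.0),
        lung_mask_fb.spacing,
        lung_mask_fb.origin,
    )
    out = {"left_lung": expansion_metrics(merged, lung_mask_fb).as_dict()}
    if v20_mask.voxel_count:
        out["v20_region"] = expansion_metrics(merged, v20_mask).as_dict()
    out["diagnostics"] = {
        "lung_stages": lung_dvf.diagnostics,
        "nonlung_stages": nonlung_dvf.diagnostics,
    }
    return out


# ---------------------------------------------------------------------------
# Cohort runs and file interchange
# ---------------------------------------------------------------------------

def export_pair(pair: PatientPair, out_dir: str, patient_id: str = "patient") -> dict:
    """Write a phantom pair in the research formats; returns its manifest."""
    os.makedirs(out_dir, exist_ok=True)
    entry = {"id": patient_id}
    for phase in ("fb", "dibh"):
        ph = getattr(pair, phase)
        paths = {
            "ct": os.path.join(out_dir, f"{phase}_ct.mha"),
            "structures": os.path.join(out_dir, f"{phase}_structures.json"),
            "dose": os.path.join(out_dir, f"{phase}_dose.mha"),
        }
        write_mha(paths["ct"], ph.ct)
        write_structures_json(paths["structures"], ph.structures)
        write_mha(paths["dose"], ph.dose)
        entry[phase] = paths
    table_path = os.path.join(out_dir, "density_table.csv")
    write_density_csv(table_path, default_density_table())
    entry["density_table"] = table_path
    return entry


def load_pair(entry: dict) -> dict:
    return {
        phase: {
            "ct": read_mha(entry[phase]["ct"]),
            "structures": read_structures_json(entry[phase]["structures"]),
            "dose": read_mha(entry[phase]["dose"]),
        }
        for phase in ("fb", "dibh")
    }


def _load_manifest(data_dir: str) -> List[dict]:
    path = os.path.join(data_dir, "manifest.json")
    with open(path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    return manifest["patients"]


def run_cohort(config: RunConfig) -> Tuple[CohortResult, List[dict]]:
    """Run the full cohort analysis; returns (result, per-patient failures).

    Individual patient failures are recorded and skipped; the cohort aborts
    only if fewer than 2 patients succeed.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    failures: List[dict] = []
    analyzed: List[PatientMetrics] = []

    if config.mode == "synthetic":
        dist = CohortDistribution(adverse_fraction=config.adverse_fraction)
        pairs = generate_cohort(
            config.n_patients, dist, seed=config.seed, base_params=config.base_phantom_params()
        )
        items = [(f"synthetic_{i:03d}", pair, pair.params.adverse) for i, pair in enumerate(pairs)]
    else:
        items = []
        for entry in _load_manifest(config.data_dir):
            items.append((entry["id"], entry, bool(entry.get("adverse", False))))

    metrics_dir = os.path.join(config.output_dir, "patients")
    os.makedirs(metrics_dir, exist_ok=True)
    for patient_id, payload, adverse in items:
        try:
            pair = payload if isinstance(payload, PatientPair) else load_pair(payload)
            pm = run_patient(pair, config, patient_id=patient_id, adverse=adverse)
            analyzed.append(pm)
            with open(os.path.join(metrics_dir, f"{patient_id}.json"), "w", encoding="utf-8") as fh:
                json.dump(pm.as_dict(), fh, indent=1)
        except DosemassError as exc:
            log.error("patient %s failed: %s", patient_id, exc)
            failures.append({"patient_id": patient_id, "error": str(exc)})

    if len(analyzed) < 2:
        raise DosemassError(
            f"only {len(analyzed)} patients analyzed successfully; need >= 2 "
            f"({len(failures)} failures)"
        )
    result = build_summary(analyzed)
    _write_reports(result, config)
    return result, failures


def _write_reports(result: CohortResult, config: RunConfig) -> None:
    out = config.output_dir
    result.summary.to_csv(os.path.join(out, "summary.csv"))
    result.per_patient.to_csv(os.path.join(out, "per_patient.csv"))
    if result.correlations is not None:
        correlation_table_flat(result.correlations).to_csv(
            os.path.join(out, "correlations.csv"), index=False
        )
    bundle = {
        "software": {"dosemass": __version__, "python": platform.python_version(),
                     "numpy": np.__version__},
        "config": config.as_dict(),
        "tests_wilcoxon_p": result.tests,
        "regressions": {k: v.as_dict() for k, v in result.regressions.items()},
    }
    with open(os.path.join(out, "results.json"), "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=1)


def export_cohort(pairs: List[PatientPair], out_dir: str) -> str:
    """Export phantom pairs + manifest for files-mode reruns; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for i, pair in enumerate(pairs):
        pid = f"synthetic_{i:03d}"
        entry = export_pair(pair, os.path.join(out_dir, pid), patient_id=pid)
        entry["adverse"] = bool(pair.params.adverse)
        entries.append(entry)
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"patients": entries}, fh, indent=1)
    return path
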