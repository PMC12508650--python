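"""NIfTI / CSV / YAML interfaces and the end-to-end pipeline runner."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort_stats import group_comparison_battery
from .errors import CohortValidationError, GeometryError
from .grid import (
    BrainGrid,
    PlaneSet,
    TemplateGeometry,
    build_grid,
    default_plane_set,
    mni152_2mm_geometry,
)
from .prediction import (
    classification_metrics,
    fit_binary_logistic,
    fit_multinomial,
    forward_conditional_select,
    metrics_frame,
)
from .synthetic import default_group_specs, simulate_cohort
from .topography import TumourMask, cohort_summary, minmax_frequency, occurrence_map

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_mask",
    "write_volume",
    "resample_mask_to",
    "read_cohort",
    "read_plane_set",
    "write_plane_set",
    "run_full_pipeline",
]

REQUIRED_COHORT_COLUMNS = [
    "patient_id", "group", "age", "sex", "seizure", "cognitive_deficit",
    "motor_deficit", "language_deficit", "visual_deficit", "headache",
    "asymptomatic", "border", "contrast", "volume_ml", "bg_voxel_count",
    "laterality", "location",
]
GROUP_LEVELS = {"astro_IDHm", "astro_IDHwt", "oligo"}
BINARY_COLUMNS = [
    "seizure", "cognitive_deficit", "motor_deficit", "language_deficit",
    "visual_deficit", "headache", "asymptomatic", "contrast",
]
YES_NO = {"Y": 1, "N": 0, "YES": 1, "NO": 0, "1": 1, "0": 0}


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    seed: int = 0
    out_dir: str = "bg_out"
    axial_mm: tuple = (-24.0, 4.0, 32.0)
    coronal_mm: tuple = (-38.0, 10.0)
    sagittal_mm: tuple = (-26.0, 0.0, 26.0)
    min_overlap_mm3: float = 0.0
    bilateral_threshold: float = 0.05
    p_enter: float = 0.05
    p_remove: float = 0.10
    template_shape: tuple = (91, 109, 91)
    template_affine: tuple = field(
        default_factory=lambda: tuple(map(tuple, mni152_2mm_geometry().affine))
    )

    def plane_set(self) -> PlaneSet:
        return PlaneSet(tuple(self.axial_mm), tuple(self.coronal_mm), tuple(self.sagittal_mm))

    def geometry(self) -> TemplateGeometry:
        return TemplateGeometry(tuple(self.template_shape), np.asarray(self.template_affine))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def read_mask(path, patient_id: str | None = None) -> TumourMask:
    """Load a binary NIfTI mask; non-binary input is binarized at > 0.5."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise GeometryError(f"cannot read {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"{path} is {data.ndim}D; expected a 3D mask")
    affine = img.affine
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError(f"{path} has a non-invertible affine")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        warnings.warn(f"{path.name}: non-binary values; binarizing at > 0.5", stacklevel=2)
        data = data > 0.5
    return TumourMask(
        data=data.astype(bool),
        affine=affine,
        patient_id=patient_id or path.name.split(".")[0],
    )


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), str(path))


def resample_mask_to(mask: TumourMask, geometry: TemplateGeometry) -> TumourMask:
    """Nearest-neighbour resample onto the template lattice (world-space)."""
    from nilearn.image import resample_img

    if mask.data.shape == geometry.shape and np.allclose(mask.affine, geometry.affine, atol=1e-4):
        return mask
    logger.warning("resampling mask %s to template geometry (nearest)", mask.patient_id)
    src = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = resample_img(
            src,
            target_affine=geometry.affine,
            target_shape=geometry.shape,
            interpolation="nearest",
            force_resample=True,
            copy_header=True,
        )
    return TumourMask(
        data=np.asanyarray(res.dataobj).astype(bool),
        affine=geometry.affine,
        patient_id=mask.patient_id,
    )


def read_cohort(path) -> pd.DataFrame:
    """Read and schema-validate a cohort CSV.

    Y/N indicator columns are normalized to 0/1.  Unknown columns are kept
    but ignored by the battery.  All violations are collected and reported
    together.
    """
    df = pd.read_csv(path)
    problems = []
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing required column(s): {missing}"])
    dup = df["patient_id"][df["patient_id"].duplicated()].tolist()
    if dup:
        problems.append(f"duplicate patient_id: {sorted(set(dup))}")
    for col in BINARY_COLUMNS:
        vals = df[col].astype(str).str.strip().str.upper()
        unknown = sorted(set(vals) - set(YES_NO))
        if unknown:
            problems.append(f"column {col}: unrecognized values {unknown}")
        else:
            df[col] = vals.map(YES_NO).astype(int)
    bad_age = df.loc[pd.to_numeric(df["age"], errors="coerce").fillna(-1) < 18, "patient_id"].tolist()
    if bad_age:
        problems.append(f"age < 18 (adult cohort): {bad_age}")
    bad_group = sorted(set(df["group"].astype(str)) - GROUP_LEVELS)
    if bad_group:
        problems.append(f"unknown group level(s): {bad_group}")
    bad_lat = sorted(set(df["laterality"].astype(str)) - {"L", "R", "B"})
    if bad_lat:
        problems.append(f"unknown laterality level(s): {bad_lat}")
    bad_border = sorted(set(df["border"].astype(str)) - {"sharp", "diffuse"})
    if bad_border:
        problems.append(f"unknown border level(s): {bad_border}")
    if problems:
        raise CohortValidationError(problems)
    counts = df["group"].value_counts().to_dict()
    logger.info("cohort: %d rows, groups %s", len(df), counts)
    return df


def read_plane_set(path) -> PlaneSet:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    g = raw.get("grid", raw)
    return PlaneSet(tuple(g["axial_mm"]), tuple(g["coronal_mm"]), tuple(g["sagittal_mm"]))


def write_plane_set(planes: PlaneSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "grid": {
                    "axial_mm": list(planes.axial_mm),
                    "coronal_mm": list(planes.coronal_mm),
                    "sagittal_mm": list(planes.sagittal_mm),
                }
            },
            fh,
        )


def run_full_pipeline(config: RunConfig, specs=None) -> dict:
    """Simulate a cohort, then run topography, statistics and prediction.

    Writes, under ``config.out_dir``: per-group frequency maps (NIfTI),
    per-patient occupancy summary, the between-group battery table, the
    univariable seizure regression table, the diagnosis model metrics table
    and a provenance run log.  Deterministic under a fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if specs is None:
        specs = default_group_specs()
    grid = build_grid(config.plane_set(), config.geometry())
    cohort = simulate_cohort(specs, grid, config.seed)
    table = cohort.table.copy()

    # topography recomputed from masks, overriding the drawn covariates
    summary = cohort_summary(
        cohort.masks, grid, config.min_overlap_mm3, config.bilateral_threshold
    )
    table = table.drop(columns=["bg_voxel_count", "volume_ml", "laterality"]).merge(
        summary, on="patient_id"
    )
    table.to_csv(out / "cohort.csv", index=False)

    freq_info = {}
    for spec in specs:
        masks = [m for m, g in zip(cohort.masks, cohort.table["group"]) if g == spec.name]
        fmap = occurrence_map(masks, grid, group=spec.name)
        write_volume(fmap.data, fmap.affine, out / f"freqmap_{spec.name}.nii.gz")
        fmap.cell_table.to_csv(out / f"cells_{spec.name}.csv", index=False)
        mn, mx = minmax_frequency(fmap)
        freq_info[spec.name] = {"min_nonzero_pct": mn, "max_pct": mx}

    battery = group_comparison_battery(table)
    battery.to_csv(out / "between_groups.csv", index=False)

    uni = fit_binary_logistic(
        table["seizure"].to_numpy(),
        table[["age", "volume_ml", "bg_voxel_count"]],
        univariable=True,
    )
    pd.concat([f.to_frame() for f in uni], ignore_index=True).to_csv(
        out / "seizure_univariable.csv", index=False
    )
    multi = forward_conditional_select(
        table["seizure"].to_numpy(),
        table[["age", "volume_ml", "bg_voxel_count"]],
        p_enter=config.p_enter,
        p_remove=config.p_remove,
    )
    multi.to_frame().to_csv(out / "seizure_multivariable.csv", index=False)

    X = pd.DataFrame(
        {
            "age_gt40": (table["age"] > 40).astype(float),
            "seizure": table["seizure"].astype(float),
            "cognitive_deficit": table["cognitive_deficit"].astype(float),
            "bg_voxel_count": table["bg_voxel_count"].astype(float),
        }
    )
    model = fit_multinomial(table["group"], X, reference="astro_IDHm")
    metrics = classification_metrics(model, table["group"])
    metrics_frame(metrics).to_csv(out / "diagnosis_metrics.csv", index=False)

    grid_codes = grid.rasterize()
    write_volume(grid_codes, grid.geometry.affine, out / "grid_labels.nii.gz")
    grid.code_table().to_csv(out / "grid_codes.csv", index=False)

    runlog = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_patients": int(len(table)),
        "groups": table["group"].value_counts().to_dict(),
        "frequency_maps": freq_info,
        "selected_seizure_predictors": multi.selected,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(runlog, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return runlog
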