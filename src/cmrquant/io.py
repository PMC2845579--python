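"""Readers and writers for phantom studies, contours, tables and configs.

Volumetric data travel as single-file NIfTI with a diagonal RAS-like
affine (axis order slice, row, col[, frame]); acquisition metadata that
NIfTI cannot carry (frame times, state, mask label codes, voxel volume)
ride in a JSON sidecar next to each image.  Tabular outputs are UTF-8
CSV with a fixed column order and floats at six significant digits.
Configuration is YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .function import ContourSet, SliceContours
from .lge import LGEStudy
from .perfusion import PerfusionStudy
from .synthetic import AIFParams, FermiShape, PhantomConfig

#: integer codes in perfusion / LGE label maps
LABEL_MYO = 1
LABEL_REMOTE = 2
LABEL_BLOOD_POOL = 2

_FLOAT_FMT = "%.6g"

PERFUSION_COLUMNS = [
    "segment_id", "slice_level", "territory", "label",
    "mbf_rest", "mbf_stress", "mpr", "convergence",
]
LGE_COLUMNS = [
    "mde_total_g", "mde_core_g", "mde_peri_g",
    "pct_total_of_lv", "pct_core_of_total", "pct_peri_of_total",
    "transmurality_class",
]
FUNCTION_COLUMNS = ["edv_ml", "esv_ml", "ef_pct", "mass_g"]


def write_csv(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> None:
    if columns is not None:
        df = df[columns]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _affine(voxel_mm: float = 1.0) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


# ---------------------------------------------------------------------------
# perfusion studies
# ---------------------------------------------------------------------------

def save_perfusion_study(study: PerfusionStudy, prefix: str | Path) -> None:
    """Write <prefix>.nii (4D), <prefix>_labels.nii and <prefix>.json."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(study.data, _affine()), f"{prefix}.nii")
    labels = study.myo_masks.astype(np.int16) * LABEL_MYO
    labels[0][study.blood_pool_mask] = LABEL_BLOOD_POOL
    nib.save(nib.Nifti1Image(labels, _affine()), f"{prefix}_labels.nii")
    sidecar = {
        "frame_times_s": study.frame_times.tolist(),
        "state": study.state,
        "slice_levels": list(study.slice_levels),
        "n_baseline_frames": study.n_baseline_frames,
        "labels": {"myocardium": LABEL_MYO, "blood_pool": LABEL_BLOOD_POOL},
    }
    Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=1))


def load_perfusion_study(prefix: str | Path) -> PerfusionStudy:
    prefix = Path(prefix)
    data = np.asarray(nib.load(f"{prefix}.nii").dataobj, dtype=float)
    labels = np.asarray(nib.load(f"{prefix}_labels.nii").dataobj)
    meta = json.loads(Path(f"{prefix}.json").read_text())
    return PerfusionStudy(
        data=data,
        frame_times=np.array(meta["frame_times_s"]),
        myo_masks=labels == LABEL_MYO,
        blood_pool_mask=labels[0] == LABEL_BLOOD_POOL,
        state=meta["state"],
        slice_levels=tuple(meta["slice_levels"]),
        n_baseline_frames=int(meta["n_baseline_frames"]),
    )


# ---------------------------------------------------------------------------
# LGE studies
# ---------------------------------------------------------------------------

def save_lge_study(study: LGEStudy, prefix: str | Path) -> None:
    """Write <prefix>.nii, <prefix>_labels.nii (1 myo, 2 remote), JSON."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(study.image, _affine()), f"{prefix}.nii")
    labels = study.myo_mask.astype(np.int16) * LABEL_MYO
    labels[study.remote_mask] = LABEL_REMOTE
    nib.save(nib.Nifti1Image(labels, _affine()), f"{prefix}_labels.nii")
    sidecar = {
        "voxel_volume_ml": study.voxel_volume_ml,
        "density_g_per_ml": study.density_g_per_ml,
        "labels": {"myocardium": LABEL_MYO, "remote": LABEL_REMOTE},
    }
    Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=1))


def load_lge_study(prefix: str | Path) -> LGEStudy:
    prefix = Path(prefix)
    image = np.asarray(nib.load(f"{prefix}.nii").dataobj, dtype=float)
    labels = np.asarray(nib.load(f"{prefix}_labels.nii").dataobj)
    meta = json.loads(Path(f"{prefix}.json").read_text())
    return LGEStudy(
        image=image,
        myo_mask=labels >= LABEL_MYO,
        remote_mask=labels == LABEL_REMOTE,
        voxel_volume_ml=float(meta["voxel_volume_ml"]),
        density_g_per_ml=float(meta["density_g_per_ml"]),
    )


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

def save_contours(contours: ContourSet, path: str | Path) -> None:
    doc = {
        "slice_thickness_mm": contours.slice_thickness_mm,
        "min_basal_area_mm2": contours.min_basal_area_mm2,
        "ed": [
            {"endo": sc.endo.tolist(),
             "epi": None if sc.epi is None else sc.epi.tolist()}
            for sc in contours.ed
        ],
        "es": [
            {"endo": sc.endo.tolist(),
             "epi": None if sc.epi is None else sc.epi.tolist()}
            for sc in contours.es
        ],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(doc))


def load_contours(path: str | Path) -> ContourSet:
    doc = json.loads(Path(path).read_text())

    def make(entries):
        return [
            SliceContours(
                np.array(e["endo"]),
                None if e["epi"] is None else np.array(e["epi"]),
            )
            for e in entries
        ]

    return ContourSet(
        ed=make(doc["ed"]), es=make(doc["es"]),
        slice_thickness_mm=float(doc["slice_thickness_mm"]),
        min_basal_area_mm2=float(doc.get("min_basal_area_mm2", 100.0)),
    )


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    SD multipliers must be positive and strictly ordered; the paired-test
    significance level alpha must lie in (0, 1).
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    k_total: float = 2.0
    k_core: float = 3.0
    density_g_per_ml: float = 1.05
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.k_total < self.k_core):
            raise ValueError(
                "SD multipliers must be positive with k_total < k_core"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.density_g_per_ml <= 0:
            raise ValueError("tissue density must be positive")


def _config_to_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["phantom"]["grid_shape"] = list(config.phantom.grid_shape)
    return d


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    ph = doc.pop("phantom", {})
    if "aif_params" in ph:
        ph["aif_params"] = AIFParams(**ph["aif_params"])
    if "fermi_shape" in ph:
        ph["fermi_shape"] = FermiShape(**ph["fermi_shape"])
    if "grid_shape" in ph:
        ph["grid_shape"] = tuple(ph["grid_shape"])
    if "effect_sizes" in ph:
        ph["effect_sizes"] = {
            k: ((v[0][0], v[0][1]), (v[1][0], v[1][1]))
            for k, v in ph["effect_sizes"].items()
        }
    return PipelineConfig(phantom=PhantomConfig(**ph), **doc)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config)))


def config_hash(config: PipelineConfig) -> str:
    """SHA-256 of the canonicalized (sorted-key JSON) configuration."""
    canon = json.dumps(_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
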