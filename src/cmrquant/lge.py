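"""Late gadolinium enhancement (LGE) scar quantification.

Infarcted myocardium retains gadolinium and appears hyperenhanced once
normal myocardium is nulled.  Voxels are classified against a reference
remote region of visibly normal myocardium on the same slice: total
delayed enhancement is signal intensity above the remote mean + 2 SD,
the strongly enhanced infarct core is above + 3 SD, and the heterogeneous
peri-infarct zone is the 2-to-3 SD band.  Masses follow from voxel counts
times voxel volume times myocardial tissue density (1.05 g/mL), and are
reported absolutely and as percentages of LV mass and of total scar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

TISSUE_DENSITY_G_PER_ML = 1.05

#: label-map codes for the exported partition
LABEL_PERI = 1
LABEL_CORE = 2


@dataclass
class LGEStudy:
    """One LGE short-axis stack with myocardium and remote-ROI masks.

    ``image`` is (n_slices, rows, cols); masks are boolean arrays of the
    same shape.  The remote ROI must lie inside the myocardium on every
    slice where enhancement is analysed.
    """

    image: np.ndarray
    myo_mask: np.ndarray
    remote_mask: np.ndarray
    voxel_volume_ml: float
    density_g_per_ml: float = TISSUE_DENSITY_G_PER_ML

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.myo_mask = np.asarray(self.myo_mask, dtype=bool)
        self.remote_mask = np.asarray(self.remote_mask, dtype=bool)
        if self.image.ndim != 3:
            raise ValueError("image must be (slices, rows, cols)")
        if self.myo_mask.shape != self.image.shape:
            raise ValueError("myocardium mask must match image shape")
        if self.remote_mask.shape != self.image.shape:
            raise ValueError("remote mask must match image shape")
        if np.any(self.remote_mask & ~self.myo_mask):
            raise ValueError("remote ROI must lie inside the myocardium")
        if self.voxel_volume_ml <= 0:
            raise ValueError("voxel volume must be positive")

    @property
    def n_slices(self) -> int:
        return int(self.image.shape[0])


@dataclass
class InfarctPartition:
    """Core / peri-infarct / total masks and the derived mass metrics."""

    total_mask: np.ndarray
    core_mask: np.ndarray
    peri_mask: np.ndarray
    mde_total_g: float
    mde_core_g: float
    mde_peri_g: float
    pct_core_of_total: float
    pct_peri_of_total: float
    remote_stats: list[tuple[float, float]] = field(default_factory=list)
    pct_total_of_lv: float = float("nan")

    def label_map(self) -> np.ndarray:
        out = np.zeros(self.total_mask.shape, dtype=np.int16)
        out[self.peri_mask] = LABEL_PERI
        out[self.core_mask] = LABEL_CORE
        return out


def remote_stats(study: LGEStudy, slice_index: int) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of remote-ROI intensities on one slice.

    A remote ROI smaller than 8 voxels is accepted with an
    unreliable-reference warning; an empty ROI is an error.
    """
    vals = study.image[slice_index][study.remote_mask[slice_index]]
    if vals.size == 0:
        raise ValueError(f"remote ROI is empty on slice {slice_index}")
    if vals.size < 8:
        warnings.warn(
            f"remote ROI on slice {slice_index} has only {vals.size} voxels; "
            "reference statistics may be unreliable"
        )
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


class InfarctSegmenter(BaseEstimator):
    """Remote-referenced SD-threshold voxel classifier.

    ``fit`` computes per-slice remote statistics and the two thresholds;
    ``predict`` labels myocardial voxels (0 normal, 1 peri-infarct,
    2 core).  Membership above a threshold is strict (``>``); a voxel
    exactly at the 3 SD boundary stays in the peri-infarct band.  A
    degenerate remote reference (SD = 0) collapses both thresholds to the
    remote mean, so any voxel strictly above it is core.

    Parameters
    ----------
    k_total, k_core : float
        SD multipliers for the total and core thresholds (defaults 2, 3).

    Attributes
    ----------
    remote_stats_ : list of (mean, sd) per slice.
    thresholds_ : (n_slices, 2) array of (total, core) thresholds.
    """

    def __init__(self, k_total: float = 2.0, k_core: float = 3.0) -> None:
        self.k_total = k_total
        self.k_core = k_core

    def fit(self, study: LGEStudy) -> "InfarctSegmenter":
        if not (0 < self.k_total < self.k_core):
            raise ValueError("SD multipliers must be positive and ordered")
        if not study.myo_mask.any():
            raise ValueError("myocardium mask is empty")
        self.remote_stats_ = [
            remote_stats(study, s) for s in range(study.n_slices)
        ]
        self.thresholds_ = np.array(
            [
                (mu + self.k_total * sd, mu + self.k_core * sd)
                for mu, sd in self.remote_stats_
            ]
        )
        return self

    def predict(self, study: LGEStudy) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("call fit() before predict()")
        labels = np.zeros(study.image.shape, dtype=np.int16)
        for s in range(study.n_slices):
            t_total, t_core = self.thresholds_[s]
            myo = study.myo_mask[s]
            si = study.image[s]
            labels[s][myo & (si > t_total) & (si <= t_core)] = LABEL_PERI
            labels[s][myo & (si > t_core)] = LABEL_CORE
        return labels


def partition_infarct(study: LGEStudy) -> InfarctPartition:
    """Classify the myocardium into core and peri-infarct zones.

    Per slice, total = myocardial voxels with SI > remote mean + 2 SD;
    core = SI > mean + 3 SD; peri-infarct is the half-open band between
    them.  Masses are voxel count x voxel volume x 1.05 g/mL.
    """
    seg = InfarctSegmenter().fit(study)
    labels = seg.predict(study)
    core = labels == LABEL_CORE
    peri = labels == LABEL_PERI
    total = core | peri
    g_per_voxel = study.voxel_volume_ml * study.density_g_per_ml
    total_g = float(total.sum() * g_per_voxel)
    core_g = float(core.sum() * g_per_voxel)
    peri_g = float(peri.sum() * g_per_voxel)
    if total_g > 0:
        pct_core = 100.0 * core_g / total_g
        pct_peri = 100.0 * peri_g / total_g
    else:
        pct_core = pct_peri = 0.0
    return InfarctPartition(
        total_mask=total,
        core_mask=core,
        peri_mask=peri,
        mde_total_g=total_g,
        mde_core_g=core_g,
        mde_peri_g=peri_g,
        pct_core_of_total=pct_core,
        pct_peri_of_total=pct_peri,
        remote_stats=seg.remote_stats_,
    )


def pct_infarct_of_lv(partition: InfarctPartition, lv_mass_g: float) -> float:
    """Total scar mass as a percentage of LV mass (%MDE_total)."""
    if lv_mass_g <= 0:
        raise ValueError("LV mass must be positive")
    return 100.0 * partition.mde_total_g / lv_mass_g


# ---------------------------------------------------------------------------
# transmural extent
# ---------------------------------------------------------------------------

TRANSMURALITY_CLASSES = ("<50%", "50-75%", ">75%")


def classify_transmurality(fraction: float) -> str:
    """Class boundaries closed on the left: 0.5 maps to '50-75%'."""
    if fraction < 0.5:
        return "<50%"
    if fraction <= 0.75:
        return "50-75%"
    return ">75%"


def transmural_extent(
    partition: InfarctPartition,
    study: LGEStudy,
    n_sectors: int = 6,
    rays_per_sector: int = 36,
    center: tuple[float, float] | None = None,
) -> dict:
    """Per-sector transmurality of the total-enhancement mask.

    Radial rays from the myocardial centroid sample the wall; per sector
    the transmurality is the mean over rays of (infarcted chord length) /
    (wall chord length).  Sectors whose rays never cross the wall are
    skipped with a warning.  The per-study class is the maximum sector
    class.
    """
    slices_fracs: dict[int, list[float]] = {i: [] for i in range(n_sectors)}
    for s in range(study.n_slices):
        myo = study.myo_mask[s]
        if not myo.any():
            continue
        c = np.argwhere(myo).mean(axis=0) if center is None else np.array(center)
        inf = partition.total_mask[s]
        rmax = float(np.hypot(*myo.shape))
        radii = np.arange(0.25, rmax, 0.5)
        for sector in range(n_sectors):
            for j in range(rays_per_sector):
                ang = 2 * np.pi * (sector + (j + 0.5) / rays_per_sector) / n_sectors
                rr = np.round(c[0] - radii * np.sin(ang)).astype(int)
                cc = np.round(c[1] + radii * np.cos(ang)).astype(int)
                ok = (rr >= 0) & (rr < myo.shape[0]) & (cc >= 0) & (cc < myo.shape[1])
                wall = myo[rr[ok], cc[ok]]
                n_wall = int(wall.sum())
                if n_wall == 0:
                    continue
                n_inf = int(inf[rr[ok], cc[ok]][wall].sum())
                slices_fracs[sector].append(n_inf / n_wall)

    per_sector = {}
    for sector, fracs in slices_fracs.items():
        if not fracs:
            warnings.warn(f"sector {sector} has no wall crossings; skipped")
            continue
        frac = float(np.mean(fracs))
        per_sector[sector] = {
            "transmurality": frac,
            "class": classify_transmurality(frac),
        }
    if not per_sector:
        raise ValueError("no sector yielded a measurable wall")
    order = {c: i for i, c in enumerate(TRANSMURALITY_CLASSES)}
    study_class = max(
        (v["class"] for v in per_sector.values()), key=order.__getitem__
    )
    return {"sectors": per_sector, "study_class": study_class}
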