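"""Global LV function and regional wall thickening from traced contours.

Volumes follow Simpson's summation over short-axis slices: each slice
contributes its planimetered polygon area times the slice thickness plus
gap.  Ejection fraction is (EDV - ESV)/EDV x 100; LV mass is the
end-diastolic epicardial-minus-endocardial volume times the myocardial
tissue density of 1.05 g/mL.  Wall thickness per angular sector is the
mean epicardial-minus-endocardial radial distance along rays cast from
the endocardial centroid, and percent systolic wall thickening is
100 x (ES - ED)/ED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, Polygon

TISSUE_DENSITY_G_PER_ML = 1.05


class InvalidContourError(ValueError):
    """Contour polygon is unusable (self-intersecting or degenerate)."""


def polygon_area_mm2(vertices: np.ndarray) -> float:
    """Planimetered area of a simple polygon with vertices in mm."""
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InvalidContourError("contour needs at least 3 (x, y) vertices")
    if not LinearRing(pts).is_simple:
        raise InvalidContourError("contour polygon is self-intersecting")
    poly = Polygon(pts)
    if poly.area <= 0:
        raise InvalidContourError("contour polygon has non-positive area")
    return float(poly.area)


@dataclass
class SliceContours:
    """Endo/epi polygons for one short-axis slice at one cardiac phase."""

    endo: np.ndarray                # (n, 2) vertices in mm
    epi: np.ndarray | None = None   # optional on apical-most slices

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        if self.epi is not None:
            self.epi = np.asarray(self.epi, dtype=float)
            if not Polygon(self.epi).contains(Polygon(self.endo)):
                raise InvalidContourError(
                    "epicardial contour must enclose the endocardial contour"
                )


@dataclass
class ContourSet:
    """Per-slice ED and ES contours plus slice geometry.

    ``slice_thickness_mm`` includes any inter-slice gap (Simpson's rule
    multiplies each slice area by this increment).
    """

    ed: list[SliceContours]
    es: list[SliceContours]
    slice_thickness_mm: float
    min_basal_area_mm2: float = 100.0   # basal-slice inclusion cutoff (1 cm^2)

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")


def volume_from_contours(
    slices: list[SliceContours],
    slice_thickness_mm: float,
    surface: str = "endo",
    min_area_mm2: float = 0.0,
) -> float:
    """Simpson-summation cavity (endo) or epicardial volume in mL."""
    if not slices:
        raise ValueError("contour set contains no slices")
    total_mm3 = 0.0
    counted = 0
    for sc in slices:
        poly = sc.endo if surface == "endo" else sc.epi
        if poly is None:
            continue
        area = polygon_area_mm2(poly)
        if surface == "endo" and area <= min_area_mm2:
            continue  # basal slice mostly outflow tract: excluded
        total_mm3 += area * slice_thickness_mm
        counted += 1
    if counted == 0:
        raise ValueError(f"no valid {surface} contour in the set")
    return total_mm3 / 1000.0


def ejection_fraction(edv_ml: float, esv_ml: float) -> float:
    """EF % = 100 x (EDV - ESV) / EDV."""
    if edv_ml <= 0:
        raise ValueError("EDV must be positive")
    return 100.0 * (edv_ml - esv_ml) / edv_ml


def lv_mass(epi_volume_ed_ml: float, endo_volume_ed_ml: float) -> float:
    """LV mass in g = (epi ED volume - endo ED volume) x 1.05 g/mL."""
    if epi_volume_ed_ml <= endo_volume_ed_ml:
        raise ValueError("epicardial volume must exceed endocardial volume")
    return (epi_volume_ed_ml - endo_volume_ed_ml) * TISSUE_DENSITY_G_PER_ML


def wall_thickening(ed_thickness_mm: float, es_thickness_mm: float) -> float:
    """Percent systolic wall thickening, 100 x (ES - ED)/ED."""
    if ed_thickness_mm <= 0:
        raise ValueError("end-diastolic thickness must be positive")
    return 100.0 * (es_thickness_mm - ed_thickness_mm) / ed_thickness_mm


def _boundary_radius(poly: np.ndarray, center: np.ndarray, angle: float) -> float:
    """Distance from center to the polygon boundary along one ray.

    The boundary is treated in polar coordinates about the centroid; valid
    for the star-shaped contours of short-axis myocardium.
    """
    pts = np.asarray(poly, dtype=float) - center
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    r = np.hypot(pts[:, 0], pts[:, 1])
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # wrap for periodic interpolation
    theta = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r = np.concatenate([r, r, r])
    a = np.mod(angle + np.pi, 2 * np.pi) - np.pi
    return float(np.interp(a, theta, r))


def sector_wall_thickness(
    sc: SliceContours, n_sectors: int = 6, rays_per_sector: int = 36,
    origin_angle_deg: float = 0.0,
) -> np.ndarray:
    """Mean radial epi-endo distance per angular sector (mm).

    Rays are cast from the endocardial centroid; sectors are equiangular
    counterclockwise from ``origin_angle_deg``.  A sector whose wall is
    degenerate (epi radius not exceeding endo) yields NaN.
    """
    if sc.epi is None:
        raise ValueError("epicardial contour required for wall thickness")
    center = np.asarray(sc.endo, dtype=float).mean(axis=0)
    out = np.full(n_sectors, np.nan)
    for sector in range(n_sectors):
        vals = []
        for j in range(rays_per_sector):
            ang = np.radians(origin_angle_deg) + 2 * np.pi * (
                sector + (j + 0.5) / rays_per_sector
            ) / n_sectors
            t = _boundary_radius(sc.epi, center, ang) - _boundary_radius(
                sc.endo, center, ang
            )
            if t > 0:
                vals.append(t)
        if vals:
            out[sector] = float(np.mean(vals))
    return out


@dataclass
class VentricularFunction:
    edv_ml: float
    esv_ml: float
    ef_pct: float
    mass_g: float
    thickening_pct: dict[int, float]  # segment-style sector index -> %

    def __post_init__(self) -> None:
        if not (0.0 <= self.ef_pct <= 100.0):
            raise ValueError("EF must lie in [0, 100] %")
        if self.mass_g <= 0:
            raise ValueError("LV mass must be positive")


def quantify_function(
    contours: ContourSet, n_sectors: int = 6
) -> VentricularFunction:
    """EDV, ESV, EF, mass and per-sector thickening from one contour set.

    Thickening is averaged over slices carrying both contours; sectors
    with a non-positive ED thickness are excluded.
    """
    edv = volume_from_contours(
        contours.ed, contours.slice_thickness_mm, "endo",
        contours.min_basal_area_mm2,
    )
    esv = volume_from_contours(
        contours.es, contours.slice_thickness_mm, "endo",
        contours.min_basal_area_mm2,
    )
    # mass from the slices that carry both contours, so a basal endo slice
    # excluded by the area cutoff cannot unbalance the epi-endo difference
    both = [sc for sc in contours.ed if sc.epi is not None]
    epi_ed = volume_from_contours(both, contours.slice_thickness_mm, "epi")
    endo_ed = volume_from_contours(both, contours.slice_thickness_mm, "endo")
    ef = ejection_fraction(edv, esv)
    mass = lv_mass(epi_ed, endo_ed)

    per_sector: dict[int, list[float]] = {i: [] for i in range(n_sectors)}
    for ed_sc, es_sc in zip(contours.ed, contours.es):
        if ed_sc.epi is None or es_sc.epi is None:
            continue
        ed_t = sector_wall_thickness(ed_sc, n_sectors)
        es_t = sector_wall_thickness(es_sc, n_sectors)
        for i in range(n_sectors):
            if np.isfinite(ed_t[i]) and ed_t[i] > 0 and np.isfinite(es_t[i]):
                per_sector[i].append(wall_thickening(ed_t[i], es_t[i]))
    thickening = {
        i: float(np.mean(v)) for i, v in per_sector.items() if v
    }
    return VentricularFunction(
        edv_ml=edv, esv_ml=esv, ef_pct=ef, mass_g=mass,
        thickening_pct=thickening,
    )
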