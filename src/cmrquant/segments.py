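"""Standardized 16-segment model of the left ventricle.

Short-axis myocardium is divided into equiangular sectors at three slice
levels: six basal (segments 1-6), six mid-ventricular (7-12) and four
apical (13-16).  Angles are measured counterclockwise from the anterior
right-ventricular insertion point.  Each segment maps to a coronary
territory (LAD / RCA / LCX) and carries a targeted / non-targeted label
describing whether it lies in the ischaemic territory under treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SLICE_LEVELS = ("basal", "mid", "apical")

#: segment id -> (slice level, sector index within slice, coronary territory)
_SEGMENT_DEFS: dict[int, tuple[str, int, str]] = {
    1: ("basal", 0, "LAD"),    # basal anterior
    2: ("basal", 1, "LAD"),    # basal anteroseptal
    3: ("basal", 2, "RCA"),    # basal inferoseptal
    4: ("basal", 3, "RCA"),    # basal inferior
    5: ("basal", 4, "LCX"),    # basal inferolateral
    6: ("basal", 5, "LCX"),    # basal anterolateral
    7: ("mid", 0, "LAD"),
    8: ("mid", 1, "LAD"),
    9: ("mid", 2, "RCA"),
    10: ("mid", 3, "RCA"),
    11: ("mid", 4, "LCX"),
    12: ("mid", 5, "LCX"),
    13: ("apical", 0, "LAD"),  # apical anterior
    14: ("apical", 1, "LAD"),  # apical septal
    15: ("apical", 2, "RCA"),  # apical inferior
    16: ("apical", 3, "LCX"),  # apical lateral
}

_SECTORS_PER_LEVEL = {"basal": 6, "mid": 6, "apical": 4}


@dataclass(frozen=True)
class Segment:
    segment_id: int
    slice_level: str
    sector_index: int
    territory: str
    targeted: bool
    theta_start_deg: float  # counterclockwise from anterior RV insertion
    theta_end_deg: float


@dataclass
class SegmentModel:
    """16-segment model with angular sector boundaries and region labels.

    Parameters
    ----------
    targeted_territory : str
        Coronary territory whose segments carry the "targeted" label
        (the region that received intramyocardial injections).
    origin_angle_deg : float
        Image-frame angle of the anterior RV insertion point, i.e. the
        zero of the segment angular coordinate.
    """

    targeted_territory: str = "LAD"
    origin_angle_deg: float = 90.0
    segments: list[Segment] = field(init=False)

    def __post_init__(self) -> None:
        if self.targeted_territory not in {"LAD", "RCA", "LCX"}:
            raise ValueError(
                f"unknown coronary territory {self.targeted_territory!r}"
            )
        segs = []
        for sid, (level, idx, terr) in _SEGMENT_DEFS.items():
            width = 360.0 / _SECTORS_PER_LEVEL[level]
            segs.append(
                Segment(
                    segment_id=sid,
                    slice_level=level,
                    sector_index=idx,
                    territory=terr,
                    targeted=(terr == self.targeted_territory),
                    theta_start_deg=idx * width,
                    theta_end_deg=(idx + 1) * width,
                )
            )
        self.segments = segs

    def segments_for_level(self, level: str) -> list[Segment]:
        if level not in SLICE_LEVELS:
            raise ValueError(f"unknown slice level {level!r}")
        return [s for s in self.segments if s.slice_level == level]

    def segment(self, segment_id: int) -> Segment:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(segment_id)

    def sector_labels(
        self, level: str, rows: int, cols: int, center: tuple[float, float]
    ) -> np.ndarray:
        """Per-voxel sector index map for one slice.

        Angles run counterclockwise (in the y-up mathematical sense) from
        ``origin_angle_deg``; sectors are half-open ``[start, end)`` so the
        map partitions the full circle with no overlap.
        """
        rr, cc = np.mgrid[0:rows, 0:cols]
        # image rows increase downwards; negate to get a y-up frame
        theta = np.degrees(np.arctan2(-(rr - center[0]), cc - center[1]))
        theta = np.mod(theta - self.origin_angle_deg, 360.0)
        width = 360.0 / _SECTORS_PER_LEVEL[level]
        return np.floor(theta / width).astype(int)
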