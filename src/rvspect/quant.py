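"""RV polar map and uptake-ratio quantification.

The segmented RV myocardium is projected onto a 2D angular (bullseye) map:
each sector covers a (polar band, azimuth wedge) of directions from the RV
sphere center and carries the maximum LV-normalized count among the
myocardium voxels falling in it.  The free wall is split into three
circumferential segments (anterior, lateral, inferior) and the maximal and
average RV-to-LV uptake ratios are reported per segment on a 0-100 scale.
An elevated stress maximal ratio in the lateral segment associates with
severe left-coronary or three-vessel disease; the conventional decision
cutoff of 30 is exposed as a configurable threshold, not hard-coded logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScalarVolume
from .lv import LVResult
from .rv import RVSegmentationResult

SEGMENT_NAMES = ("anterior", "lateral", "inferior")
EXCLUDED = "excluded"
DEFAULT_RATIO_THRESHOLD = 30.0  # maximal RV/LV cutoff suggestive of CAD


@dataclass
class PolarMap:
    """Angular max-count map over (polar band, azimuth sector)."""

    grid: np.ndarray  # (n_polar, n_azimuth), NaN where excluded
    n_polar: int
    n_azimuth: int
    segment_labels: np.ndarray = field(default=None)  # (n_polar, n_azimuth) of str

    def __post_init__(self) -> None:
        if self.segment_labels is None:
            self.segment_labels = np.full(self.grid.shape, EXCLUDED, dtype=object)

    @property
    def included(self) -> np.ndarray:
        return ~np.isnan(self.grid)

    def values(self, segment: str) -> np.ndarray:
        m = (self.segment_labels == segment) & self.included
        return self.grid[m]


@dataclass
class QuantResult:
    """Per-segment and global RV/LV uptake ratios (percent) and cavity volume."""

    max_ratio: dict[str, float]
    mean_ratio: dict[str, float]
    global_max_ratio: float  # stress maximal RV/LV, lateral segment
    cavity_volume_ml: float = np.nan

    def as_dict(self) -> dict:
        return {
            "max_ratio_percent": self.max_ratio,
            "mean_ratio_percent": self.mean_ratio,
            "global_max_ratio_percent": self.global_max_ratio,
            "cavity_volume_ml": self.cavity_volume_ml,
        }


def build_polar_map(
    vol: ScalarVolume,
    rv: RVSegmentationResult,
    lv: LVResult | None = None,
    n_polar: int = 18,
    n_azimuth: int = 36,
    lv_max: float | None = None,
) -> PolarMap:
    """Per-sector maximum normalized count over the RV myocardium mask.

    Counts are normalized to the maximum LV count (pass either the LV result
    or an explicit ``lv_max``; raw counts otherwise assumed pre-normalized).
    Sectors containing no myocardium voxel are excluded (NaN).
    """
    if lv_max is None:
        lv_max = lv.max_count if lv is not None else 1.0
    mask = rv.mask_myocardium
    if not mask.any():
        raise ValueError("empty RV myocardium mask")
    idx = np.argwhere(mask)
    pts = idx * np.array(vol.spacing)
    rel = pts - rv.model.center_arr
    r = np.linalg.norm(rel, axis=1)
    r = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(rel[:, 2] / r, -1, 1))
    phi = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    i = np.clip((theta / np.pi * n_polar).astype(int), 0, n_polar - 1)
    j = np.clip((phi / (2 * np.pi) * n_azimuth).astype(int), 0, n_azimuth - 1)
    vals = vol.data[tuple(idx.T)] / lv_max
    grid = np.full((n_polar, n_azimuth), -np.inf)
    np.maximum.at(grid, (i, j), vals)
    grid[np.isinf(grid)] = np.nan
    return PolarMap(grid=grid, n_polar=n_polar, n_azimuth=n_azimuth)


def segment_polar_map(pmap: PolarMap, free_wall_center_deg: float = 180.0) -> PolarMap:
    """Label the free-wall azimuth range into three circumferential thirds.

    The azimuth columns containing myocardium form the free-wall arc; it is
    split into equal thirds labeled anterior / lateral / inferior in
    anatomical order (anterior on the -Y side, inferior on the +Y side, the
    lateral segment in between on the free wall).  Septal-facing sectors stay
    excluded.
    """
    included_cols = np.nonzero(pmap.included.any(axis=0))[0]
    if len(included_cols) == 0:
        raise ValueError("polar map has no included sectors")
    centers = (included_cols + 0.5) * 360.0 / pmap.n_azimuth
    # order along the arc from the anterior edge (most negative offset from
    # the free-wall center; -Y is at azimuth 270 deg, +Y at 90 deg)
    offset = (centers - free_wall_center_deg + 180.0) % 360.0 - 180.0
    order = np.argsort(-offset)  # anterior side (toward 270 deg) first
    cols = included_cols[order]
    groups = np.array_split(cols, 3)
    labels = np.full(pmap.grid.shape, EXCLUDED, dtype=object)
    for name, grp in zip(SEGMENT_NAMES, groups):
        for c in grp:
            labels[:, c] = np.where(pmap.included[:, c], name, EXCLUDED)
    return PolarMap(
        grid=pmap.grid, n_polar=pmap.n_polar, n_azimuth=pmap.n_azimuth,
        segment_labels=labels,
    )


def rv_lv_ratios(pmap: PolarMap, cavity_volume_ml: float = np.nan) -> QuantResult:
    """Maximal and average RV/LV uptake ratios per segment, in percent.

    The global maximal ratio is reported from the lateral segment (the RV
    free wall), the quantity used for coronary-disease classification.
    """
    max_ratio, mean_ratio = {}, {}
    for name in SEGMENT_NAMES:
        vals = pmap.values(name)
        if len(vals) == 0:
            max_ratio[name] = np.nan
            mean_ratio[name] = np.nan
        else:
            max_ratio[name] = float(100.0 * vals.max())
            mean_ratio[name] = float(100.0 * vals.mean())
    return QuantResult(
        max_ratio=max_ratio,
        mean_ratio=mean_ratio,
        global_max_ratio=max_ratio["lateral"],
        cavity_volume_ml=cavity_volume_ml,
    )


def quantify(
    vol: ScalarVolume,
    lv: LVResult,
    rv: RVSegmentationResult,
    n_polar: int = 18,
    n_azimuth: int = 36,
) -> tuple[PolarMap, QuantResult]:
    """Polar map + uptake ratios + cavity volume in one call."""
    pmap = build_polar_map(vol, rv, lv=lv, n_polar=n_polar, n_azimuth=n_azimuth)
    pmap = segment_polar_map(pmap)
    return pmap, rv_lv_ratios(pmap, cavity_volume_ml=rv.cavity_volume_ml)
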