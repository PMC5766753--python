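"""Tongue analysis geometry: tip, midline, 1-cm bands, 16 grids, circle ROI.

The anterior 2 cm of the tongue is split through the midline into left (L)
and right (R) sides, into two 1-cm horizontal bands measured from the tip
(Band 1 = first centimetre, Band 2 = second), and each (side, band) into 4
equal-width vertical strips numbered from the midline outward, giving grids
L1–L8 and R1–R8 (1–4 in Band 1, 5–8 in Band 2).  A 6-mm diameter counting
circle is placed to the left of the midline as close to the tip as possible,
emulating the classic manual counting region.

Conventions: pixel coordinates are 0-based with (x = column, y = row) and
origin top-left; band intervals are half-open from the tip ([0, 10) mm and
[10, 20) mm); a centroid exactly on the midline counts as LEFT.  The tongue
tip is at the image bottom by default (protrusion downward in the frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .quantify import GRID_LABELS, Papilla, QuantResult, count_in_circle

logger = logging.getLogger(__name__)

__all__ = ["TongueGeometry", "derive_geometry", "assign_papillae", "summarize"]


@dataclass
class TongueGeometry:
    """Calibration plus the derived spatial partition of the tongue."""

    mm_per_px: float
    tongue_mask: np.ndarray
    tip_row: int
    midline_col: float
    tip_at: str = "bottom"
    band_edges_mm: tuple[float, float, float] = (0.0, 10.0, 20.0)
    #: lateral mask extreme column per (side, band), e.g. ("L", 1) -> min col
    band_extremes: dict[tuple[str, int], float] = field(default_factory=dict)
    circle_centre_px: tuple[float, float] | None = None
    circle_diameter_mm: float = 6.0

    # -- elementary assignment rules ------------------------------------

    def dist_from_tip_mm(self, y: float) -> float:
        d_px = (self.tip_row - y) if self.tip_at == "bottom" else (y - self.tip_row)
        return d_px * self.mm_per_px

    def side_of_x(self, x: float) -> str:
        return "L" if x <= self.midline_col else "R"

    def band_of_y(self, y: float) -> int | None:
        """1, 2, or None for beyond the second band."""
        d = self.dist_from_tip_mm(y)
        e0, e1, e2 = self.band_edges_mm
        if d < e0:
            d = e0  # numeric guard; mask pixels never protrude past the tip
        if d < e1:
            return 1
        if d < e2:
            return 2
        return None

    def grid_of(self, x: float, y: float) -> tuple[str, int, str] | None:
        """(side, band, grid label) for a point, or None beyond Band 2."""
        band = self.band_of_y(y)
        if band is None:
            return None
        side = self.side_of_x(x)
        inner = self.midline_col
        outer = self.band_extremes.get((side, band), inner)
        span = abs(outer - inner)
        if span <= 0:
            strip = 1
        else:
            frac = abs(x - inner) / span
            strip = min(3, int(frac * 4)) + 1
        grid_no = strip if band == 1 else strip + 4
        return side, band, f"{side}{grid_no}"

    def to_dict(self) -> dict:
        e0, e1, e2 = self.band_edges_mm
        return {
            "mm_per_px": self.mm_per_px,
            "tip_at": self.tip_at,
            "tip_row": int(self.tip_row),
            "midline_col": float(self.midline_col),
            "band_edges_mm": [e0, e1, e2],
            "band_extreme_cols": {
                f"{s}{b}": float(v) for (s, b), v in self.band_extremes.items()
            },
            "circle_centre_px": (
                None
                if self.circle_centre_px is None
                else [float(self.circle_centre_px[0]), float(self.circle_centre_px[1])]
            ),
            "circle_diameter_mm": self.circle_diameter_mm,
        }


def _band_rows(
    mask_rows: np.ndarray, tip_row: int, tip_at: str, mm_per_px: float, lo: float, hi: float
) -> np.ndarray:
    d = (tip_row - mask_rows) if tip_at == "bottom" else (mask_rows - tip_row)
    d_mm = d * mm_per_px
    return (d_mm >= lo) & (d_mm < hi)


def derive_geometry(
    tongue_mask: np.ndarray,
    mm_per_px: float,
    tip_at: str = "bottom",
    midline_col: float | None = None,
    circle_centre_px: tuple[float, float] | None = None,
    circle_diameter_mm: float = 6.0,
    band_edges_mm: tuple[float, float, float] = (0.0, 10.0, 20.0),
) -> TongueGeometry:
    """Derive the analysis geometry from the tongue mask and calibration.

    * tip row: the extreme mask row in the protrusion direction
      (bottom-most by default);
    * midline: the vertical line through the column centroid of the mask,
      unless overridden;
    * band lateral extremes: per (side, band), the outermost mask column,
      which anchors the 4 equal-width grid strips;
    * counting circle: unless an explicit centre is given, the circle is
      placed wholly inside the mask, right edge tangent to the midline,
      as close to the tip as possible.
    """
    tongue_mask = np.asarray(tongue_mask, dtype=bool)
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    if tip_at not in ("bottom", "top"):
        raise ValueError("tip_at must be 'bottom' or 'top'")
    rows, cols = np.nonzero(tongue_mask)
    if rows.size == 0:
        raise ValueError("tongue mask is empty")

    tip_row = int(rows.max()) if tip_at == "bottom" else int(rows.min())
    extent_mm = (rows.max() - rows.min() + 1) * mm_per_px
    if extent_mm < band_edges_mm[2]:
        logger.warning(
            "tongue mask spans only %.1f mm; Band 2 is truncated", extent_mm
        )
    if midline_col is None:
        midline_col = float(cols.mean())
    else:
        midline_col = float(midline_col)
        col_lo, col_hi = cols.min(), cols.max()
        if not (col_lo <= midline_col <= col_hi):
            raise ValueError("midline_col does not intersect the tongue mask")

    extremes: dict[tuple[str, int], float] = {}
    for band, (lo, hi) in ((1, band_edges_mm[:2]), (2, band_edges_mm[1:])):
        in_band = _band_rows(rows, tip_row, tip_at, mm_per_px, lo, hi)
        band_cols = cols[in_band]
        left = band_cols[band_cols <= midline_col]
        right = band_cols[band_cols > midline_col]
        extremes[("L", band)] = float(left.min()) if left.size else midline_col
        extremes[("R", band)] = float(right.max()) if right.size else midline_col

    geom = TongueGeometry(
        mm_per_px=mm_per_px,
        tongue_mask=tongue_mask,
        tip_row=tip_row,
        midline_col=midline_col,
        tip_at=tip_at,
        band_edges_mm=tuple(float(e) for e in band_edges_mm),
        band_extremes=extremes,
        circle_centre_px=circle_centre_px,
        circle_diameter_mm=float(circle_diameter_mm),
    )
    if geom.circle_centre_px is None:
        geom.circle_centre_px = _auto_circle_centre(geom)
    return geom


def _auto_circle_centre(geom: TongueGeometry) -> tuple[float, float] | None:
    """Place the counting circle inside the mask, tangent to the midline,
    minimal distance from the tip."""
    r_px = (geom.circle_diameter_mm / 2.0) / geom.mm_per_px
    edt = ndimage.distance_transform_edt(geom.tongue_mask)
    target_x = geom.midline_col - r_px
    fits = edt >= r_px + 1.0  # one-pixel safety against mask discretisation
    if not fits.any():
        logger.warning("no position fits a %.1f mm circle inside the mask", geom.circle_diameter_mm)
        return None
    rows, cols = np.nonzero(fits)
    on_left = cols <= geom.midline_col
    if on_left.any():
        rows, cols = rows[on_left], cols[on_left]
    # closest to the tip first, then x closest to midline-tangency
    tip_dist = (geom.tip_row - rows) if geom.tip_at == "bottom" else (rows - geom.tip_row)
    order = np.lexsort((np.abs(cols - target_x), tip_dist))
    best = order[0]
    return float(cols[best]), float(rows[best])


def assign_papillae(papillae: list[Papilla], geometry: TongueGeometry) -> list[Papilla]:
    """Fill side/band/grid for each papilla by its centroid.

    Papillae whose centroid lies beyond the second band are flagged
    ``in_region=False`` and excluded from all counts.
    """
    for p in papillae:
        x, y = p.centroid_px
        cell = geometry.grid_of(x, y)
        if cell is None:
            p.side, p.band, p.grid = None, None, None
            p.in_region = False
        else:
            p.side, p.band, p.grid = cell
            p.in_region = True
    return papillae


def summarize(
    papillae: list[Papilla],
    geometry: TongueGeometry,
    class_map: np.ndarray | None = None,
) -> QuantResult:
    """Assemble counts, density and the circle count into a QuantResult.

    Density = retained FP pixel area over tongue area; the tongue area
    comes from ``class_map`` (union of the three tongue classes) when given,
    else from ``geometry.tongue_mask``.  Count-conservation invariants are
    asserted by the QuantResult constructor.
    """
    included = [p for p in papillae if p.in_region]
    excluded = len(papillae) - len(included)
    if any(p.grid is None for p in included):
        raise ValueError("papillae must be assigned (run assign_papillae first)")

    grid_counts = {g: 0 for g in GRID_LABELS}
    band_counts = {1: 0, 2: 0}
    side_counts = {"L": 0, "R": 0}
    for p in included:
        grid_counts[p.grid] += 1
        band_counts[p.band] += 1
        side_counts[p.side] += 1

    if class_map is not None:
        from .quantify import compute_density

        density = compute_density(included, class_map)
    else:
        tongue_px = int(geometry.tongue_mask.sum())
        if tongue_px == 0:
            raise ValueError("tongue mask is empty")
        density = sum(p.area_px for p in included) / tongue_px

    if geometry.circle_centre_px is not None:
        circle = count_in_circle(
            included,
            geometry.circle_centre_px,
            geometry.circle_diameter_mm,
            geometry.mm_per_px,
        )
    else:
        circle = 0

    mean_diam = (
        float(np.mean([p.equiv_diameter_mm for p in included])) if included else 0.0
    )
    return QuantResult(
        total_count=len(included),
        density=float(density),
        count_band1=band_counts[1],
        count_band2=band_counts[2],
        count_left=side_counts["L"],
        count_right=side_counts["R"],
        count_per_grid=grid_counts,
        circle_count=circle,
        mean_equiv_diameter_mm=mean_diam,
        n_excluded=excluded,
        mm_per_px=geometry.mm_per_px,
    )
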