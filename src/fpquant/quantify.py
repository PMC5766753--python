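"""Per-papilla metrics from the segmented class map.

Each connected component of FUNGIFORM pixels is one detected fungiform
papilla (FP).  For every papilla the pixel area, physical area, centroid and
outer boundary are measured, and a circular-equivalent diameter is derived
under the assumption that FP are circular.  Whole-tongue summaries — total
count, FP density (FP area over tongue area) and the count inside a 6-mm
circle near the tongue tip — are computed here; spatial band/grid assignment
lives in :mod:`fpquant.geometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .segmentation import TONGUE_CLASSES, TissueClass

__all__ = [
    "Papilla",
    "QuantResult",
    "GRID_LABELS",
    "equivalent_diameter",
    "extract_papillae",
    "compute_density",
    "count_in_circle",
]

#: The 16 grid labels: 4 strips per (side, band), numbered from the midline
#: outward; 1–4 in Band 1 (first centimetre from the tip), 5–8 in Band 2.
GRID_LABELS: tuple[str, ...] = tuple(
    f"{side}{i}" for side in ("L", "R") for i in range(1, 9)
)


@dataclass
class Papilla:
    """One detected fungiform papilla.

    ``centroid_px`` and ``boundary_px`` use (x, y) = (column, row) pixel
    coordinates, 0-based, origin top-left.  ``side``/``band``/``grid`` are
    filled by :func:`fpquant.geometry.assign_papillae`; ``in_region`` is
    False for papillae whose centroid lies beyond the second 1-cm band
    (these are excluded from all counts).
    """

    id: int
    area_px: int
    area_mm2: float
    centroid_px: tuple[float, float]
    boundary_px: np.ndarray
    equiv_diameter_mm: float
    side: str | None = None        # "L" or "R"
    band: int | None = None        # 1 or 2
    grid: str | None = None        # "L1".."L8", "R1".."R8"
    in_region: bool = True


@dataclass
class QuantResult:
    """Whole-image FP summary with exact count-conservation invariants."""

    total_count: int
    density: float
    count_band1: int
    count_band2: int
    count_left: int
    count_right: int
    count_per_grid: dict[str, int]
    circle_count: int
    mean_equiv_diameter_mm: float
    n_excluded: int = 0
    mm_per_px: float = float("nan")

    def __post_init__(self) -> None:
        if self.count_band1 + self.count_band2 != self.total_count:
            raise ValueError("band counts do not sum to total_count")
        if self.count_left + self.count_right != self.total_count:
            raise ValueError("side counts do not sum to total_count")
        if sum(self.count_per_grid.values()) != self.total_count:
            raise ValueError("grid counts do not sum to total_count")
        if set(self.count_per_grid) != set(GRID_LABELS):
            raise ValueError("count_per_grid must have exactly the 16 grid labels")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError("density must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "total": self.total_count,
            "density": self.density,
            "band1": self.count_band1,
            "band2": self.count_band2,
            "left": self.count_left,
            "right": self.count_right,
            "circle_count": self.circle_count,
            "mean_equiv_diameter_mm": self.mean_equiv_diameter_mm,
            "n_excluded": self.n_excluded,
        }
        d.update({g: self.count_per_grid[g] for g in GRID_LABELS})
        return d


def equivalent_diameter(area_mm2: float) -> float:
    """Diameter of the circle with the given area: ``2 * sqrt(A / pi)``."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(area_mm2 / math.pi)


def extract_papillae(
    class_map: np.ndarray,
    mm_per_px: float,
    min_area_mm2: float = 0.01,
    connectivity: int = 8,
) -> list[Papilla]:
    """Extract FP as connected components of FUNGIFORM pixels.

    Components smaller than ``min_area_mm2`` are discarded as colour noise
    (default 0.01 mm^2, about 0.11 mm equivalent diameter — below any
    plausible papilla).  Papillae are ordered by their top-most, then
    left-most pixel, so extraction is deterministic.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent,
    the default: blob edges fragment less).
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    if min_area_mm2 < 0:
        raise ValueError("min_area_mm2 must be non-negative")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")

    fung = class_map == int(TissueClass.FUNGIFORM)
    labelled = measure.label(fung, connectivity=1 if connectivity == 4 else 2)
    props = measure.regionprops(labelled)

    px_area_mm2 = mm_per_px * mm_per_px
    records = []
    for p in props:
        area_px = int(p.area)
        area_mm2 = area_px * px_area_mm2
        if area_mm2 < min_area_mm2:
            continue
        coords = p.coords  # (N, 2) as (row, col)
        top_row = int(coords[:, 0].min())
        left_col_at_top = int(coords[coords[:, 0] == top_row, 1].min())
        cy, cx = p.centroid
        # outer contour of this component, in (x, y) order
        rmin, cmin, rmax, cmax = p.bbox
        patch = np.zeros((rmax - rmin + 2, cmax - cmin + 2), dtype=float)
        patch[1:-1, 1:-1] = p.image
        contours = measure.find_contours(patch, 0.5)
        boundary = max(contours, key=len) if contours else np.empty((0, 2))
        boundary = boundary[:, ::-1] + np.array([cmin - 1, rmin - 1])
        records.append(
            (
                (top_row, left_col_at_top),
                Papilla(
                    id=-1,
                    area_px=area_px,
                    area_mm2=area_mm2,
                    centroid_px=(float(cx), float(cy)),
                    boundary_px=boundary,
                    equiv_diameter_mm=equivalent_diameter(area_mm2),
                ),
            )
        )
    records.sort(key=lambda r: r[0])
    papillae = []
    for i, (_, pap) in enumerate(records, start=1):
        pap.id = i
        papillae.append(pap)
    return papillae


def compute_density(papillae: list[Papilla], class_map: np.ndarray) -> float:
    """FP density: retained FP pixel area over whole tongue area.

    The denominator is the union of the three tongue classes (fungiform +
    filiform + base); the numerator uses the papillae that survived the
    minimum-area filter, consistent with how they are counted.
    """
    tongue_px = int(
        sum((class_map == int(c)).sum() for c in TONGUE_CLASSES)
    )
    if tongue_px == 0:
        raise ValueError("class map contains no tongue pixels")
    fp_px = sum(p.area_px for p in papillae)
    return fp_px / tongue_px


def count_in_circle(
    papillae: list[Papilla],
    centre_px: tuple[float, float],
    diameter_mm: float,
    mm_per_px: float,
) -> int:
    """Count papillae whose centroid falls inside a circle (boundary inclusive).

    Emulates the common manual protocol of counting FP inside a 6-mm
    diameter circle placed near the tongue tip; membership is by centroid so
    counts over disjoint circles stay additive.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be positive")
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    r_px = (diameter_mm / 2.0) / mm_per_px
    cx, cy = centre_px
    n = 0
    for p in papillae:
        dx = p.centroid_px[0] - cx
        dy = p.centroid_px[1] - cy
        if math.hypot(dx, dy) <= r_px:
            n += 1
    return n
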