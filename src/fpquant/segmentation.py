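"""Colour-learning segmentation of tongue images.

The anterior tongue surface is segmented into three tissue classes —
fungiform papillae (pink, mushroom-shaped, the detection target), filiform
papillae (whitish, threadlike, non-gustatory) and tongue base (the light-pink
tissue in between) — by nearest-neighbour classification in CIELAB colour
space.  Class colours ("markers") are learned as the mean CIELAB colour of
user-supplied training ROIs; each pixel then receives the class of the
nearest marker under Euclidean colour distance.  A fourth BACKGROUND class
absorbs non-tongue pixels (lips, teeth, shadow) so the three tissue classes
tile exactly the tongue surface.

Sub-regions of the image may be re-analysed with locally learned markers and
merged back into the global result, which handles colour-shade drift across
the tongue (the tip is typically pinker than the posterior part).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
from skimage import color as _skcolor
from skimage.draw import polygon2mask

logger = logging.getLogger(__name__)

__all__ = [
    "TissueClass",
    "CLASS_PRIORITY",
    "TONGUE_CLASSES",
    "RoiSpec",
    "ColourMarker",
    "ReanalysisSpec",
    "rgb_to_lab",
    "roi_to_mask",
    "learn_markers",
    "classify_pixels",
    "reanalyze_region",
]


class TissueClass(IntEnum):
    """Pixel classes.  Integer values double as the indexed-PNG palette."""

    BACKGROUND = 0
    FUNGIFORM = 1
    FILIFORM = 2
    BASE = 3


#: Deterministic tie-break order for equidistant markers.
CLASS_PRIORITY: tuple[TissueClass, ...] = (
    TissueClass.FUNGIFORM,
    TissueClass.FILIFORM,
    TissueClass.BASE,
    TissueClass.BACKGROUND,
)

#: The classes whose union defines "the tongue" (the density denominator).
TONGUE_CLASSES: tuple[TissueClass, ...] = (
    TissueClass.FUNGIFORM,
    TissueClass.FILIFORM,
    TissueClass.BASE,
)


@dataclass(frozen=True)
class RoiSpec:
    """A training region for one tissue class.

    ``region`` is one of

    * an axis-aligned rectangle ``(x0, y0, width, height)`` in pixels
      (half-open, 0-based, x = column / y = row, origin top-left),
    * an ``(N, 2)`` array of polygon vertices in ``(x, y)`` pixel
      coordinates, or
    * an ``(H, W)`` boolean mask.
    """

    class_label: TissueClass
    region: object

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return roi_to_mask(self.region, shape)


@dataclass(frozen=True)
class ColourMarker:
    """The mean CIELAB colour of one class's pooled training pixels."""

    class_label: TissueClass
    mean_lab: tuple[float, float, float]
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("a colour marker needs at least one training pixel")


@dataclass
class ReanalysisSpec:
    """A rectangular sub-region to re-segment with locally learned markers.

    ``rectangle`` is ``(x0, y0, width, height)``; ``local_rois`` are training
    ROIs (clipped to the rectangle); alternatively ready-made
    ``local_markers`` may be given.
    """

    rectangle: tuple[int, int, int, int]
    local_rois: list[RoiSpec] = field(default_factory=list)
    local_markers: list[ColourMarker] = field(default_factory=list)


# ---------------------------------------------------------------------------
# colour conversion
# ---------------------------------------------------------------------------

def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB image to CIELAB (D65 reference white).

    Parameters
    ----------
    img
        ``(H, W, 3)`` array of sRGB values in 0–255.

    Returns
    -------
    ``(H, W, 3)`` float array; channel 0 is L* in [0, 100], channels 1–2
    are a*, b*.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB image, got shape {img.shape}"
        )
    if np.issubdtype(img.dtype, np.floating):
        if img.min() < 0 or img.max() > 255:
            raise ValueError("RGB values must lie in [0, 255]")
        arr = img / 255.0
    else:
        arr = img.astype(np.float64) / 255.0
    return _skcolor.rgb2lab(arr)


# ---------------------------------------------------------------------------
# ROI handling and marker learning
# ---------------------------------------------------------------------------

def roi_to_mask(region: object, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise an ROI region spec into an (H, W) boolean mask."""
    h, w = shape
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.shape != (h, w):
            raise ValueError("boolean ROI mask shape does not match image")
        return region
    region_arr = np.asarray(region)
    if region_arr.ndim == 1 and region_arr.size == 4:
        x0, y0, rw, rh = (int(v) for v in region_arr)
        if rw < 1 or rh < 1:
            raise ValueError("ROI rectangle must have positive width and height")
        if x0 < 0 or y0 < 0 or x0 + rw > w or y0 + rh > h:
            raise ValueError("ROI rectangle lies outside the image")
        m = np.zeros((h, w), dtype=bool)
        m[y0 : y0 + rh, x0 : x0 + rw] = True
        return m
    if region_arr.ndim == 2 and region_arr.shape[1] == 2:
        if region_arr.min() < 0 or (region_arr[:, 0] > w - 1).any() or (
            region_arr[:, 1] > h - 1
        ).any():
            raise ValueError("ROI polygon lies outside the image")
        # polygon2mask expects (row, col) vertex order
        m = polygon2mask((h, w), region_arr[:, ::-1])
        if not m.any():
            raise ValueError("ROI polygon contains no interior pixel")
        return m
    raise TypeError(
        "ROI region must be a rectangle (x0, y0, w, h), an (N, 2) polygon "
        "or a boolean mask"
    )


def learn_markers(
    img_lab: np.ndarray,
    rois: Sequence[RoiSpec],
    required: Iterable[TissueClass] = TONGUE_CLASSES,
) -> list[ColourMarker]:
    """Learn one colour marker per class as the mean CIELAB over pooled ROIs.

    Multiple ROIs of the same class are pooled (unweighted over all their
    pixels) because papilla colour shade varies across the tongue surface.

    Raises
    ------
    ValueError
        If any class in ``required`` ends up with zero training pixels.
    """
    h, w = img_lab.shape[:2]
    pixels: dict[TissueClass, list[np.ndarray]] = {}
    for roi in rois:
        m = roi.mask((h, w))
        pixels.setdefault(TissueClass(roi.class_label), []).append(img_lab[m])
    markers: list[ColourMarker] = []
    for cls in CLASS_PRIORITY:
        if cls not in pixels:
            continue
        pooled = np.concatenate(pixels[cls], axis=0)
        if pooled.shape[0] == 0:
            raise ValueError(f"class {cls.name} has zero ROI pixels")
        mean = pooled.mean(axis=0)
        markers.append(ColourMarker(cls, tuple(float(v) for v in mean), int(pooled.shape[0])))
    missing = [c for c in required if c not in {m.class_label for m in markers}]
    if missing:
        raise ValueError(
            "missing training ROIs for class(es): "
            + ", ".join(c.name for c in missing)
        )
    return markers


# ---------------------------------------------------------------------------
# nearest-neighbour classification
# ---------------------------------------------------------------------------

def classify_pixels(
    img_lab: np.ndarray,
    markers: Sequence[ColourMarker],
    analysis_mask: np.ndarray | None = None,
    channels: str = "lab",
) -> np.ndarray:
    """Assign every pixel the class of its nearest colour marker.

    Distance is Euclidean in (L*, a*, b*) by default; ``channels="ab"``
    drops the lightness channel for stronger illumination invariance.
    Ties go to the class earliest in :data:`CLASS_PRIORITY`, making the
    result deterministic and independent of marker input order.

    Pixels outside ``analysis_mask`` (if given) are labelled BACKGROUND.

    Returns an ``(H, W)`` uint8 label map with :class:`TissueClass` values.
    """
    if channels not in ("lab", "ab"):
        raise ValueError("channels must be 'lab' or 'ab'")
    labels_seen = [m.class_label for m in markers]
    if len(set(labels_seen)) != len(labels_seen):
        raise ValueError("duplicate class labels among markers")
    if len(labels_seen) < 2:
        raise ValueError("need at least two markers with distinct classes")

    ordered = sorted(markers, key=lambda m: CLASS_PRIORITY.index(m.class_label))
    data = img_lab[..., 1:] if channels == "ab" else img_lab
    h, w = img_lab.shape[:2]
    best_d = np.full((h, w), np.inf)
    out = np.full((h, w), int(TissueClass.BACKGROUND), dtype=np.uint8)
    for m in ordered:
        ref = np.asarray(m.mean_lab, dtype=np.float64)
        if channels == "ab":
            ref = ref[1:]
        d = ((data - ref) ** 2).sum(axis=-1)
        take = d < best_d  # strict '<': first (highest-priority) marker wins ties
        out[take] = int(m.class_label)
        best_d[take] = d[take]
    if analysis_mask is not None:
        analysis_mask = np.asarray(analysis_mask, dtype=bool)
        if analysis_mask.shape != (h, w):
            raise ValueError("analysis_mask shape does not match image")
        out[~analysis_mask] = int(TissueClass.BACKGROUND)
    return out


def reanalyze_region(
    img_lab: np.ndarray,
    base_map: np.ndarray,
    spec: ReanalysisSpec,
    global_markers: Sequence[ColourMarker] | None = None,
    analysis_mask: np.ndarray | None = None,
    channels: str = "lab",
) -> np.ndarray:
    """Re-segment a rectangular sub-region with local markers.

    Pixels inside ``spec.rectangle`` are re-classified using markers learned
    from ``spec.local_rois`` (clipped to the rectangle) or taken from
    ``spec.local_markers``; every pixel outside the rectangle is copied from
    ``base_map`` unchanged.  A tongue class absent from the local markers
    falls back to the corresponding global marker (logged), so the local
    marker set only needs to cover the classes that actually drift.
    """
    h, w = img_lab.shape[:2]
    x0, y0, rw, rh = (int(v) for v in spec.rectangle)
    if x0 < 0 or y0 < 0 or x0 + rw > w or y0 + rh > h or rw < 0 or rh < 0:
        raise ValueError("re-analysis rectangle lies outside the image")
    out = base_map.copy()
    if rw == 0 or rh == 0:
        return out

    rect_mask = np.zeros((h, w), dtype=bool)
    rect_mask[y0 : y0 + rh, x0 : x0 + rw] = True

    local: dict[TissueClass, ColourMarker] = {}
    if spec.local_rois:
        clipped = [
            RoiSpec(r.class_label, r.mask((h, w)) & rect_mask)
            for r in spec.local_rois
        ]
        clipped = [r for r in clipped if r.region.any()]
        for m in learn_markers(img_lab, clipped, required=()):
            local[m.class_label] = m
    for m in spec.local_markers:
        local[m.class_label] = m

    present = set(local)
    global_by_class = {m.class_label: m for m in (global_markers or [])}
    merged: list[ColourMarker] = []
    for cls in CLASS_PRIORITY:
        if cls in present:
            merged.append(local[cls])
        elif cls in global_by_class:
            if cls in TONGUE_CLASSES:
                logger.info(
                    "re-analysis rectangle has no local marker for %s; "
                    "falling back to the global marker",
                    cls.name,
                )
            merged.append(global_by_class[cls])
    tongue_missing = [c for c in TONGUE_CLASSES if c not in {m.class_label for m in merged}]
    if TissueClass.FUNGIFORM not in present and TissueClass.FUNGIFORM not in global_by_class:
        raise ValueError("re-analysis needs a FUNGIFORM marker (local or global)")
    if tongue_missing:
        raise ValueError(
            "no marker (local or global) for: " + ", ".join(c.name for c in tongue_missing)
        )

    sub_mask = rect_mask if analysis_mask is None else (rect_mask & np.asarray(analysis_mask, bool))
    sub = classify_pixels(img_lab, merged, analysis_mask=sub_mask, channels=channels)
    out[rect_mask] = sub[rect_mask]
    return out
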