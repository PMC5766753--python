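"""Config handling, image/mask I/O and the end-to-end pipeline runner.

The analysis is driven by a YAML or JSON config naming the image(s), the
mm-per-pixel calibration (derived from a ruler in frame at capture time),
the training ROIs per tissue class, optional re-analysis rectangles and
geometry overrides.  Outputs per image: indexed label mask PNG, QC overlay
PNG, per-papilla CSV, summary JSON and geometry JSON, plus a mean summary
across images of the same tongue.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import geometry as _geom
from . import quantify as _quant
from . import segmentation as _seg
from . import stats as _stats
from .quantify import GRID_LABELS, Papilla, QuantResult
from .segmentation import ReanalysisSpec, RoiSpec, TissueClass

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "load_config",
    "read_image",
    "read_mask",
    "write_label_png",
    "write_overlay_png",
    "papillae_to_dataframe",
    "rois_from_csv",
    "run_quantify",
    "run_validate",
]

#: overlay colours (RGB) per class for QC rendering
_CLASS_COLOURS = {
    TissueClass.BACKGROUND: (0, 0, 0),
    TissueClass.FUNGIFORM: (220, 30, 60),
    TissueClass.FILIFORM: (245, 245, 235),
    TissueClass.BASE: (250, 180, 185),
}

_ROI_CLASS_NAMES = {
    "fungiform": TissueClass.FUNGIFORM,
    "filiform": TissueClass.FILIFORM,
    "base": TissueClass.BASE,
    "background": TissueClass.BACKGROUND,
}


@dataclass
class AnalysisConfig:
    """Validated analysis settings (see package docs for the file schema)."""

    images: list[Path]
    mm_per_px: float
    rois: list[RoiSpec]
    tongue_mask_path: Path | None = None
    reanalysis: list[ReanalysisSpec] = field(default_factory=list)
    tip_at: str = "bottom"
    midline_col: float | None = None
    circle_centre_px: tuple[float, float] | None = None
    circle_diameter_mm: float = 6.0
    min_area_mm2: float = 0.01
    connectivity: int = 8
    distance_channels: str = "lab"
    out_dir: Path = Path("fpquant_out")
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)


def _parse_roi_entry(cls: TissueClass, entry) -> RoiSpec:
    if isinstance(entry, dict):
        if "rect" in entry:
            return RoiSpec(cls, np.asarray(entry["rect"]))
        if "polygon" in entry:
            return RoiSpec(cls, np.asarray(entry["polygon"], dtype=float))
        raise ValueError(f"ROI entry for {cls.name} must have 'rect' or 'polygon'")
    return RoiSpec(cls, np.asarray(entry))


def _parse_rois(spec: dict) -> list[RoiSpec]:
    rois: list[RoiSpec] = []
    for name, entries in (spec or {}).items():
        key = name.lower()
        if key not in _ROI_CLASS_NAMES:
            raise ValueError(f"unknown ROI class '{name}'")
        cls = _ROI_CLASS_NAMES[key]
        if not isinstance(entries, list):
            entries = [entries]
        rois.extend(_parse_roi_entry(cls, e) for e in entries)
    return rois


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and schema-validate a YAML/JSON analysis config.

    Validation happens before any computation: referenced files must exist,
    the calibration must be positive, and the three tongue classes must each
    have at least one training ROI.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    base = path.parent

    imgs = raw.get("images", raw.get("image"))
    if imgs is None:
        raise ValueError("config must name 'image' or 'images'")
    if not isinstance(imgs, list):
        imgs = [imgs]
    images = []
    for p in imgs:
        ip = (base / p).resolve() if not Path(p).is_absolute() else Path(p)
        if not ip.exists():
            raise FileNotFoundError(f"image not found: {ip}")
        images.append(ip)

    mm_per_px = float(raw.get("mm_per_px", 0))
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be a positive number")

    rois = _parse_rois(raw.get("rois", {}))
    have = {r.class_label for r in rois}
    missing = [c for c in _seg.TONGUE_CLASSES if c not in have]
    if missing:
        raise ValueError(
            "missing ROI definitions for class(es): "
            + ", ".join(c.name for c in missing)
        )

    mask_path = raw.get("tongue_mask")
    if mask_path is not None:
        mask_path = (base / mask_path).resolve() if not Path(mask_path).is_absolute() else Path(mask_path)
        if not mask_path.exists():
            raise FileNotFoundError(f"tongue mask not found: {mask_path}")

    reanalysis = []
    for item in raw.get("reanalysis", []) or []:
        rect = tuple(int(v) for v in item["rect"])
        local = _parse_rois(item.get("rois", {}))
        reanalysis.append(ReanalysisSpec(rectangle=rect, local_rois=local))

    g = raw.get("geometry", {}) or {}
    tip_at = g.get("tip", "bottom")
    if tip_at not in ("bottom", "top"):
        raise ValueError("geometry.tip must be 'bottom' or 'top'")
    centre = g.get("circle_centre")
    if centre is not None:
        centre = (float(centre[0]), float(centre[1]))

    connectivity = int(raw.get("connectivity", 8))
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    channels = raw.get("distance_channels", "lab")
    if channels not in ("lab", "ab"):
        raise ValueError("distance_channels must be 'lab' or 'ab'")

    out_dir = raw.get("out_dir", "fpquant_out")
    out_dir = (base / out_dir) if not Path(out_dir).is_absolute() else Path(out_dir)

    return AnalysisConfig(
        images=images,
        mm_per_px=mm_per_px,
        rois=rois,
        tongue_mask_path=mask_path,
        reanalysis=reanalysis,
        tip_at=tip_at,
        midline_col=g.get("midline_col"),
        circle_centre_px=centre,
        circle_diameter_mm=float(g.get("circle_diameter_mm", 6.0)),
        min_area_mm2=float(raw.get("min_area_mm2", 0.01)),
        connectivity=connectivity,
        distance_channels=channels,
        out_dir=out_dir,
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )


# ---------------------------------------------------------------------------
# image / mask / artifact I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF/JPEG); alpha is dropped."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path}: expected an RGB image, got single channel")
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask PNG (0 = background, 255 = tongue)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_label_png(path: str | Path, class_map: np.ndarray) -> None:
    """Write the class map as an indexed PNG (palette index = class value)."""
    img = Image.fromarray(class_map.astype(np.uint8), mode="P")
    palette = [0] * 768
    for cls, rgb in _CLASS_COLOURS.items():
        palette[3 * int(cls) : 3 * int(cls) + 3] = list(rgb)
    img.putpalette(palette)
    img.save(path)


def _draw_vline(img: np.ndarray, col: float, colour=(0, 0, 255)) -> None:
    c = int(round(col))
    if 0 <= c < img.shape[1]:
        img[:, c] = colour


def _draw_hline(img: np.ndarray, row: float, colour=(0, 0, 255)) -> None:
    r = int(round(row))
    if 0 <= r < img.shape[0]:
        img[r, :] = colour


def write_overlay_png(
    path: str | Path,
    rgb: np.ndarray,
    class_map: np.ndarray,
    geometry: _geom.TongueGeometry | None = None,
    alpha: float = 0.45,
) -> None:
    """QC overlay: class colours blended over the photo plus geometry lines."""
    over = rgb.astype(float).copy()
    for cls, col in _CLASS_COLOURS.items():
        if cls == TissueClass.BACKGROUND:
            continue
        m = class_map == int(cls)
        over[m] = (1 - alpha) * over[m] + alpha * np.asarray(col, dtype=float)
    out = np.clip(np.rint(over), 0, 255).astype(np.uint8)
    if geometry is not None:
        mm = geometry.mm_per_px
        _draw_vline(out, geometry.midline_col)
        for e in geometry.band_edges_mm[1:]:
            row = geometry.tip_row - e / mm if geometry.tip_at == "bottom" else geometry.tip_row + e / mm
            _draw_hline(out, row)
        if geometry.circle_centre_px is not None:
            cx, cy = geometry.circle_centre_px
            r = (geometry.circle_diameter_mm / 2) / mm
            theta = np.linspace(0, 2 * np.pi, 512)
            xs = np.clip(np.rint(cx + r * np.cos(theta)).astype(int), 0, out.shape[1] - 1)
            ys = np.clip(np.rint(cy + r * np.sin(theta)).astype(int), 0, out.shape[0] - 1)
            out[ys, xs] = (0, 0, 255)
    iio.imwrite(path, out)


def papillae_to_dataframe(papillae: list[Papilla]) -> pd.DataFrame:
    rows = [
        {
            "id": p.id,
            "x_px": p.centroid_px[0],
            "y_px": p.centroid_px[1],
            "area_px": p.area_px,
            "area_mm2": p.area_mm2,
            "equiv_diameter_mm": p.equiv_diameter_mm,
            "side": p.side or "",
            "band": p.band if p.band is not None else "",
            "grid": p.grid or "",
            "in_region": p.in_region,
        }
        for p in papillae
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id", "x_px", "y_px", "area_px", "area_mm2",
            "equiv_diameter_mm", "side", "band", "grid", "in_region",
        ],
    )


def rois_from_csv(path: str | Path) -> list[RoiSpec]:
    """Convert rectangle ROIs exported from an annotation tool's CSV.

    Expects columns ``class,x,y,width,height`` (extra columns ignored);
    class names as in the config schema (fungiform/filiform/base/background).
    """
    df = pd.read_csv(path)
    needed = {"class", "x", "y", "width", "height"}
    if not needed.issubset(df.columns):
        raise ValueError(f"ROI CSV must have columns {sorted(needed)}")
    out = []
    for _, row in df.iterrows():
        cls = _ROI_CLASS_NAMES[str(row["class"]).strip().lower()]
        out.append(
            RoiSpec(cls, np.asarray(
                [int(row["x"]), int(row["y"]), int(row["width"]), int(row["height"])]
            ))
        )
    return out


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# pipeline runners
# ---------------------------------------------------------------------------

def quantify_image(
    rgb: np.ndarray, cfg: AnalysisConfig
) -> tuple[QuantResult, list[Papilla], np.ndarray, _geom.TongueGeometry]:
    """Segment → (re-analyse) → extract → geometry → assign → summarise."""
    lab = _seg.rgb_to_lab(rgb)
    markers = _seg.learn_markers(lab, cfg.rois)
    analysis_mask = read_mask(cfg.tongue_mask_path) if cfg.tongue_mask_path else None
    class_map = _seg.classify_pixels(
        lab, markers, analysis_mask=analysis_mask, channels=cfg.distance_channels
    )
    for spec in cfg.reanalysis:
        class_map = _seg.reanalyze_region(
            lab, class_map, spec,
            global_markers=markers,
            analysis_mask=analysis_mask,
            channels=cfg.distance_channels,
        )
    papillae = _quant.extract_papillae(
        class_map, cfg.mm_per_px, cfg.min_area_mm2, cfg.connectivity
    )
    tongue_mask = np.isin(class_map, [int(c) for c in _seg.TONGUE_CLASSES])
    geom = _geom.derive_geometry(
        tongue_mask,
        cfg.mm_per_px,
        tip_at=cfg.tip_at,
        midline_col=cfg.midline_col,
        circle_centre_px=cfg.circle_centre_px,
        circle_diameter_mm=cfg.circle_diameter_mm,
    )
    papillae = _geom.assign_papillae(papillae, geom)
    result = _geom.summarize(papillae, geom, class_map=class_map)
    return result, papillae, class_map, geom


def run_quantify(cfg: AnalysisConfig, write: bool = True) -> dict:
    """Run the full pipeline on every config image; write artifacts.

    Returns ``{"per_image": [summary dicts], "mean": averaged summary}``.
    Measures of the same tongue photographed several times are averaged
    across images, mirroring multi-image acquisition practice.
    """
    out_dir = Path(cfg.out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
    per_image = []
    for img_path in cfg.images:
        logger.info("processing %s", img_path)
        rgb = read_image(img_path)
        result, papillae, class_map, geom = quantify_image(rgb, cfg)
        summary = result.to_dict()
        summary["image"] = img_path.name
        per_image.append(summary)
        if write:
            stem_dir = out_dir / img_path.stem
            stem_dir.mkdir(parents=True, exist_ok=True)
            write_label_png(stem_dir / "labels.png", class_map)
            write_overlay_png(stem_dir / "overlay.png", rgb, class_map, geom)
            papillae_to_dataframe(papillae).to_csv(
                stem_dir / "papillae.csv", index=False, float_format="%.6f"
            )
            _json_dump(summary, stem_dir / "summary.json")
            _json_dump(geom.to_dict(), stem_dir / "geometry.json")

    numeric_keys = [k for k in per_image[0] if k != "image"]
    mean = {
        k: float(np.mean([s[k] for s in per_image])) for k in numeric_keys
    }
    mean["n_images"] = len(per_image)
    report = {"per_image": per_image, "mean": mean}
    if write:
        _json_dump(report, out_dir / "summary.json")
        _json_dump(cfg.raw, out_dir / "config_echo.json")
    return report


def run_validate(
    table: pd.DataFrame,
    x_col: str,
    y_col: str,
    rater_cols: list[str] | None = None,
) -> dict:
    """Method-agreement report for a tidy table of per-subject counts.

    ``x_col``/``y_col`` are the two methods to compare (e.g. automated vs
    reference counts); ``rater_cols`` optionally names >= 2 columns treated
    as repeated raters/images for the ICC.
    """
    for c in [x_col, y_col] + list(rater_cols or []):
        if c not in table.columns:
            raise ValueError(f"column '{c}' not in table")
    if len(table) < 3:
        raise ValueError("need at least 3 rows for agreement statistics")
    ba = _stats.bland_altman(table[x_col], table[y_col])
    sp = _stats.spearman(table[x_col], table[y_col])
    report = {
        "n": int(len(table)),
        "bland_altman": ba.to_dict(),
        "spearman": {"r": sp.r, "p_value": sp.p_value},
    }
    if rater_cols:
        icc = _stats.icc_two_way_random_absolute(table[list(rater_cols)].to_numpy())
        report["icc"] = icc.to_dict()
    return report
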