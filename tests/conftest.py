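"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately written along different
computational routes than the package (per-pixel loops, closed-form colour
chains, explicit variance-component decompositions) so they can serve as
independent references.
"""

from __future__ import annotations

import numpy as np
import pytest

from fpquant import (
    CLASS_PRIORITY,
    SyntheticParams,
    TissueClass,
    assign_papillae,
    classify_pixels,
    derive_geometry,
    extract_papillae,
    generate_tongue_image,
    markers_from_truth,
    rgb_to_lab,
    summarize,
    truth_to_manual_counts,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def srgb_to_lab_oracle(rgb):
    """Closed-form sRGB -> XYZ(D65) -> CIELAB chain, written independently."""
    c = np.asarray(rgb, dtype=float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    M = np.array(
        [
            [0.4124564, 0.3575761, 0.1804375],
            [0.2126729, 0.7151522, 0.0721750],
            [0.0193339, 0.1191920, 0.9503041],
        ]
    )
    xyz = M @ lin
    white = np.array([0.95047, 1.0, 1.08883])
    t = xyz / white
    delta = 6.0 / 29.0
    ft = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * ft[1] - 16.0
    a = 500.0 * (ft[0] - ft[1])
    b = 200.0 * (ft[1] - ft[2])
    return np.array([L, a, b])


def brute_force_classify(lab, markers):
    """Exhaustive per-pixel nearest-marker search (priority tie-break)."""
    h, w = lab.shape[:2]
    prio = {c: i for i, c in enumerate(CLASS_PRIORITY)}
    ms = sorted(markers, key=lambda m: prio[m.class_label])
    refs = [np.asarray(m.mean_lab) for m in ms]
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            px = lab[i, j]
            best_d = None
            best_c = None
            for m, ref in zip(ms, refs):
                d = float(((px - ref) ** 2).sum())
                if best_d is None or d < best_d:
                    best_d = d
                    best_c = m.class_label
            out[i, j] = int(best_c)
    return out


def icc_variance_components_oracle(m):
    """ICC(2,1)/(2,k) via explicit two-way random variance components.

    Decomposes the matrix cell-by-cell into subject, rater and residual
    effects, estimates the three variance components, and forms the
    absolute-agreement ratios from them.
    """
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += (m[i].sum() / k - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += (m[:, j].sum() / n - grand) ** 2
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            resid = m[i, j] - m[i].sum() / k - m[:, j].sum() / n + grand
            ss_err += resid**2
    msr = k * ss_rows / (n - 1)
    msc = n * ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    var_subject = (msr - mse) / k
    var_rater = (msc - mse) / n
    icc_single = var_subject / (var_subject + var_rater + mse)
    icc_average = var_subject / (var_subject + (var_rater + mse) / k)
    return icc_single, icc_average


def count_in_circle_oracle(centroids, centre, radius_px):
    n = 0
    for cx, cy in centroids:
        if ((cx - centre[0]) ** 2 + (cy - centre[1]) ** 2) ** 0.5 <= radius_px:
            n += 1
    return n


# ---------------------------------------------------------------------------
# pipeline helpers / fixtures
# ---------------------------------------------------------------------------

SMALL_PARAMS = SyntheticParams(
    shape_px=(250, 320),
    mm_per_px=0.1,
    tongue_half_width_mm=14.0,
    tongue_tip_depth_mm=11.0,
    n_papillae=40,
)


def small_params(**overrides):
    import dataclasses

    return dataclasses.replace(SMALL_PARAMS, **overrides)


def run_pipeline(img, truth, min_area_mm2=0.01):
    """Markers from truth patches -> segment -> extract -> assign -> summary."""
    mm = truth.params.mm_per_px
    markers = markers_from_truth(img, truth)
    cmap = classify_pixels(rgb_to_lab(img), markers)
    paps = extract_papillae(cmap, mm, min_area_mm2=min_area_mm2)
    tongue = np.isin(cmap, [int(c) for c in (TissueClass.FUNGIFORM, TissueClass.FILIFORM, TissueClass.BASE)])
    geom = derive_geometry(tongue, mm)
    paps = assign_papillae(paps, geom)
    return summarize(paps, geom, class_map=cmap), paps, cmap, geom


@pytest.fixture(scope="session")
def small_tongue():
    """One small noiseless synthetic tongue plus its truth and reference counts."""
    img, truth = generate_tongue_image(small_params(seed=7, noise_sigma=0.0))
    return img, truth, truth_to_manual_counts(truth)
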