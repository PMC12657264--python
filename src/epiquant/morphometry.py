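"""Myelin ultrastructure morphometry on TEM-like images and LFB stain metrics.

Per-fiber inner/outer diameter, G-ratio (inner/outer, lower = thicker
myelin) and sheath thickness are measured from segmented dark annuli;
pathology (sheath decompaction, contour disruption, intrasheath vesicles)
is scored per fiber. Optical density and corpus-callosum thickness cover
the Luxol-fast-blue readouts.

Diameters are equivalent-circle diameters, d = 2 sqrt(area / pi) — the
rotation-invariant convention standard in G-ratio studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, segmentation

__all__ = [
    "FiberSegment",
    "FiberMeasurement",
    "MorphometrySummary",
    "PathologyParams",
    "segment_fibers",
    "measure_fiber",
    "classify_pathology",
    "summarize_morphometry",
    "measure_od",
    "measure_thickness",
]


@dataclass
class FiberSegment:
    """One segmented fiber: sheath annulus mask and lumen mask."""

    label: int
    outer_mask: np.ndarray  # boolean, the dark sheath ring
    inner_mask: np.ndarray  # boolean, the lumen
    centroid: tuple[float, float]


@dataclass(frozen=True)
class FiberMeasurement:
    inner_diameter_um: float
    outer_diameter_um: float
    g_ratio: float
    thickness_um: float
    pathology_flag: bool = False
    decompaction_score: float = 0.0
    disruption_score: float = 0.0
    vesicle_score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.inner_diameter_um < self.outer_diameter_um):
            raise ValueError("require 0 < inner diameter < outer diameter")


@dataclass(frozen=True)
class MorphometrySummary:
    n_fibers: int
    pathological_pct: float
    mean_g_ratio: float
    mean_thickness_um: float
    mean_inner_um: float
    mean_outer_um: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass(frozen=True)
class PathologyParams:
    """Per-score thresholds; a fiber is flagged when any score exceeds its
    threshold. Defaults were tuned on the synthetic generator, where truth
    labels — not biological fidelity — are the test surface."""

    decompaction_cv: float = 0.10
    disruption: float = 0.10
    vesicle_count: float = 0.5
    vesicle_level_frac: float = 0.5  # brightness cut between sheath and lumen level
    min_vesicle_px: int = 3


# ---------------------------------------------------------------------------
# segmentation


def segment_fibers(
    image: np.ndarray,
    pixel_size_um: float,
    threshold: float | None = None,
    min_area_px: int = 64,
    min_lumen_frac: float = 0.10,
) -> list[FiberSegment]:
    """Segment dark annular sheaths on a light background.

    Sheath pixels are thresholded (Otsu unless ``threshold`` given), holes
    are filled, and filled regions containing several substantial lumens are
    split by a lumen-seeded watershed. Segments touching the image border
    are discarded, as are those below ``min_area_px``. Holes smaller than
    ``min_lumen_frac`` of their fiber (e.g. intrasheath vesicles) are not
    treated as lumens.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if threshold is None:
        # Otsu drifts toward the minority (sheath) class when most of the
        # field is background; the midpoint of the two class means is stable
        t0 = filters.threshold_otsu(image)
        threshold = (image[image < t0].mean() + image[image >= t0].mean()) / 2.0
    sheath = image < threshold
    filled = ndimage.binary_fill_holes(sheath)
    holes = filled & ~sheath

    filled_labels, _ = ndimage.label(filled)
    segments: list[FiberSegment] = []
    next_label = 1
    for region in measure.regionprops(filled_labels):
        rr0, cc0, rr1, cc1 = region.bbox
        if rr0 == 0 or cc0 == 0 or rr1 == image.shape[0] or cc1 == image.shape[1]:
            continue  # bisected by the border
        comp = filled_labels == region.label
        if comp.sum() < min_area_px:
            continue
        comp_holes = holes & comp
        hole_labels, n_holes = ndimage.label(comp_holes)
        if n_holes == 0:
            continue  # no resolvable lumen
        sizes = ndimage.sum_labels(np.ones_like(hole_labels), hole_labels, np.arange(1, n_holes + 1))
        lumen_ids = [i + 1 for i, s in enumerate(sizes) if s >= min_lumen_frac * comp.sum()]
        if not lumen_ids:
            continue
        if len(lumen_ids) == 1:
            lumen = hole_labels == lumen_ids[0]
            ring = comp & sheath
            cy, cx = ndimage.center_of_mass(comp)
            segments.append(FiberSegment(next_label, ring, lumen, (cy, cx)))
            next_label += 1
        else:
            # touching fibers: split the component between lumens
            markers = np.where(np.isin(hole_labels, lumen_ids), hole_labels, 0)
            dist = ndimage.distance_transform_edt(~comp_holes)
            basins = segmentation.watershed(dist, markers=markers, mask=comp)
            for lid in lumen_ids:
                basin = basins == lid
                lumen = hole_labels == lid
                ring = basin & sheath
                if ring.sum() < min_area_px:
                    continue
                cy, cx = ndimage.center_of_mass(basin)
                segments.append(FiberSegment(next_label, ring, lumen, (cy, cx)))
                next_label += 1
    return segments


def _equivalent_diameter(area_px: float, pixel_size_um: float) -> float:
    return 2.0 * math.sqrt(area_px / math.pi) * pixel_size_um


def measure_fiber(seg: FiberSegment, pixel_size_um: float) -> FiberMeasurement:
    """Equivalent-circle diameters, G-ratio and sheath thickness for a fiber."""
    inner_area = int(seg.inner_mask.sum())
    if inner_area == 0:
        raise ValueError(f"fiber {seg.label}: unresolvable lumen (empty inner mask)")
    outer_filled = ndimage.binary_fill_holes(seg.outer_mask | seg.inner_mask)
    outer_area = int(outer_filled.sum())
    d_in = _equivalent_diameter(inner_area, pixel_size_um)
    d_out = _equivalent_diameter(outer_area, pixel_size_um)
    return FiberMeasurement(
        inner_diameter_um=d_in,
        outer_diameter_um=d_out,
        g_ratio=d_in / d_out,
        thickness_um=(d_out - d_in) / 2.0,
    )


def classify_pathology(
    image: np.ndarray,
    seg: FiberSegment,
    params: PathologyParams = PathologyParams(),
    background_level: float | None = None,
) -> tuple[bool, dict]:
    """Score decompaction, contour disruption and intrasheath vesicles.

    decompaction = coefficient of variation of sheath-ring intensity;
    disruption = 1 - solidity of the filled fiber contour;
    vesicle = count of bright blobs inside the ring (pixels brighter than a
    cut between the ring median and the surrounding/background level).
    The flag is raised when any score strictly exceeds its threshold.
    """
    image = np.asarray(image, dtype=float)
    ring_vals = image[seg.outer_mask]
    ring_median = float(np.median(ring_vals))
    decompaction = float(ring_vals.std() / ring_vals.mean()) if ring_vals.mean() > 0 else 0.0

    outer_filled = ndimage.binary_fill_holes(seg.outer_mask | seg.inner_mask)
    props = measure.regionprops(outer_filled.astype(np.uint8))[0]
    disruption = 1.0 - float(props.solidity)

    if background_level is None:
        background_level = float(np.median(image[~outer_filled])) if (~outer_filled).any() else ring_median
    cut = ring_median + params.vesicle_level_frac * (background_level - ring_median)
    # scan the whole sheath zone (filled fiber minus lumen): vesicles are
    # bright, so they are excluded from the thresholded ring mask itself
    sheath_zone = outer_filled & ~seg.inner_mask
    bright = sheath_zone & (image > cut)
    labels, n_blobs = ndimage.label(bright)
    if n_blobs:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_blobs + 1))
        n_vesicles = int(np.sum(sizes >= params.min_vesicle_px))
    else:
        n_vesicles = 0

    scores = {
        "decompaction": decompaction,
        "disruption": disruption,
        "vesicle": float(n_vesicles),
    }
    flag = (
        decompaction > params.decompaction_cv
        or disruption > params.disruption
        or n_vesicles > params.vesicle_count
    )
    return flag, scores


def summarize_morphometry(measurements: list[FiberMeasurement]) -> MorphometrySummary:
    if not measurements:
        raise ValueError("no fiber measurements to summarise")
    n = len(measurements)
    return MorphometrySummary(
        n_fibers=n,
        pathological_pct=100.0 * sum(m.pathology_flag for m in measurements) / n,
        mean_g_ratio=float(np.mean([m.g_ratio for m in measurements])),
        mean_thickness_um=float(np.mean([m.thickness_um for m in measurements])),
        mean_inner_um=float(np.mean([m.inner_diameter_um for m in measurements])),
        mean_outer_um=float(np.mean([m.outer_diameter_um for m in measurements])),
    )


def measure_fibers(
    image: np.ndarray,
    pixel_size_um: float,
    pathology_params: PathologyParams = PathologyParams(),
    **segment_kwargs,
) -> pd.DataFrame:
    """Convenience: segment, measure and classify every fiber in an image."""
    segments = segment_fibers(image, pixel_size_um, **segment_kwargs)
    rows = []
    for seg in segments:
        meas = measure_fiber(seg, pixel_size_um)
        flag, scores = classify_pathology(image, seg, pathology_params)
        rows.append(
            {
                "label": seg.label,
                "centroid_row": seg.centroid[0],
                "centroid_col": seg.centroid[1],
                "inner_diameter_um": meas.inner_diameter_um,
                "outer_diameter_um": meas.outer_diameter_um,
                "g_ratio": meas.g_ratio,
                "thickness_um": meas.thickness_um,
                "pathology_flag": flag,
                **{f"{k}_score": v for k, v in scores.items()},
            }
        )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# LFB stain metrics


def measure_od(
    image: np.ndarray, roi_mask: np.ndarray, background_mask: np.ndarray
) -> float:
    """Optical density of a stained ROI relative to an unstained background.

    OD = log10(mean background intensity / mean ROI intensity); an ROI
    brighter than background gives a negative OD.
    """
    image = np.asarray(image, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not roi_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    if (roi_mask & background_mask).any():
        raise ValueError("ROI and background masks must be disjoint")
    roi_mean = float(image[roi_mask].mean())
    bg_mean = float(image[background_mask].mean())
    if roi_mean <= 0 or bg_mean <= 0:
        raise ValueError("mean intensities must be positive for OD")
    return math.log10(bg_mean / roi_mean)


def measure_thickness(
    mask: np.ndarray,
    axis_point: tuple[float, float],
    direction: tuple[float, float],
    pixel_size_um: float = 1.0,
    step_px: float = 0.25,
) -> float:
    """Straight-line thickness of a structure at a point.

    The line through ``axis_point`` (row, col) along ``direction`` is
    sampled at ``step_px`` resolution; the returned value is the length (in
    um) of the contiguous in-mask run nearest the axis point. A run that
    reaches the image boundary (e.g. a direction parallel to a band) is
    degenerate and raises.
    """
    mask = np.asarray(mask, dtype=bool)
    dr, dc = direction
    norm = math.hypot(dr, dc)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    dr, dc = dr / norm, dc / norm
    r0, c0 = axis_point
    diag = math.hypot(*mask.shape)
    ts = np.arange(-diag, diag + step_px, step_px)
    rr = r0 + ts * dr
    cc = c0 + ts * dc
    inside = (rr >= -0.5) & (rr < mask.shape[0] - 0.5) & (cc >= -0.5) & (cc < mask.shape[1] - 0.5)
    hit = np.zeros(ts.size, dtype=bool)
    ri = np.clip(np.round(rr[inside]).astype(int), 0, mask.shape[0] - 1)
    ci = np.clip(np.round(cc[inside]).astype(int), 0, mask.shape[1] - 1)
    hit[inside] = mask[ri, ci]
    if not hit.any():
        raise ValueError("line does not intersect the mask")
    # contiguous runs of hits; pick the one nearest t = 0
    padded = np.concatenate(([False], hit, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = list(zip(edges[0::2], edges[1::2]))
    t_zero = np.searchsorted(ts, 0.0)

    def run_dist(run):
        a, b = run
        if a <= t_zero < b:
            return 0.0
        return min(abs(ts[a]), abs(ts[b - 1]))

    a, b = min(runs, key=run_dist)
    inside_idx = np.flatnonzero(inside)
    # a run clipped by the image edge (still in-mask at the last sampled
    # point) means the direction runs along the structure: degenerate
    if a == inside_idx[0] or b - 1 == inside_idx[-1]:
        raise ValueError(
            "measurement line exits the image while inside the mask (degenerate direction)"
        )
    length_px = ts[b - 1] - ts[a] + step_px
    return float(length_px * pixel_size_um)
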