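"""From detections to the measured quantities.

Covers maximum-intensity projection, polygon ROI masking, the cross-mouse
section matching rule (a section position is used only if every mouse has
it), per-mouse totals normalized by injection-site cell counts, percentages
of the male-group mean, and inter-region log2 intensity ratios normalized to
the injection site and referenced to the NAC average.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .core import ImageStack

__all__ = [
    "MouseSummary",
    "max_project",
    "polygon_to_mask",
    "apply_roi",
    "match_sections",
    "summarize_mouse",
    "percent_of_male_mean",
    "region_mean_intensity",
    "log2_region_ratio",
]


@dataclass
class MouseSummary:
    """Per-mouse totals over matched sections and the derived densities.

    ``axon_density`` is skeleton pixels per red-channel (cytosolic reporter)
    labeled cell; ``bouton_density`` is boutons per green-channel (vesicular
    reporter) labeled cell. The percent-of-male fields are filled by
    :func:`percent_of_male_mean` at the cohort level.
    """

    mouse_id: str
    sex: str
    axon_pixels_total: int
    bouton_count_total: int
    tdtomato_cells_vta: int
    sypgfp_cells_vta: int
    bla_area_total_um2: float
    axon_density: float
    bouton_density: float
    axon_density_pct_male: float = np.nan
    bouton_density_pct_male: float = np.nan


def max_project(stack) -> np.ndarray:
    """Maximum-intensity projection of a z-stack to a single plane."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, dtype=float)
    if data.ndim == 2:
        return data.copy()
    if data.ndim != 3 or data.shape[0] < 1:
        raise ValueError("expected a non-empty (z, rows, cols) stack")
    return data.max(axis=0)


def polygon_to_mask(polygon_px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean inside-mask of a pixel-coordinate polygon.

    A pixel belongs to the ROI iff its centre — (col + 0.5, row + 0.5) in
    polygon coordinates — lies strictly inside the polygon (even-odd rule).
    This makes ROI areas bit-reproducible across platforms.
    """
    polygon_px = np.asarray(polygon_px, dtype=float).reshape(-1, 2)
    if len(polygon_px) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = Polygon(polygon_px)
    if not poly.is_valid or poly.area == 0.0:
        raise ValueError("degenerate ROI polygon")
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    return shapely.contains_xy(poly, cols.ravel(), rows.ravel()).reshape(h, w)


def apply_roi(
    image: np.ndarray,
    polygon_px: np.ndarray,
    pixel_size_um: float,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Zero out pixels outside the ROI polygon.

    Returns (masked image, ROI area within the frame in µm², boolean mask).
    """
    image = np.asarray(image, dtype=float)
    mask = polygon_to_mask(polygon_px, image.shape)
    out = np.where(mask, image, 0.0)
    area_um2 = float(mask.sum()) * pixel_size_um**2
    return out, area_um2, mask


def match_sections(manifest: pd.DataFrame, region: str = "BLA") -> list[int]:
    """Section positions present for every mouse; only these are quantified.

    ``manifest`` needs columns ``mouse_id``, ``region`` and ``section_index``
    (ordinal anterior-posterior position). If any mouse misses a position,
    that position is dropped for all mice; if no position is shared, raises.
    """
    sub = manifest[manifest["region"] == region]
    if sub.empty:
        raise ValueError(f"manifest has no {region} sections")
    sets = [set(g["section_index"]) for _, g in sub.groupby("mouse_id")]
    common = set.intersection(*sets)
    if not common:
        raise ValueError("no section position is present for every mouse")
    return sorted(common)


def summarize_mouse(
    mouse_id: str,
    sex: str,
    per_section: pd.DataFrame,
    tdtomato_cells_vta: int,
    sypgfp_cells_vta: int,
    matched_positions: Optional[Sequence[int]] = None,
) -> MouseSummary:
    """Sum one mouse's detections over matched sections and normalize.

    ``per_section`` needs columns ``section_index``, ``axon_pixels``,
    ``bouton_count``, ``roi_area_um2``. Densities are exact ratios
    total / injection-site cell count; zero cell counts leave the density
    undefined and raise.
    """
    if matched_positions is not None:
        per_section = per_section[per_section["section_index"].isin(set(matched_positions))]
    if tdtomato_cells_vta <= 0 or sypgfp_cells_vta <= 0:
        raise ValueError(f"mouse {mouse_id}: zero labeled cells; density undefined")
    axon_total = int(per_section["axon_pixels"].sum())
    bouton_total = int(per_section["bouton_count"].sum())
    area_total = float(per_section["roi_area_um2"].sum())
    return MouseSummary(
        mouse_id=mouse_id,
        sex=sex,
        axon_pixels_total=axon_total,
        bouton_count_total=bouton_total,
        tdtomato_cells_vta=int(tdtomato_cells_vta),
        sypgfp_cells_vta=int(sypgfp_cells_vta),
        bla_area_total_um2=area_total,
        axon_density=axon_total / tdtomato_cells_vta,
        bouton_density=bouton_total / sypgfp_cells_vta,
    )


def percent_of_male_mean(values: Sequence[float], sexes: Sequence[str]) -> np.ndarray:
    """Express each value as a percentage of the male-group mean.

    By construction the male group then averages exactly 100%.
    """
    values = np.asarray(values, dtype=float)
    sexes = np.asarray(sexes)
    male = values[sexes == "male"]
    if male.size == 0:
        raise ValueError("no male mice to define the reference mean")
    ref = male.mean()
    if ref == 0:
        raise ValueError("male-group mean is zero; percentages undefined")
    return values / ref * 100.0


def region_mean_intensity(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """Average raw fluorescence per pixel inside the ROI (no background
    subtraction)."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    return float(np.asarray(image, dtype=float)[roi_mask].mean())


def log2_region_ratio(
    region_means: pd.DataFrame,
    vta_means: Mapping[str, float],
    nac_average: str = "geometric",
) -> pd.DataFrame:
    """Inter-region labeling intensity as log2 ratios referenced to NAC.

    Each mouse's regional mean intensity is first divided by that mouse's
    injection-site (VTA) mean intensity to control for labeling-efficiency
    variation, then by the across-mice average of the NAC ratio, and
    expressed as log2. With the default geometric NAC average, the NAC
    column averages exactly 0 across mice by construction; ``"arithmetic"``
    selects a plain mean reference instead (for which the NAC log2 average
    is only approximately 0).

    ``region_means`` needs columns ``mouse_id``, ``region``,
    ``mean_intensity``; all intensities must be positive.
    """
    if nac_average not in ("geometric", "arithmetic"):
        raise ValueError("nac_average must be 'geometric' or 'arithmetic'")
    df = region_means.copy()
    if (df["mean_intensity"] <= 0).any():
        raise ValueError("nonpositive regional intensity")
    vta = df["mouse_id"].map(lambda m: float(vta_means[m]))
    if (vta <= 0).any():
        raise ValueError("nonpositive VTA intensity")
    df["vta_mean_intensity"] = vta
    df["rel"] = df["mean_intensity"] / vta
    nac = df.loc[df["region"] == "NAC", "rel"]
    if nac.empty:
        raise ValueError("no NAC rows to define the reference")
    if nac_average == "geometric":
        nac_avg = float(np.exp(np.log(nac).mean()))
    else:
        nac_avg = float(nac.mean())
    df["log2_ratio_vs_nac"] = np.log2(df["rel"] / nac_avg)
    return df[["mouse_id", "region", "mean_intensity", "vta_mean_intensity",
               "log2_ratio_vs_nac"]]
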