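"""Automated vessel-area segmentation.

Composes the 8-bit filter stack — normalize, Gaussian blur (2 px), Sobel
edge magnitude, local variance (5 px), local median (3 px), subtract
(image SD by default), multiply (255), invert — and measures the resulting
binary mask with a connected-component particle analysis (8-connectivity,
size-filtered).  Foreground is defined as the pixels equal to 0 after the
final inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .imagecore import (
    FilterParams,
    Micrograph,
    gaussian_blur,
    invert8,
    local_median,
    local_variance,
    multiply_saturate,
    normalize_to_8bit,
    sobel_magnitude,
    subtract_saturate,
)

__all__ = [
    "ParticleTable",
    "SegmentationResult",
    "analyze_particles",
    "segment_vessels",
    "validate_against_reference",
]

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class ParticleTable:
    """Connected-component statistics of a binary mask.

    ``rows`` has one record per retained particle: label, area_px2,
    area_um2, centroid_row, centroid_col and bounding box.  Totals are
    relative to the full image area.
    """

    rows: pd.DataFrame
    image_area_px2: int
    pixel_size: float = 1.0

    @property
    def particle_count(self) -> int:
        return len(self.rows)

    @property
    def total_area(self) -> float:
        return float(self.rows["area_px2"].sum()) if len(self.rows) else 0.0

    @property
    def percent_area(self) -> float:
        return 100.0 * self.total_area / self.image_area_px2


@dataclass
class SegmentationResult:
    mask: np.ndarray  # boolean, True = vessel
    particles: ParticleTable
    area_fraction: float
    params_used: dict

    @property
    def percent_area(self) -> float:
        return 100.0 * self.area_fraction


def analyze_particles(
    mask: np.ndarray,
    min_area: float = 0.0,
    max_area: float = math.inf,
    pixel_size: float = 1.0,
) -> ParticleTable:
    """8-connected component analysis with a size filter.

    Components with area outside ``[min_area, max_area]`` (px^2) are
    discarded.  Labels of retained particles are renumbered contiguously
    from 1; centroids are arithmetic means of member pixel coordinates.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if max_area < min_area:
        raise ValueError("max_area must be >= min_area")
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=EIGHT_CONNECTED)
    records = []
    if n:
        areas = np.bincount(labeled.ravel())[1:]
        keep = np.flatnonzero((areas >= min_area) & (areas <= max_area)) + 1
        if keep.size:
            centroids = ndimage.center_of_mass(mask, labeled, keep)
            slices = ndimage.find_objects(labeled)
            for new_label, (old, (cr, cc)) in enumerate(
                zip(keep, centroids), start=1
            ):
                sl = slices[old - 1]
                records.append(
                    {
                        "label": new_label,
                        "area_px2": int(areas[old - 1]),
                        "area_um2": areas[old - 1] * pixel_size**2,
                        "centroid_row": cr,
                        "centroid_col": cc,
                        "bbox_top": sl[0].start,
                        "bbox_left": sl[1].start,
                        "bbox_bottom": sl[0].stop,
                        "bbox_right": sl[1].stop,
                    }
                )
    rows = pd.DataFrame(
        records,
        columns=[
            "label",
            "area_px2",
            "area_um2",
            "centroid_row",
            "centroid_col",
            "bbox_top",
            "bbox_left",
            "bbox_bottom",
            "bbox_right",
        ],
    )
    return ParticleTable(
        rows=rows, image_area_px2=int(mask.size), pixel_size=pixel_size
    )


def segment_vessels(
    img: Micrograph | np.ndarray,
    params: FilterParams | None = None,
    min_area: float = 25.0,
    max_area: float = math.inf,
    channel: str | None = None,
    pixel_size: float | None = None,
    debug_stages: dict | None = None,
) -> SegmentationResult:
    """Run the full segmentation stack on a single channel.

    ``debug_stages``, when a dict, receives every intermediate stage image
    keyed by stage name.
    """
    if params is None:
        params = FilterParams()
    if isinstance(img, Micrograph):
        a = img.channel(channel)
        if pixel_size is None:
            pixel_size = img.pixel_size
    else:
        a = np.asarray(img, dtype=float)
    if pixel_size is None:
        pixel_size = 1.0

    eb = params.eight_bit_mode
    stages = {}
    x = normalize_to_8bit(a)
    stages["normalize"] = x
    x = gaussian_blur(x, params.gaussian_sigma, eight_bit=eb)
    stages["gaussian"] = x
    x = sobel_magnitude(x, eight_bit=eb)
    stages["sobel"] = x
    x = local_variance(x, params.variance_radius, eight_bit=eb)
    stages["variance"] = x
    x = local_median(x, params.median_radius, eight_bit=eb)
    stages["median"] = x
    sigma_used = params.resolve_subtract(x)
    x = subtract_saturate(x, sigma_used, eight_bit=eb)
    stages["subtract"] = x
    x = multiply_saturate(x, params.multiply_factor, eight_bit=eb)
    stages["multiply"] = x
    inverted = invert8(np.clip(x, 0, 255))
    stages["invert"] = inverted

    # vessels are the dark (0) objects of the inverted image
    mask = inverted == 0
    particles = analyze_particles(
        mask, min_area=min_area, max_area=max_area, pixel_size=pixel_size
    )
    # Mask of the particles that survived the size filter.
    labeled, n = ndimage.label(mask, structure=EIGHT_CONNECTED)
    if n:
        areas = np.bincount(labeled.ravel())[1:]
        keep = np.flatnonzero((areas >= min_area) & (areas <= max_area)) + 1
        retained = np.isin(labeled, keep)
    else:
        retained = np.zeros_like(mask)
    if debug_stages is not None:
        debug_stages.update(stages)

    area_fraction = particles.total_area / mask.size
    params_used = {
        "gaussian_sigma": params.gaussian_sigma,
        "variance_radius": params.variance_radius,
        "median_radius": params.median_radius,
        "subtract_constant": params.subtract_constant,
        "sigma_used": sigma_used,
        "multiply_factor": params.multiply_factor,
        "eight_bit_mode": eb,
        "min_area": min_area,
        "max_area": max_area,
    }
    return SegmentationResult(
        mask=retained,
        particles=particles,
        area_fraction=float(area_fraction),
        params_used=params_used,
    )


def validate_against_reference(auto, reference) -> dict:
    """OLS fit of automated area fractions on reference fractions.

    Returns slope, intercept, r_squared (squared Pearson correlation) and
    the two-sided p-value for the zero-slope null.
    """
    auto = np.asarray(auto, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if auto.shape != reference.shape or auto.ndim != 1:
        raise ValueError("auto and reference must be equal-length vectors")
    if auto.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(reference) == 0:
        raise ValueError("reference values are constant: degenerate fit")
    fit = stats.linregress(reference, auto)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
    }
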