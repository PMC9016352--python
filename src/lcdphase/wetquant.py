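"""Quantification formulas for sedimentation blots, FRAP traces and droplet
morphology.

These mirror the bench-side analyses: the supernatant fraction
``S/(S + C)`` from band intensities, background- and bleach-corrected FRAP
recovery ``I(t) = (ROI1 - ROI3)/(ROI2 - ROI3)`` normalized to the prebleach
level, its area under the curve, and droplet segmentation with the roundness
(``4 A / (pi * major_axis^2)``, the inverse aspect ratio) and circularity
(``4 pi A / perimeter^2``) filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

__all__ = [
    "FrapTrace",
    "sedimentation_ratio",
    "frap_normalize",
    "frap_auc",
    "segment_droplets",
]


def sedimentation_ratio(
    supernatant_intensity: float, pellet_intensity: float
) -> float:
    """Supernatant fraction ``S / (S + C)`` from band intensities."""
    s, c = float(supernatant_intensity), float(pellet_intensity)
    if s < 0 or c < 0:
        raise ValueError("band intensities must be non-negative")
    if s + c == 0:
        raise ValueError("both intensities zero: ratio undefined")
    return s / (s + c)


@dataclass
class FrapTrace:
    """ROI gray-value series for one bleached droplet.

    ROI1 = bleached area, ROI2 = whole droplet, ROI3 = background;
    ``bleach_index`` is the first post-bleach frame.
    """

    times: np.ndarray  # s
    roi_bleached: np.ndarray
    roi_whole: np.ndarray
    roi_background: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi_bleached = np.asarray(self.roi_bleached, dtype=float)
        self.roi_whole = np.asarray(self.roi_whole, dtype=float)
        self.roi_background = np.asarray(self.roi_background, dtype=float)
        n = len(self.times)
        if any(
            len(a) != n
            for a in (self.roi_bleached, self.roi_whole, self.roi_background)
        ):
            raise ValueError("all ROI series must share the times length")
        if not 1 <= self.bleach_index < n:
            raise ValueError("bleach_index must be >= 1 and inside the series")

    @classmethod
    def from_csv(cls, path, bleach_index: int) -> "FrapTrace":
        df = pd.read_csv(path)
        return cls(
            times=df["time"].to_numpy(),
            roi_bleached=df["roi1"].to_numpy(),
            roi_whole=df["roi2"].to_numpy(),
            roi_background=df["roi3"].to_numpy(),
            bleach_index=bleach_index,
        )


def frap_normalize(trace: FrapTrace, prebleach_window: int = 1) -> np.ndarray:
    """Background-corrected, acquisition-bleaching-corrected recovery curve.

    ``I(t) = (ROI1(t) - ROI3(t)) / (ROI2(t) - ROI3(t))`` divided by the mean
    of I over the ``prebleach_window`` frames before the bleach, so the
    prebleach level is exactly 1.
    """
    denom = trace.roi_whole - trace.roi_background
    if np.any(denom <= 0):
        raise ValueError("ROI2 - ROI3 must be positive everywhere")
    i_t = (trace.roi_bleached - trace.roi_background) / denom
    w = int(prebleach_window)
    if not 1 <= w <= trace.bleach_index:
        raise ValueError("prebleach_window must fit before bleach_index")
    ref = i_t[trace.bleach_index - w : trace.bleach_index].mean()
    if ref == 0:
        raise ValueError("prebleach intensity is zero")
    return i_t / ref


def frap_auc(
    times: np.ndarray,
    normalized: np.ndarray,
    t_start: float,
    t_end: float,
) -> float:
    """Trapezoidal area under the normalized recovery curve over
    [t_start, t_end]; endpoints are linearly interpolated."""
    times = np.asarray(times, dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    if t_start < times[0] or t_end > times[-1]:
        raise ValueError("integration window outside the sampled times")
    inside = (times > t_start) & (times < t_end)
    ts = np.concatenate([[t_start], times[inside], [t_end]])
    ys = np.concatenate(
        [
            [np.interp(t_start, times, normalized)],
            normalized[inside],
            [np.interp(t_end, times, normalized)],
        ]
    )
    return float(np.trapezoid(ys, ts))


def segment_droplets(
    image: np.ndarray,
    bandpass_large_px: float = 20.0,
    min_area_px: float = 3.0,
    min_circularity: float = 0.3,
    bandpass_small_px: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment droplets in a grayscale image and measure their morphology.

    Pipeline: difference-of-Gaussians bandpass (small sigma 1 px, large sigma
    ``bandpass_large_px``), Otsu threshold, connected components, per-droplet
    area, major axis, roundness ``4 A/(pi major^2)``, circularity
    ``4 pi A / perimeter^2`` and centroid.  Rows with area < ``min_area_px``
    or circularity < ``min_circularity`` are dropped.  Returns the label
    image (all components) and the filtered table.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if image.size == 0:
        raise ValueError("empty image")
    band = filters.difference_of_gaussians(
        image, low_sigma=bandpass_small_px, high_sigma=bandpass_large_px
    )
    if np.allclose(band, band.flat[0]):
        labels = np.zeros(image.shape, dtype=int)
    else:
        thresh = filters.threshold_otsu(band)
        labels, _ = ndimage.label(band > thresh)
    rows = []
    for region in measure.regionprops(labels):
        area = float(region.area)
        major = float(region.axis_major_length)
        perimeter = float(region.perimeter)
        roundness = 4.0 * area / (math.pi * major**2) if major > 0 else 1.0
        circularity = (
            4.0 * math.pi * area / perimeter**2 if perimeter > 0 else 0.0
        )
        rows.append(
            {
                "label": region.label,
                "area": area,
                "major_axis": major,
                "roundness": roundness,
                "circularity": circularity,
                "centroid_row": region.centroid[0],
                "centroid_col": region.centroid[1],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "area", "major_axis", "roundness", "circularity",
            "centroid_row", "centroid_col",
        ],
    )
    if len(table):
        table = table[
            (table["area"] >= min_area_px)
            & (table["circularity"] >= min_circularity)
        ].reset_index(drop=True)
    return labels, table
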