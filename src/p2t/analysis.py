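"""Quantitative evaluation: normalisation, contrast, Z-linearity, cIVH."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .image import Image

__all__ = [
    "ROISet", "CIVHCurve", "normalize_image", "contrast_to_water",
    "linearity_regression", "civh", "roi_mean",
]


@dataclass(frozen=True)
class ROI:
    center: tuple[float, float]
    radius: float
    label: str = ""


class ROISet:
    """Named circular regions of interest on an image grid."""

    def __init__(self, rois: dict[str, tuple[tuple[float, float], float]]):
        self._rois = {name: ROI(tuple(c), float(r), name)
                      for name, (c, r) in rois.items()}

    def __getitem__(self, name: str) -> ROI:
        return self._rois[name]

    def names(self):
        return list(self._rois)

    def mask(self, image: Image, name: str) -> np.ndarray:
        roi = self._rois[name]
        m = image.roi_mask(roi.center, roi.radius)
        if not m.any():
            raise ValueError(f"ROI {name!r} contains no voxels")
        return m


def roi_mean(image: Image, center, radius) -> float:
    m = image.roi_mask(center, radius)
    if not m.any():
        raise ValueError("empty ROI")
    return float(image.values[m].mean())


def normalize_image(image: Image, center, radius,
                    mode: str = "water-insert") -> Image:
    """Divide by the mean over a reference ROI (water insert or target).

    Idempotent, and invariant to a global rescaling of the input.
    """
    if mode not in ("water-insert", "target-mean"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    ref = roi_mean(image, center, radius)
    if ref == 0:
        raise ValueError("reference ROI mean is zero")
    return image.with_values(image.values / ref, normalization=mode,
                             reference_center=tuple(center),
                             reference_radius=radius)


def contrast_to_water(image: Image, roi_center, roi_radius,
                      water_center, water_radius,
                      n_samples: int = 25,
                      rng: np.random.Generator | None = None):
    """Relative contrast (mean_roi - mean_water) / mean_water.

    Returns (contrast, sd): the standard deviation is taken over
    ``n_samples`` independent circular sub-samples drawn inside the ROI
    (radius one third of the ROI), matching the per-insert error bars of
    the phantom studies.
    """
    water = roi_mean(image, water_center, water_radius)
    if water == 0:
        raise ValueError("water ROI mean is zero")
    mean_roi = roi_mean(image, roi_center, roi_radius)
    contrast = (mean_roi - water) / water
    sd = float("nan")
    if n_samples and rng is not None:
        sub_r = roi_radius / 3.0
        reach = roi_radius - sub_r
        vals = []
        for _ in range(n_samples):
            while True:
                dx, dy = rng.uniform(-reach, reach, 2)
                if dx * dx + dy * dy <= reach * reach:
                    break
            c = (roi_center[0] + dx, roi_center[1] + dy)
            vals.append((roi_mean(image, c, sub_r) - water) / water)
        sd = float(np.std(vals, ddof=1))
    return contrast, sd


def linearity_regression(contrasts, zs):
    """Ordinary least squares of contrast on atomic number.

    Returns (slope, intercept, r_squared); r^2 is the squared Pearson
    correlation (0 when the contrasts are constant).
    """
    y = np.asarray(contrasts, dtype=float)
    z = np.asarray(zs, dtype=float)
    if y.size < 3 or z.size != y.size:
        raise ValueError("need at least 3 (Z, contrast) points")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(z, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


@dataclass
class CIVHCurve:
    """Cumulative intensity-volume histogram of one structure.

    ``fractions[k]`` is the percentage of the structure's voxels with value
    strictly greater than ``thresholds[k]``; the curve starts at 100 % for
    any threshold below the structure minimum and is non-increasing.
    """

    thresholds: np.ndarray
    fractions: np.ndarray  # percent

    def __post_init__(self):
        if np.any(np.diff(self.fractions) > 1e-12):
            raise ValueError("cIVH must be non-increasing")


def civh(image: Image, mask: np.ndarray, thresholds=None) -> CIVHCurve:
    """Volume fraction of ``mask`` above each intensity threshold."""
    vals = image.values[mask]
    if vals.size == 0:
        raise ValueError("empty structure mask")
    if thresholds is None:
        thresholds = np.linspace(0.0, float(vals.max()), 256)
    thresholds = np.asarray(thresholds, dtype=float)
    frac = np.array([(vals > t).mean() * 100.0 for t in thresholds])
    return CIVHCurve(thresholds, frac)
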