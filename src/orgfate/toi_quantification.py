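"""Tissue-outcome quantification: pigment/lens areas and 4-level size classes.

RPE (dark pigment) area is measured on endpoint stereo-like images via a
fixed chain: Yen's global threshold isolates the organoid ROI, the ROI is
converted to 8-bit and min-max rescaled to [0, 255], and Sauvola's local
threshold (radius 15 px, k = 0.5, r = 128) separates pigment from tissue.
Pigment is the *dark* side of the Sauvola decision: the primitive
:func:`sauvola_threshold` marks pixels brighter than the local threshold
t = m(1 + k(s/r - 1)), and the pigment mask is its complement inside the
ROI.  Lens areas are treated as circles (area = pi r^2), matching how lens
cross-sections are annotated.

Measured areas are discretised into four classes: class 0 = tissue absent;
classes 1/2/3 = area at or below the 33rd percentile, between the 33rd and
66th, and above the 66th percentile of positive areas pooled over the
training data.  Reference cutoffs from the real dataset are provided as
constants.  A bin-centre-distance diagnostic normalises each sample's
distance to its bin's central value (0 = centre, 1 = edge).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_yen

__all__ = [
    "SauvolaParams",
    "ClassCutoffs",
    "RPE_REFERENCE_CUTOFFS",
    "LENS_REFERENCE_CUTOFFS",
    "sauvola_threshold",
    "quantify_rpe_area",
    "quantify_lens_area",
    "fit_lens_circle",
    "compute_class_cutoffs",
    "assign_size_class",
    "bin_center_distance",
    "to_8bit",
]


@dataclass(frozen=True)
class SauvolaParams:
    radius: int = 15
    k: float = 0.5
    r: float = 128.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")

    @property
    def window(self) -> int:
        return 2 * self.radius + 1


@dataclass(frozen=True)
class ClassCutoffs:
    """33rd/66th percentile area cutoffs (um^2) for one tissue."""

    tissue: str
    q33: float
    q66: float
    source: str = "computed"

    def __post_init__(self) -> None:
        if not 0 < self.q33 < self.q66:
            raise ValueError("cutoffs must satisfy 0 < q33 < q66")


#: Published cutoffs of the reference dataset (um^2).
RPE_REFERENCE_CUTOFFS = ClassCutoffs("rpe", 4541.73, 7548.51, source="configured")
LENS_REFERENCE_CUTOFFS = ClassCutoffs("lens", 16324.85, 29083.23, source="configured")


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Linear min-max scale any numeric image to uint8 (round half to even)."""
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.rint((img - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def sauvola_threshold(image: np.ndarray, p: SauvolaParams | None = None) -> np.ndarray:
    """Sauvola local threshold surface decision: foreground iff pixel > t.

    t = m * (1 + k * (s / r - 1)) with m, s the mean and standard deviation
    over the mirror-padded square window of side 2*radius + 1 centred at the
    pixel.  Returns the boolean map of pixels strictly above t (the bright /
    background side); darker-than-context structures are its complement.
    """
    p = SauvolaParams() if p is None else p
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if p.window > min(img.shape):
        raise ValueError(
            f"window {p.window} exceeds image extent {min(img.shape)}")
    m = ndimage.uniform_filter(img, size=p.window, mode="mirror")
    m2 = ndimage.uniform_filter(img * img, size=p.window, mode="mirror")
    s = np.sqrt(np.maximum(m2 - m * m, 0.0))
    t = m * (1.0 + p.k * (s / p.r - 1.0))
    return img > t


def quantify_rpe_area(stereo_image: np.ndarray, um_per_px: float = 1.0,
                      p: SauvolaParams | None = None,
                      return_masks: bool = False):
    """Measure the pigmented (RPE) area in an endpoint stereo image, in um^2.

    Chain: (1) organoid ROI = largest component of Yen's global threshold
    (organoid darker than background), holes filled; (2) 8-bit conversion;
    (3) min-max rescale of in-ROI intensities to [0, 255]; (4) Sauvola local
    threshold; (5) area = dark-side pixel count inside the ROI x um_per_px^2.

    A flat-intensity ROI yields area 0 with a warning.
    """
    p = SauvolaParams() if p is None else p
    img8 = to_8bit(stereo_image)
    t = threshold_yen(img8)
    roi = img8 <= t  # organoid = dark side, threshold-inclusive
    labels, n = ndimage.label(roi)
    if n == 0:
        raise ValueError("empty ROI: Yen threshold found no organoid")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    roi = ndimage.binary_fill_holes(labels == 1 + int(np.argmax(sizes)))

    vals = img8[roi].astype(np.float64)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        warnings.warn("flat-intensity ROI: pigment area set to 0", stacklevel=2)
        area = 0.0
        pigment = np.zeros_like(roi)
    else:
        rescaled = np.zeros(img8.shape, dtype=np.float64)
        rescaled[roi] = np.rint((img8[roi] - lo) * (255.0 / (hi - lo)))
        bright = sauvola_threshold(rescaled, p)
        pigment = roi & ~bright
        area = float(pigment.sum()) * um_per_px ** 2
    if return_masks:
        return area, roi, pigment
    return area


def quantify_lens_area(radius_px: float | None = None, um_per_px: float = 1.0,
                       diameter_points=None) -> float:
    """Lens area as a circle: pi * (radius * um_per_px)^2.

    The radius may be given directly (px) or as a two-point diameter
    annotation ``diameter_points = ((y0, x0), (y1, x1))``.
    """
    if radius_px is None:
        if diameter_points is None:
            raise ValueError("provide radius_px or diameter_points")
        (y0, x0), (y1, x1) = diameter_points
        radius_px = math.hypot(y1 - y0, x1 - x0) / 2.0
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    return math.pi * (radius_px * um_per_px) ** 2


def fit_lens_circle(image: np.ndarray, mask: np.ndarray) -> float:
    """Estimate the bright lens disc radius (px) inside an organoid mask.

    The lens renders as a saturated bright disc, so its pixels sit in the
    upper tail of the in-mask intensity distribution: the threshold is the
    midpoint between the 25th-percentile intensity (a tissue level robust
    even when the lens covers most of the mask) and the maximum (lens
    level).  The equivalent-circle radius of the largest bright component
    is returned; raises if none is found.
    """
    img = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    vals = img[mask]
    t = 0.5 * (np.percentile(vals, 25) + vals.max())
    bright = mask & (img > t)
    labels, n = ndimage.label(bright)
    if n == 0:
        raise ValueError("no bright lens disc found in mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    area = float(sizes.max())
    return math.sqrt(area / math.pi)


# ---------------------------------------------------------------------------
# size classes

def compute_class_cutoffs(positive_areas, tissue: str = "rpe") -> ClassCutoffs:
    """Empirical tercile cutoffs from pooled positive areas.

    The boundaries are the 33rd/66th percentiles in the tercile sense
    (100/3 and 200/3), which is what makes the three size groups equally
    sized; rounding them to integer percent ranks would systematically
    inflate the top group.
    """
    areas = np.asarray(positive_areas, dtype=np.float64)
    if areas.size == 0 or np.any(areas <= 0):
        raise ValueError("positive_areas must be non-empty and strictly positive")
    q33, q66 = np.percentile(areas, [100.0 / 3.0, 200.0 / 3.0])
    return ClassCutoffs(tissue, float(q33), float(q66), source="computed")


def assign_size_class(area: float, present: bool,
                      cutoffs: ClassCutoffs) -> int:
    """Map (presence, area) to the 4-level class {0, 1, 2, 3}.

    Absent -> 0.  Present: 1 if area <= q33, 2 if q33 < area <= q66, else 3
    (left-closed bins; 'below the 33rd percentile' keeps the boundary in the
    lower class).
    """
    if not present:
        return 0
    if area <= 0:
        raise ValueError("present tissue must have positive area")
    if area <= cutoffs.q33:
        return 1
    if area <= cutoffs.q66:
        return 2
    return 3


def bin_center_distance(area: float, cls: int, cutoffs: ClassCutoffs,
                        pooled_areas) -> float:
    """Normalised distance of a sample to the centre of its size bin.

    Bins are (min, q33], (q33, q66], (q66, max] over the pooled positive
    areas; the centre is the midpoint of the bin bounds and the distance is
    |area - centre| / half-width, so 0 at the centre and 1 at either edge.
    """
    if cls < 1:
        raise ValueError("bin-centre distance is defined for classes 1-3")
    pooled = np.asarray(pooled_areas, dtype=np.float64)
    lo, hi = pooled.min(), pooled.max()
    bounds = {1: (lo, cutoffs.q33), 2: (cutoffs.q33, cutoffs.q66),
              3: (cutoffs.q66, hi)}[cls]
    if not bounds[0] <= area <= bounds[1]:
        raise ValueError(f"area {area} outside its class-{cls} bin {bounds}")
    center = 0.5 * (bounds[0] + bounds[1])
    half = 0.5 * (bounds[1] - bounds[0])
    if half == 0:
        return 0.0
    return abs(area - center) / half
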