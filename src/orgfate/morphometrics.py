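"""Per-frame morphometric feature extraction: exactly 165 named features.

The feature space combines the standard region descriptors (area, convex
area, filled area, bounding box, centroid, eccentricity, equivalent
diameter, Euler number, extent, Feret diameter, axis lengths, orientation,
perimeter, solidity, intensity statistics), raw / central / normalised /
Hu image-moment sets in both binary and intensity-weighted form, seven
higher-level shape descriptors (aspect ratio, roundness, circularity, form
factor, compactness, effective diameter, convexity) and nine custom
intensity features (blur, ROI contrast, image contrast, median, modal
value, integrated density, raw integrated density, skewness, kurtosis).

Registry composition (pinned; the total count of 165 is contractual):

====================================  =====
geometry descriptors                     22
intensity descriptors                    12
custom shape descriptors                  7
custom intensity descriptors              9
binary moments m/mu (5x5 grids)          50
binary moments nu (2 <= p+q <= 4)        12
binary Hu invariants                      7
weighted moments m/mu (4x4 grids)        32
weighted moments nu (2 <= p+q <= 3)       7
weighted Hu invariants                    7
====================================  =====
total                                   165

Conventions: moments are computed on the region's local (cropped) window in
(row, col) order, following the regionprops convention.  The Laplacian is
the 4-neighbour discrete kernel with mirror boundary; modal-value ties break
toward the smallest intensity; skewness/kurtosis of a constant in-mask
distribution are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

__all__ = [
    "FeatureRegistry",
    "default_registry",
    "FEATURE_NAMES",
    "extract_features",
    "compute_custom_shape_features",
    "compute_custom_intensity_features",
    "compute_morphometrics",
    "N_FEATURES",
]

N_FEATURES = 165
REGISTRY_VERSION = "1.0"

_LAPLACIAN = np.array([[0.0, 1.0, 0.0],
                       [1.0, -4.0, 1.0],
                       [0.0, 1.0, 0.0]])


def _moment_names(prefix: str, orders) -> list[str]:
    return [f"{prefix}_{p}{q}" for p, q in orders]


_GRID4 = [(p, q) for p in range(4) for q in range(4)]
_GRID5 = [(p, q) for p in range(5) for q in range(5)]
_NU_23 = [(p, q) for p in range(4) for q in range(4) if 2 <= p + q <= 3]
_NU_24 = [(p, q) for p in range(5) for q in range(5) if 2 <= p + q <= 4]

GEOMETRY_NAMES = [
    "area", "area_bbox", "area_convex", "area_filled",
    "bbox_height", "bbox_width",
    "centroid_row", "centroid_col",
    "eccentricity", "equivalent_diameter", "euler_number", "extent",
    "feret_diameter_max",
    "inertia_tensor_0_0", "inertia_tensor_1_1",
    "inertia_tensor_eigval_1", "inertia_tensor_eigval_2",
    "major_axis_length", "minor_axis_length", "orientation",
    "perimeter", "solidity",
]
INTENSITY_NAMES = [
    "intensity_min", "intensity_max", "intensity_mean", "intensity_std",
    "intensity_p10", "intensity_p25", "intensity_p75", "intensity_p90",
    "weighted_centroid_row", "weighted_centroid_col",
    "weighted_centroid_local_row", "weighted_centroid_local_col",
]
CUSTOM_SHAPE_NAMES = [
    "aspect_ratio", "roundness", "circularity", "form_factor",
    "compactness", "effective_diameter", "convexity",
]
CUSTOM_INTENSITY_NAMES = [
    "blur", "roi_contrast", "image_contrast", "median_intensity",
    "modal_value", "integrated_density", "raw_integrated_density",
    "intensity_skewness", "intensity_kurtosis",
]
MOMENT_NAMES = (
    _moment_names("m", _GRID5)
    + _moment_names("mu", _GRID5)
    + _moment_names("nu", _NU_24)
    + [f"hu_{i}" for i in range(1, 8)]
    + _moment_names("wm", _GRID4)
    + _moment_names("wmu", _GRID4)
    + _moment_names("wnu", _NU_23)
    + [f"whu_{i}" for i in range(1, 8)]
)

FEATURE_NAMES = (
    GEOMETRY_NAMES + INTENSITY_NAMES + CUSTOM_SHAPE_NAMES
    + CUSTOM_INTENSITY_NAMES + MOMENT_NAMES
)
assert len(FEATURE_NAMES) == N_FEATURES
assert len(set(FEATURE_NAMES)) == N_FEATURES


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered, versioned list of (name, category, formula id) entries."""

    entries: tuple = ()
    version: str = REGISTRY_VERSION

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def default_registry() -> FeatureRegistry:
    entries = (
        [(n, "geometry", n) for n in GEOMETRY_NAMES]
        + [(n, "intensity", n) for n in INTENSITY_NAMES]
        + [(n, "custom_shape", n) for n in CUSTOM_SHAPE_NAMES]
        + [(n, "custom_intensity", n) for n in CUSTOM_INTENSITY_NAMES]
        + [(n, "moments", n) for n in MOMENT_NAMES]
    )
    reg = FeatureRegistry(entries=tuple(entries))
    assert len(reg) == N_FEATURES
    return reg


_DEFAULT_REGISTRY = default_registry()


def _single_region(mask: np.ndarray):
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(f"mask must have exactly one connected component, got {n}")
    return mask


def compute_custom_shape_features(mask: np.ndarray, _props=None) -> dict[str, float]:
    """Higher-level shape descriptors from the binary mask alone."""
    mask = _single_region(mask)
    props = _props if _props is not None else measure.regionprops(
        mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    if minor == 0:
        raise ValueError("degenerate mask: zero minor axis length")
    convex_perimeter = measure.perimeter(props.image_convex)
    return {
        "aspect_ratio": major / minor,
        "roundness": 4.0 * area / (np.pi * major ** 2),
        "circularity": 4.0 * np.pi * area / perimeter ** 2,
        "form_factor": 4.0 * np.pi * area / perimeter ** 2,
        "compactness": perimeter ** 2 / area,
        "effective_diameter": 2.0 * np.sqrt(area / np.pi),
        "convexity": float(convex_perimeter) / perimeter,
    }


def compute_custom_intensity_features(image: np.ndarray,
                                      mask: np.ndarray) -> dict[str, float]:
    """Custom intensity descriptors over the in-mask pixel distribution."""
    mask = _single_region(mask)
    img = np.asarray(image, dtype=np.float64)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    vals = img[mask]
    lap = ndimage.convolve(img, _LAPLACIAN, mode="mirror")
    flat = np.ptp(vals) == 0
    area = float(mask.sum())
    # modal value: most frequent in-mask intensity, ties -> smallest value
    uniq, counts = np.unique(vals, return_counts=True)
    modal = float(uniq[np.argmax(counts)])
    return {
        "blur": float(np.var(lap[mask])),
        "roi_contrast": float(vals.max() - vals.min()),
        "image_contrast": float(img.max() - img.min()),
        "median_intensity": float(np.median(vals)),
        "modal_value": modal,
        "integrated_density": float(vals.mean() * area),
        "raw_integrated_density": float(vals.sum()),
        "intensity_skewness": 0.0 if flat else float(stats.skew(vals)),
        "intensity_kurtosis": 0.0 if flat else float(stats.kurtosis(vals)),
    }


def _moment_block(local_img: np.ndarray, prefix: str) -> dict[str, float]:
    """Raw, central, normalised and Hu moments of a local-window image.

    The binary (unweighted) block carries the full 5x5 raw/central grids and
    normalised moments up to total order 4; the intensity-weighted block the
    4x4 grids and order-3 normalised moments.  Hu invariants (order 3) are
    emitted for both.
    """
    m = measure.moments(local_img, order=4)
    r = m[1, 0] / m[0, 0]
    c = m[0, 1] / m[0, 0]
    mu = measure.moments_central(local_img, center=(r, c), order=4)
    with np.errstate(invalid="ignore", divide="ignore"):
        nu = measure.moments_normalized(mu, order=4)
        hu = measure.moments_hu(nu[:4, :4].copy())
    out: dict[str, float] = {}
    grid = _GRID4 if prefix else _GRID5
    nu_orders = _NU_23 if prefix else _NU_24
    for p, q in grid:
        out[f"{prefix}m_{p}{q}"] = float(m[p, q])
        out[f"{prefix}mu_{p}{q}"] = float(mu[p, q])
    for p, q in nu_orders:
        out[f"{prefix}nu_{p}{q}"] = float(nu[p, q])
    for i in range(7):
        out[f"{prefix}hu_{i + 1}"] = float(hu[i])
    return out


def extract_features(image: np.ndarray, mask: np.ndarray,
                     registry: FeatureRegistry | None = None) -> np.ndarray:
    """Extract the full 165-feature row for one accepted frame.

    Parameters
    ----------
    image : grayscale frame (any numeric dtype; cast to float64)
    mask : single-component binary organoid mask, same shape
    registry : feature registry; defaults to the pinned v1.0 registry

    Returns
    -------
    float64 array of length 165, ordered per the registry; all values finite.
    """
    registry = _DEFAULT_REGISTRY if registry is None else registry
    mask = _single_region(mask)
    img = np.asarray(image, dtype=np.float64)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")

    props = measure.regionprops(mask.astype(np.uint8), intensity_image=img)[0]
    minr, minc, maxr, maxc = props.bbox
    vals = img[mask]
    eig = props.inertia_tensor_eigvals
    it = props.inertia_tensor

    values: dict[str, float] = {
        "area": float(props.area),
        "area_bbox": float(props.area_bbox),
        "area_convex": float(props.area_convex),
        "area_filled": float(props.area_filled),
        "bbox_height": float(maxr - minr), "bbox_width": float(maxc - minc),
        "centroid_row": float(props.centroid[0]),
        "centroid_col": float(props.centroid[1]),
        "eccentricity": float(props.eccentricity),
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "euler_number": float(props.euler_number),
        "extent": float(props.extent),
        "feret_diameter_max": float(props.feret_diameter_max),
        "inertia_tensor_0_0": float(it[0, 0]),
        "inertia_tensor_1_1": float(it[1, 1]),
        "inertia_tensor_eigval_1": float(eig[0]),
        "inertia_tensor_eigval_2": float(eig[1]),
        "major_axis_length": float(props.axis_major_length),
        "minor_axis_length": float(props.axis_minor_length),
        "orientation": float(props.orientation),
        "perimeter": float(props.perimeter),
        "solidity": float(props.solidity),
        "intensity_min": float(vals.min()),
        "intensity_max": float(vals.max()),
        "intensity_mean": float(vals.mean()),
        "intensity_std": float(vals.std()),
        "intensity_p10": float(np.percentile(vals, 10)),
        "intensity_p25": float(np.percentile(vals, 25)),
        "intensity_p75": float(np.percentile(vals, 75)),
        "intensity_p90": float(np.percentile(vals, 90)),
        "weighted_centroid_row": float(props.centroid_weighted[0]),
        "weighted_centroid_col": float(props.centroid_weighted[1]),
        "weighted_centroid_local_row": float(props.centroid_weighted_local[0]),
        "weighted_centroid_local_col": float(props.centroid_weighted_local[1]),
    }
    values.update(compute_custom_shape_features(mask, _props=props))
    values.update(compute_custom_intensity_features(img, mask))

    local_mask = mask[minr:maxr, minc:maxc].astype(np.float64)
    local_weighted = local_mask * img[minr:maxr, minc:maxc]
    values.update(_moment_block(local_mask, ""))
    values.update(_moment_block(local_weighted, "w"))

    row = np.array([values[name] for name in registry.names], dtype=np.float64)
    if not np.all(np.isfinite(row)):
        bad = [n for n, v in zip(registry.names, row) if not np.isfinite(v)]
        raise ValueError(f"non-finite features: {bad}")
    return row


# ---------------------------------------------------------------------------
# dataset-level extraction

def compute_morphometrics(wells, loops=None, projection: str = "none",
                          segmenter=None, use_true_masks: bool = False,
                          working_size: int | None = None,
                          registry: FeatureRegistry | None = None) -> pd.DataFrame:
    """Build the morphometrics table for a collection of well time series.

    One row per (experiment, well, loop) that passes QC; excluded loops and
    rejected frames are dropped.  By default features come from the middle
    z-slice; ``projection`` may be ``"sum"`` or ``"max"`` to use z-projected
    stacks instead.  ``use_true_masks=True`` bypasses the segmenter and uses
    the generator's ground-truth masks (useful to separate feature behaviour
    from segmentation behaviour).
    """
    from . import segmentation as seg

    registry = _DEFAULT_REGISTRY if registry is None else registry
    if projection not in ("none", "sum", "max"):
        raise ValueError("projection must be 'none', 'sum' or 'max'")
    rows, meta = [], []
    for well in wells:
        cfg = well.cfg
        sel = range(cfg.n_loops) if loops is None else loops
        wsize = working_size if working_size is not None else min(
            seg.WORKING_SIZE, max(cfg.frame_px, 64))
        for loop in sel:
            if loop in well.excluded_loops:
                continue
            if projection == "none":
                img = well.frame(loop, cfg.middle_z).astype(np.float64)
            else:
                stack = np.stack([well.frame(loop, z).astype(np.float64)
                                  for z in range(cfg.n_z)])
                img = stack.sum(axis=0) if projection == "sum" else stack.max(axis=0)
            if use_true_masks:
                mask = well.true_mask(loop)
                labels, n = ndimage.label(mask)
                if n != 1:
                    continue
            else:
                res = seg.segment_and_postprocess(img, segmenter=segmenter,
                                                  working_size=wsize)
                if not res.accepted:
                    continue
                mask = res.mask
            rows.append(extract_features(img, mask, registry))
            meta.append((well.experiment_id, well.well_id, loop))
    table = pd.DataFrame(rows, columns=registry.names)
    table.insert(0, "experiment_id", [m[0] for m in meta])
    table.insert(1, "well_id", [m[1] for m in meta])
    table.insert(2, "loop", [m[2] for m in meta])
    table.attrs["registry_version"] = registry.version
    table.attrs["projection"] = projection
    return table
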