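"""Attribution-map consensus metrics over stored saliency maps.

Saliency maps are inputs (from any attribution backend, or the synthetic
fixture generator below); this module quantifies their agreement.  Each map
is first z-scored inside the organoid mask; out-of-mask pixels never
influence any metric.  Four readouts:

1. pairwise method agreement: Dice of the binary top-1%/5%/10% in-mask
   pixel sets for every method pair, averaged over the three fractions;
2. cross-model consistency: Spearman correlation of in-mask |saliency|
   ranks between models, per method;
3. focus and drift: Shannon entropy of the probability map formed from the
   top 10% of in-mask pixels (lower = more focused), and the frame-to-frame
   displacement of its centre of mass;
4. region votes: SLIC-style superpixels inside the mask (50 segments,
   compactness 0.1) scored by mean saliency per method; a region receives a
   method's vote when its score is in the top 10% of region scores, and the
   per-frame fractions of regions voted by >= 2, 3, 4 methods are reported.

Entropies use the natural log.  Top-q ties break by flat pixel index.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SaliencyMap",
    "zscore_within_mask",
    "pairwise_method_dice",
    "cross_model_rank_correlation",
    "topq_entropy",
    "center_of_mass_drift",
    "slic_superpixels",
    "superpixel_votes",
    "save_saliency_store",
    "load_saliency_store",
    "synthesize_saliency_maps",
]

MASK_SENTINEL = np.nan
DEFAULT_TOP_FRACS = (0.01, 0.05, 0.10)


@dataclass
class SaliencyMap:
    """One attribution map with its organoid mask and provenance."""

    model_id: str
    method_id: str
    well_id: str
    loop: int
    map: np.ndarray
    mask: np.ndarray
    condition: str = "trained"

    def __post_init__(self) -> None:
        if self.map.shape != self.mask.shape:
            raise ValueError("map and mask must share shape")
        if self.condition not in ("trained", "baseline"):
            raise ValueError("condition must be 'trained' or 'baseline'")


def zscore_within_mask(saliency: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardise in-mask pixels to mean 0 / sd 1; outside set to NaN."""
    mask = np.asarray(mask).astype(bool)
    s = np.asarray(saliency, dtype=np.float64)
    vals = s[mask]
    if vals.size < 2:
        raise ValueError("mask must contain at least 2 pixels")
    sd = vals.std()
    if sd == 0:
        raise ValueError("constant in-mask saliency")
    out = np.full(s.shape, MASK_SENTINEL)
    out[mask] = (vals - vals.mean()) / sd
    return out


def _top_fraction_indices(values: np.ndarray, frac: float) -> np.ndarray:
    """Indices of the top ``frac`` values; ties break by index (ascending)."""
    n = values.size
    m = max(1, int(np.floor(frac * n)))
    order = np.argsort(-values, kind="stable")
    return order[:m]


def pairwise_method_dice(maps: dict, mask: np.ndarray,
                         top_fracs=DEFAULT_TOP_FRACS) -> dict:
    """Mean Dice of top-fraction in-mask pixel sets for every method pair.

    ``maps`` maps method id -> saliency map (raw or standardised; the top
    sets are invariant to the in-mask affine rescaling of z-scoring).
    """
    if len(maps) < 2:
        raise ValueError("need >= 2 methods")
    mask = np.asarray(mask).astype(bool)
    invals = {k: np.asarray(v, dtype=np.float64)[mask] for k, v in maps.items()}
    out = {}
    for a, b in itertools.combinations(sorted(maps), 2):
        dices = []
        for frac in top_fracs:
            ia = set(_top_fraction_indices(invals[a], frac))
            ib = set(_top_fraction_indices(invals[b], frac))
            if not ia or not ib:
                raise ValueError(f"fraction {frac} selects no pixels")
            dices.append(2.0 * len(ia & ib) / (len(ia) + len(ib)))
        out[(a, b)] = float(np.mean(dices))
    return out


def cross_model_rank_correlation(maps: dict, mask: np.ndarray) -> dict:
    """Spearman correlation of in-mask |saliency| ranks between models.

    ``maps`` maps model id -> saliency map on the shared mask.  Values are
    rank-transformed with average ranks for ties, then Pearson-correlated.
    """
    if len(maps) < 2:
        raise ValueError("need >= 2 models")
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 3:
        raise ValueError("need >= 3 in-mask pixels")
    ranks = {k: stats.rankdata(np.abs(np.asarray(v, np.float64)[mask]))
             for k, v in maps.items()}
    out = {}
    for a, b in itertools.combinations(sorted(maps), 2):
        ra, rb = ranks[a], ranks[b]
        if ra.std() == 0 or rb.std() == 0:
            raise ValueError("constant ranks: correlation undefined")
        out[(a, b)] = float(np.corrcoef(ra, rb)[0, 1])
    return out


def _topq_probability(saliency: np.ndarray, mask: np.ndarray, q: float):
    """Top-q in-mask probability vector + pixel coordinates."""
    mask = np.asarray(mask).astype(bool)
    vals = np.asarray(saliency, dtype=np.float64)[mask]
    if vals.size < 10:
        raise ValueError("need >= 10 in-mask pixels")
    idx = _top_fraction_indices(vals, q)
    coords = np.argwhere(mask)[idx]
    sel = vals[idx]
    if sel.min() <= 0 or sel.sum() <= 0:
        warnings.warn("non-positive saliency mass in top set; using uniform "
                      "probabilities", stacklevel=2)
        p = np.full(sel.shape, 1.0 / sel.size)
    else:
        p = sel / sel.sum()
    return p, coords


def topq_entropy(saliency: np.ndarray, mask: np.ndarray, q: float = 0.10) -> float:
    """Shannon entropy (nats) of the top-q in-mask probability map.

    Bounded by [0, log m] for m selected pixels; log(m) when the selected
    saliencies are equal, 0 in the single-point-mass limit.
    """
    p, _ = _topq_probability(saliency, mask, q)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def topq_center_of_mass(saliency: np.ndarray, mask: np.ndarray,
                        q: float = 0.10) -> np.ndarray:
    p, coords = _topq_probability(saliency, mask, q)
    return (p[:, None] * coords).sum(axis=0)


def center_of_mass_drift(maps_by_loop: dict, masks_by_loop: dict,
                         q: float = 0.10) -> dict:
    """Frame-to-frame displacement (px) of the top-q centre of mass.

    ``maps_by_loop``/``masks_by_loop`` map loop index -> arrays.  Steps with
    a missing intermediate loop are skipped.  Returns {loop n: |COM(n+1) -
    COM(n)|}.
    """
    loops = sorted(maps_by_loop)
    if len(loops) < 2:
        raise ValueError("need >= 2 loops")
    com = {lp: topq_center_of_mass(maps_by_loop[lp], masks_by_loop[lp], q)
           for lp in loops}
    out = {}
    for lp in loops:
        if lp + 1 in com:
            out[lp] = float(np.linalg.norm(com[lp + 1] - com[lp]))
    return out


def slic_superpixels(image: np.ndarray, mask: np.ndarray,
                     n_segments: int = 50, compactness: float = 0.1) -> np.ndarray:
    """SLIC-style superpixels clipped to the mask (0 outside)."""
    from skimage.segmentation import slic

    mask = np.asarray(mask).astype(bool)
    return slic(np.asarray(image, dtype=np.float64), n_segments=n_segments,
                compactness=compactness, mask=mask, channel_axis=None,
                start_label=1)


def superpixel_votes(maps: dict, mask: np.ndarray, segments: np.ndarray,
                     q: float = 0.10) -> dict:
    """Region votes per method and multi-method agreement fractions.

    Each region (superpixel inside the mask) is scored by its mean
    (z-scored) saliency per method; the top 10% of region scores receive
    that method's vote (minimum one region).  Returns per-method voted
    region sets and the fractions of regions voted by >= 2, 3, 4 methods.
    """
    mask = np.asarray(mask).astype(bool)
    seg = np.asarray(segments)
    region_ids = np.array(sorted(set(seg[mask & (seg > 0)].ravel())))
    if region_ids.size == 0:
        raise ValueError("superpixels do not cover the mask")
    votes: dict = {}
    for method in sorted(maps):
        z = zscore_within_mask(maps[method], mask)
        scores = np.array([np.nanmean(z[(seg == r) & mask]) for r in region_ids])
        n_vote = max(1, int(np.floor(q * region_ids.size)))
        order = np.argsort(-scores, kind="stable")
        votes[method] = set(region_ids[order[:n_vote]])
    counts = {r: sum(r in v for v in votes.values()) for r in region_ids}
    n = region_ids.size
    agreement = {k: sum(1 for c in counts.values() if c >= k) / n
                 for k in (2, 3, 4)}
    return {"votes": votes, "agreement_fractions": agreement,
            "n_regions": int(n)}


# ---------------------------------------------------------------------------
# HDF5 store: /experiment/well/loop/{model}/{method}/{condition} -> map, mask

def save_saliency_store(path, maps: list[SaliencyMap],
                        experiment_id: str = "E001") -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for sm in maps:
            grp = fh.require_group(
                f"{experiment_id}/{sm.well_id}/{sm.loop}/{sm.model_id}/"
                f"{sm.method_id}/{sm.condition}")
            grp.create_dataset("map", data=sm.map.astype(np.float32))
            grp.create_dataset("mask", data=sm.mask.astype(np.uint8))


def load_saliency_store(path) -> list[SaliencyMap]:
    import h5py

    out: list[SaliencyMap] = []
    with h5py.File(path, "r") as fh:
        def walk(name, obj):
            import h5py as _h

            if isinstance(obj, _h.Group) and "map" in obj and "mask" in obj:
                _, well, loop, model, method, condition = name.split("/")
                out.append(SaliencyMap(
                    model_id=model, method_id=method, well_id=well,
                    loop=int(loop), map=obj["map"][()].astype(np.float64),
                    mask=obj["mask"][()].astype(bool), condition=condition))
        fh.visititems(walk)
    return out


def synthesize_saliency_maps(mask: np.ndarray, methods, models,
                             n_loops: int = 3, agreement: float = 0.5,
                             seed: int = 0) -> list[SaliencyMap]:
    """Synthetic saliency fixtures with controllable cross-method agreement.

    Each (model, loop) has a shared smooth hotspot; each method's map mixes
    that hotspot with independent smooth noise: ``agreement`` = 1 gives
    identical maps, 0 gives independent maps.  Labelled synthetic; stands in
    for attribution outputs in tests and demonstrations.
    """
    from scipy import ndimage

    mask = np.asarray(mask).astype(bool)
    rng = np.random.default_rng([seed, 41])
    coords = np.argwhere(mask)
    maps = []
    for model in models:
        for loop in range(n_loops):
            cy, cx = coords[rng.integers(0, len(coords))]
            yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
            hotspot = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                             / (2.0 * (0.08 * mask.shape[0]) ** 2))
            for method in methods:
                noise = ndimage.gaussian_filter(
                    rng.normal(0.0, 1.0, mask.shape), 3.0)
                noise = (noise - noise.mean()) / (noise.std() + 1e-12)
                m = agreement * hotspot + (1.0 - agreement) * noise
                maps.append(SaliencyMap(model_id=model, method_id=method,
                                        well_id="W000", loop=loop,
                                        map=m, mask=mask))
    return maps
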