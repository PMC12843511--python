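"""Seeded synthetic brightfield time-lapse datasets with known ground truth.

Emulates a 96-well plate acquisition: one organoid per well, imaged every
30 min over 72 h (144 loops) as 5-slice z-stacks spaced 50 um apart, with the
middle slice in focus.  Each well carries a latent tissue fate (RPE and/or
lens): the visible structure (dark pigment patch / bright lens disc) is
rendered only late in the series, while an optional subtle oriented-texture
cue distinguishes fated from non-fated organoids from loop 0 onward.  With
``signal_strength = 0`` the pre-visibility frames of fated and non-fated
wells are drawn from the same distribution (exchangeable), so downstream
predictors have nothing to learn from early frames.

All randomness flows from integer seed sequences, so a given
(config, fate, seed) triple reproduces bit-identical images and labels.
Frames are rendered on demand; nothing pixel-sized is stored per loop.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "AcquisitionConfig",
    "FateSpec",
    "BatchEffects",
    "OutcomeRecord",
    "WellTimeSeries",
    "StereoFrame",
    "simulate_experiment",
    "simulate_study",
    "render_frame",
    "render_stereo",
    "write_dataset",
]

# Intensity model (8-bit gray levels before batch offsets / noise).
_BACKGROUND = 205.0
_TISSUE = 130.0
_TISSUE_DOME = 25.0          # radial shading amplitude inside the organoid
_PIGMENT = 45.0              # RPE patch
_LENS = 238.0                # lens disc
_TEXTURE_SD = 9.0            # smooth intra-organoid texture
_PRE_NOISE_SD = 4.0          # pixel noise added before defocus blur
_POST_NOISE_SD = 0.6         # sensor noise added after blur
_CUE_AMPLITUDE = 25.0        # gray levels per unit signal_strength
_CUE_FREQ_RPE = 0.18         # cycles / px; fine texture -> Laplacian-visible
_CUE_FREQ_LENS = 0.05        # cycles / px; coarse texture -> variance-visible
_REFERENCE_FRAME_PX = 512


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry of one synthetic study.

    Defaults reproduce the real acquisition design: 96 wells per plate,
    images every 30 min for 72 h (144 loops), 5 z-slices spaced 50 um.
    ``um_per_px`` defaults to ``512 / frame_px`` so the rendered scene covers
    the same physical field of view at any raster size (512 um across),
    keeping the um^2 outcome-area scale independent of ``frame_px``.
    """

    n_experiments: int = 3
    wells_per_plate: int = 96
    duration_h: float = 72.0
    interval_min: float = 30.0
    n_z: int = 5
    z_spacing_um: float = 50.0
    frame_px: int = 512
    um_per_px: float | None = None
    seed: int = 0
    bit_depth: int = 8
    exclusion_prob: float = 0.02

    def __post_init__(self) -> None:
        if self.wells_per_plate <= 0:
            raise ValueError("wells_per_plate must be positive")
        if self.n_z <= 0 or self.frame_px <= 0:
            raise ValueError("n_z and frame_px must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        loops = self.duration_h * 60.0 / self.interval_min
        if abs(loops - round(loops)) > 1e-9:
            raise ValueError(
                f"duration_h*60/interval_min = {loops} is not an integer loop count"
            )

    @property
    def n_loops(self) -> int:
        return round(self.duration_h * 60.0 / self.interval_min)

    @property
    def images_per_plate(self) -> int:
        return self.wells_per_plate * self.n_loops * self.n_z

    @property
    def scale_um_per_px(self) -> float:
        if self.um_per_px is not None:
            return self.um_per_px
        return _REFERENCE_FRAME_PX / self.frame_px

    @property
    def middle_z(self) -> int:
        return self.n_z // 2


@dataclass(frozen=True)
class BatchEffects:
    """Per-experiment nuisance variation (SDs of seeded draws)."""

    illumination_sd: float = 6.0    # gray-level offset of the whole frame
    radius_shift_sd: float = 0.06   # relative shift of the mean organoid radius


@dataclass(frozen=True)
class FateSpec:
    """Latent fate model: probabilities, visibility onsets, area laws.

    ``rpe_visible_loop`` / ``lens_visible_loop`` default to the observed
    onsets of the real system expressed as fractions of the imaging window
    (RPE ~44/72, lens ~35/72) and are resolved against the config's loop
    count.  Area distributions are lognormal with parameters calibrated so
    that the pooled 33rd/66th percentiles of positive areas sit near the
    reference cutoffs (RPE 4,541.73 / 7,548.51 um^2; lens 16,324.85 /
    29,083.23 um^2).
    """

    rpe_prob: float = 0.5
    lens_prob: float = 0.5
    rpe_visible_loop: int | None = None
    lens_visible_loop: int | None = None
    signal_strength: float = 0.4
    rpe_area_dist: tuple = ("lognormal", {"mean_log": 8.683, "sigma_log": 0.596})
    lens_area_dist: tuple = ("lognormal", {"mean_log": 9.998, "sigma_log": 0.678})
    batch_effects: BatchEffects = field(default_factory=BatchEffects)

    _RPE_VISIBLE_FRAC = 44.0 / 72.0
    _LENS_VISIBLE_FRAC = 35.0 / 72.0

    def __post_init__(self) -> None:
        for p in (self.rpe_prob, self.lens_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fate probabilities must be in [0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")

    def resolved_visible_loops(self, cfg: AcquisitionConfig) -> tuple[int, int]:
        n = cfg.n_loops
        rpe = self.rpe_visible_loop
        lens = self.lens_visible_loop
        if rpe is None:
            rpe = int(round(self._RPE_VISIBLE_FRAC * n))
        if lens is None:
            lens = int(round(self._LENS_VISIBLE_FRAC * n))
        if not (0 <= rpe < n and 0 <= lens < n):
            raise ValueError("visible loops must satisfy 0 <= loop < n_loops")
        return rpe, lens


def _sample_area(dist: tuple, rng: np.random.Generator) -> float:
    family, params = dist
    if family == "lognormal":
        return float(rng.lognormal(params["mean_log"], params["sigma_log"]))
    if family == "uniform":
        return float(rng.uniform(params["low"], params["high"]))
    raise ValueError(f"unknown area distribution family: {family!r}")


@dataclass
class OutcomeRecord:
    """Per-organoid ground truth; area > 0 iff present, class 0 iff absent."""

    rpe_present: bool
    rpe_area_um2: float
    lens_present: bool
    lens_area_um2: float
    rpe_class: int | None = None
    lens_class: int | None = None
    morphology_cluster: int | None = None

    def __post_init__(self) -> None:
        if self.rpe_present != (self.rpe_area_um2 > 0):
            raise ValueError("rpe_area_um2 > 0 must hold iff rpe_present")
        if self.lens_present != (self.lens_area_um2 > 0):
            raise ValueError("lens_area_um2 > 0 must hold iff lens_present")


@dataclass
class WellTimeSeries:
    """All metadata needed to render one organoid's time series on demand."""

    experiment_id: str
    well_id: str
    cfg: AcquisitionConfig
    outcome: OutcomeRecord
    excluded_loops: frozenset
    params: dict

    def frame(self, loop: int, z: int) -> np.ndarray:
        return render_frame(self, loop, z)

    def true_mask(self, loop: int) -> np.ndarray:
        return _organoid_mask(self, loop)

    def frames(self, loops=None, zs=None):
        """Iterate (loop, z, image) lazily over the requested indices."""
        loops = range(self.cfg.n_loops) if loops is None else loops
        zs = range(self.cfg.n_z) if zs is None else zs
        for loop in loops:
            for z in zs:
                yield loop, z, self.frame(loop, z)


# ---------------------------------------------------------------------------
# simulation

def _well_parameters(cfg: AcquisitionConfig, fate: FateSpec,
                     exp_index: int, well_index: int,
                     batch: dict) -> tuple[dict, OutcomeRecord, frozenset]:
    rng = np.random.default_rng([cfg.seed, 7, exp_index, well_index])
    n_loops = cfg.n_loops
    fp = cfg.frame_px
    scale = fp / _REFERENCE_FRAME_PX
    um = cfg.scale_um_per_px

    rpe_vis, lens_vis = fate.resolved_visible_loops(cfg)
    rpe_fated = bool(rng.random() < fate.rpe_prob)
    lens_fated = bool(rng.random() < fate.lens_prob)

    # shape: common near-spherical start, per-well target irregularity reached
    # at the final loop -> inter-organoid divergence grows with loop index
    r0 = 0.18 * fp * (1.0 + batch["radius_shift"]) * (1.0 + 0.04 * rng.normal())
    growth = 0.5 + 0.05 * rng.normal()
    harmonics_k = np.arange(2, 6)
    harm_amp = rng.normal(0.0, 1.0, size=harmonics_k.size) / harmonics_k
    harm_phase = rng.uniform(0.0, 2.0 * np.pi, size=harmonics_k.size)
    irregularity = 0.12
    # per-loop boundary jitter, amplitude ramping with time -> consecutive
    # morphological change increases over the series
    jitter = rng.normal(0.0, 1.0, size=(n_loops, harmonics_k.size))
    jitter_phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_loops, harmonics_k.size))
    # slow centroid drift
    steps = rng.normal(0.0, 0.35 * max(scale, 0.1), size=(n_loops, 2))
    centers = np.array([fp / 2.0, fp / 2.0]) + np.cumsum(steps, axis=0)

    rpe_area = _sample_area(fate.rpe_area_dist, rng) if rpe_fated else 0.0
    lens_area = _sample_area(fate.lens_area_dist, rng) if lens_fated else 0.0
    # the rendered lens must fit inside the organoid; clip the drawn area so
    # ground truth matches what is actually drawn
    r_final_px = r0 * (1.0 + growth)
    max_lens_r_um = 0.80 * r_final_px * um
    if lens_fated:
        lens_area = min(lens_area, math.pi * max_lens_r_um ** 2)
    # structure anchor points (unit offsets from the centre, polar); the two
    # tissues sit in opposite half-planes so neither occludes the other
    rpe_angle = rng.uniform(0.0, 2.0 * np.pi)
    rpe_anchor = (rng.uniform(0.30, 0.55), rpe_angle)
    lens_anchor = (rng.uniform(0.05, 0.25), rpe_angle + np.pi)
    cue_phase = rng.uniform(0.0, 2.0 * np.pi)

    outcome = OutcomeRecord(
        rpe_present=rpe_fated, rpe_area_um2=rpe_area,
        lens_present=lens_fated, lens_area_um2=lens_area,
    )

    excluded: frozenset = frozenset()
    if rng.random() < cfg.exclusion_prob and n_loops > 1:
        onset = int(rng.integers(1, n_loops))
        excluded = frozenset(range(onset, n_loops))

    params = dict(
        exp_index=exp_index, well_index=well_index,
        r0=r0, growth=growth,
        harmonics_k=harmonics_k, harm_amp=harm_amp, harm_phase=harm_phase,
        irregularity=irregularity, jitter=jitter, jitter_phase=jitter_phase,
        centers=centers,
        rpe_fated=rpe_fated, lens_fated=lens_fated,
        rpe_visible_loop=rpe_vis, lens_visible_loop=lens_vis,
        rpe_anchor=rpe_anchor, lens_anchor=lens_anchor,
        cue_phase=cue_phase, signal_strength=fate.signal_strength,
        illumination=batch["illumination"],
    )
    return params, outcome, excluded


def simulate_experiment(cfg: AcquisitionConfig, fate: FateSpec,
                        experiment_index: int = 0) -> list[WellTimeSeries]:
    """Simulate one plate (one experimental replicate).

    Deterministic in (cfg.seed, experiment_index).  Returns one
    :class:`WellTimeSeries` per well; images render lazily via
    :func:`render_frame`.
    """
    batch_rng = np.random.default_rng([cfg.seed, 3, experiment_index])
    be = fate.batch_effects
    batch = dict(
        illumination=float(batch_rng.normal(0.0, be.illumination_sd)),
        radius_shift=float(batch_rng.normal(0.0, be.radius_shift_sd)),
    )
    exp_id = f"E{experiment_index + 1:03d}"
    wells = []
    for w in range(cfg.wells_per_plate):
        params, outcome, excluded = _well_parameters(cfg, fate, experiment_index, w, batch)
        well_id = f"{chr(ord('A') + w // 12)}{w % 12 + 1:03d}"
        wells.append(WellTimeSeries(
            experiment_id=exp_id, well_id=well_id, cfg=cfg,
            outcome=outcome, excluded_loops=excluded, params=params,
        ))
    return wells


def simulate_study(cfg: AcquisitionConfig, fate: FateSpec) -> list[WellTimeSeries]:
    """Simulate ``cfg.n_experiments`` plates and pool them.

    Size classes (1/2/3) are assigned from the pooled 33rd/66th percentiles
    of positive areas across the whole study, mirroring how cutoffs are
    derived from an entire training dataset.
    """
    wells: list[WellTimeSeries] = []
    for e in range(cfg.n_experiments):
        wells.extend(simulate_experiment(cfg, fate, e))
    assign_study_classes(wells)
    return wells


def assign_study_classes(wells: list[WellTimeSeries]) -> None:
    """Fill rpe_class / lens_class from pooled positive-area percentiles."""
    from . import toi_quantification as toi

    for tissue in ("rpe", "lens"):
        areas = np.array([getattr(w.outcome, f"{tissue}_area_um2") for w in wells])
        positive = areas[areas > 0]
        if positive.size >= 3:
            cutoffs = toi.compute_class_cutoffs(positive, tissue=tissue)
        else:
            cutoffs = None
        for w in wells:
            present = getattr(w.outcome, f"{tissue}_present")
            if not present:
                cls = 0
            elif cutoffs is None:
                cls = 1
            else:
                cls = toi.assign_size_class(
                    getattr(w.outcome, f"{tissue}_area_um2"), True, cutoffs)
            setattr(w.outcome, f"{tissue}_class", cls)


# ---------------------------------------------------------------------------
# rendering

def _boundary_radius(well: WellTimeSeries, loop: int, theta: np.ndarray) -> np.ndarray:
    p = well.params
    n_loops = well.cfg.n_loops
    t = loop / max(n_loops - 1, 1)
    base = p["r0"] * (1.0 + p["growth"] * t)
    wobble = np.zeros_like(theta)
    for i, k in enumerate(p["harmonics_k"]):
        wobble += p["harm_amp"][i] * np.cos(k * theta + p["harm_phase"][i])
        wobble += 0.25 * t * p["jitter"][loop, i] * np.cos(
            k * theta + p["jitter_phase"][loop, i])
    return base * (1.0 + p["irregularity"] * t * wobble)


def _polar_grid(well: WellTimeSeries, loop: int):
    fp = well.cfg.frame_px
    cy, cx = well.params["centers"][loop]
    yy, xx = np.mgrid[0:fp, 0:fp].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    return rho, theta, (cy, cx)


def _organoid_mask(well: WellTimeSeries, loop: int) -> np.ndarray:
    if not 0 <= loop < well.cfg.n_loops:
        raise IndexError(f"loop {loop} out of range")
    rho, theta, _ = _polar_grid(well, loop)
    return rho <= _boundary_radius(well, loop, theta)


def _structure_mask(rho, theta, center, anchor, radius_px, boundary_r):
    """Disc of ``radius_px`` anchored at polar ``anchor`` inside the organoid."""
    frac, ang = anchor
    ay = center[0] + frac * boundary_r * np.sin(ang)
    ax = center[1] + frac * boundary_r * np.cos(ang)
    fp = rho.shape[0]
    yy, xx = np.mgrid[0:fp, 0:fp].astype(np.float64)
    return np.hypot(yy - ay, xx - ax) <= radius_px


def render_frame(well: WellTimeSeries, loop: int, z: int) -> np.ndarray:
    """Render one grayscale frame (uint8 or uint16 per config bit depth).

    The middle z-slice is the sharpest (defocus blur grows with the distance
    from the middle slice).  Visible structures appear only at or after their
    fate's visibility loop; pre-visibility frames of non-fated wells carry no
    trace of the fate except the oriented-texture cue (if signal_strength>0).
    """
    cfg = well.cfg
    if not 0 <= loop < cfg.n_loops:
        raise IndexError(f"loop {loop} out of range [0, {cfg.n_loops})")
    if not 0 <= z < cfg.n_z:
        raise IndexError(f"z {z} out of range [0, {cfg.n_z})")
    p = well.params
    fp = cfg.frame_px
    um = cfg.scale_um_per_px
    scale = fp / _REFERENCE_FRAME_PX

    rho, theta, center = _polar_grid(well, loop)
    boundary = _boundary_radius(well, loop, theta)
    mask = rho <= boundary
    base_r = p["r0"] * (1.0 + p["growth"] * loop / max(cfg.n_loops - 1, 1))

    img = np.full((fp, fp), _BACKGROUND + p["illumination"], dtype=np.float64)
    # organoid body with a radial dome (darker centre) and smooth texture
    rel = np.clip(rho / np.maximum(boundary, 1e-9), 0.0, 1.0)
    tissue = _TISSUE + p["illumination"] + _TISSUE_DOME * rel
    rng = np.random.default_rng([cfg.seed, 11, p["exp_index"], p["well_index"], loop, z])
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (fp, fp)),
                                      2.0 * max(scale, 0.25)) * _TEXTURE_SD * 3.0
    img[mask] = tissue[mask] + texture[mask]

    # latent fate cue: oriented sinusoid, present from loop 0 in fated wells
    if p["signal_strength"] > 0:
        yy, xx = np.mgrid[0:fp, 0:fp].astype(np.float64)
        amp = _CUE_AMPLITUDE * p["signal_strength"]
        # the two fates carry cues at distinct orientations and spatial
        # frequencies, so each is recoverable by second-order statistics
        # without being confounded by the other
        if p["rpe_fated"]:
            cue = amp * np.sin(2.0 * np.pi * _CUE_FREQ_RPE * xx + p["cue_phase"])
            img[mask] += cue[mask]
        if p["lens_fated"]:
            cue = amp * np.sin(2.0 * np.pi * _CUE_FREQ_LENS * (0.7071 * (xx + yy))
                               + p["cue_phase"] + 1.0)
            img[mask] += cue[mask]

    # visible structures ramp in after their visibility loop; pigment is
    # drawn last (opaque surface pigment occludes underlying structures)
    if p["lens_fated"] and loop >= p["lens_visible_loop"]:
        span = max(cfg.n_loops - 1 - p["lens_visible_loop"], 1)
        ramp = max((loop - p["lens_visible_loop"]) / span, 1.0 / (span + 1))
        r_px = math.sqrt(well.outcome.lens_area_um2 * ramp / math.pi) / um
        disc = _structure_mask(rho, theta, center, p["lens_anchor"], r_px, base_r)
        img[disc & mask] = _LENS + p["illumination"]
    if p["rpe_fated"] and loop >= p["rpe_visible_loop"]:
        span = max(cfg.n_loops - 1 - p["rpe_visible_loop"], 1)
        ramp = max((loop - p["rpe_visible_loop"]) / span, 1.0 / (span + 1))
        r_px = math.sqrt(well.outcome.rpe_area_um2 * ramp / math.pi) / um
        patch = _structure_mask(rho, theta, center, p["rpe_anchor"], r_px, base_r)
        img[patch & mask] = _PIGMENT + p["illumination"]

    img += rng.normal(0.0, _PRE_NOISE_SD, (fp, fp))
    # z-dependent defocus: middle slice sharpest; excluded loops are rendered
    # strongly defocused to emulate the focus loss that triggered exclusion.
    # Blur is in pixels (optical PSF at the sensor), not scene-relative, so
    # the sharpness ordering holds at any raster size.
    sigma = 0.5 + 1.1 * abs(z - cfg.middle_z)
    if loop in well.excluded_loops:
        sigma += 3.0
    img = ndimage.gaussian_filter(img, sigma)
    img += rng.normal(0.0, _POST_NOISE_SD, (fp, fp))

    img = np.clip(img, 0.0, 255.0)
    if cfg.bit_depth == 8:
        return np.rint(img).astype(np.uint8)
    return np.rint(img * 257.0).astype(np.uint16)


@dataclass
class StereoFrame:
    """Synthetic stereomicroscope-like view of one organoid at endpoint."""

    image: np.ndarray
    organoid_mask: np.ndarray
    pigment_mask: np.ndarray

    @property
    def true_pigment_px(self) -> int:
        return int(self.pigment_mask.sum())


def render_stereo(well: WellTimeSeries, pigment_area_px: float | None = None) -> StereoFrame:
    """Render the endpoint stereo image used for RPE-area quantification.

    The organoid tissue is bright and gently shaded; a few dark micro-debris
    pixels are always present (as in real stereo images), so that in-ROI
    min-max rescaling has genuinely dark content to anchor to.  The pigment
    patch, when present, is rendered with the well's true RPE area (or an
    explicit ``pigment_area_px`` override for fixtures).
    """
    cfg = well.cfg
    p = well.params
    fp = cfg.frame_px
    um = cfg.scale_um_per_px
    loop = cfg.n_loops - 1
    rho, theta, center = _polar_grid(well, loop)
    boundary = _boundary_radius(well, loop, theta)
    mask = rho <= boundary
    base_r = p["r0"] * (1.0 + p["growth"])

    rng = np.random.default_rng([cfg.seed, 13, p["exp_index"], p["well_index"]])
    img = np.full((fp, fp), 235.0)
    rel = np.clip(rho / np.maximum(boundary, 1e-9), 0.0, 1.0)
    img[mask] = (185.0 - 12.0 * rel + rng.normal(0.0, 2.0, (fp, fp)))[mask]

    # dark micro-debris: a handful of 1-2 px specks inside the organoid
    inside = np.argwhere(rho <= 0.8 * boundary)
    for _ in range(4):
        y, x = inside[rng.integers(0, len(inside))]
        img[max(y - 1, 0):y + 1, max(x - 1, 0):x + 1] = 90.0 + rng.normal(0.0, 3.0)

    pigment = np.zeros_like(mask)
    if pigment_area_px is None:
        area_px = well.outcome.rpe_area_um2 / um ** 2 if well.outcome.rpe_present else 0.0
    else:
        area_px = float(pigment_area_px)
    if area_px > 0:
        r_px = math.sqrt(area_px / math.pi)
        pigment = _structure_mask(rho, theta, center, p["rpe_anchor"], r_px, base_r) & mask

    img = np.clip(ndimage.gaussian_filter(img, 0.5), 0.0, 255.0)
    # pigment saturates the sensor floor: stamped sharp and exactly black
    # after the optics blur, as dense pigment appears in stereo imaging
    img[pigment] = 0.0
    return StereoFrame(image=np.rint(img).astype(np.uint8),
                       organoid_mask=mask, pigment_mask=pigment)


# ---------------------------------------------------------------------------
# on-disk layout: E{exp:03d}/{well}/L{loop:03d}_Z{z}.tif + outcomes.csv + masks

def write_dataset(wells: list[WellTimeSeries], out_dir, loops=None,
                  write_masks: bool = True) -> Path:
    """Write TIFF frames, PNG masks and the outcome/metadata CSV."""
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for well in wells:
        exp_dir = out / well.experiment_id / well.well_id
        exp_dir.mkdir(parents=True, exist_ok=True)
        sel = range(well.cfg.n_loops) if loops is None else loops
        for loop in sel:
            for z in range(well.cfg.n_z):
                tifffile.imwrite(exp_dir / f"L{loop:03d}_Z{z}.tif",
                                 well.frame(loop, z))
            if write_masks:
                m = (well.true_mask(loop).astype(np.uint8)) * 255
                iio.imwrite(exp_dir / f"L{loop:03d}_mask.png", m)
        o = well.outcome
        rows.append(dict(
            experiment_id=well.experiment_id, well_id=well.well_id,
            rpe_present=int(o.rpe_present), rpe_area_um2=o.rpe_area_um2,
            rpe_class=o.rpe_class if o.rpe_class is not None else "",
            lens_present=int(o.lens_present), lens_area_um2=o.lens_area_um2,
            lens_class=o.lens_class if o.lens_class is not None else "",
            excluded_from_loop=min(well.excluded_loops) if well.excluded_loops else "",
        ))
    with open(out / "outcomes.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return out
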