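"""Seeded synthetic-data generators with known ground truth.

Two emulators stand in for the experimental recordings: B-mode frame stacks
of a blood-vessel-mimicking tube phantom with stochastic hyperechoic
cavitation events, and repeated OCT B-scan series where flow pixels
decorrelate across repeats over static tissue speckle, with a programmable
treated/untreated vessel-density ratio.

Every generator is a pure function of (config, seed); ground truth is
returned alongside the data so downstream detectors and estimators can be
scored without re-deriving it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cavitation_detect import FrameStack
from .octa import OctScanSeries
from .pa_source import ParameterError

__all__ = [
    "BmodeGenConfig",
    "OctGenConfig",
    "gen_bmode_stack",
    "gen_oct_series",
]


@dataclass(frozen=True)
class BmodeGenConfig:
    """Tube-phantom B-mode stack generator settings.

    The phantom is static: each stack shares one frozen speckle pattern
    (drawn from ``pattern_seed``, so baseline and test stacks of the same
    series image the same phantom) with a bright annulus for the hyperechoic
    tube walls.  Per-frame temporal noise is truncated at
    ``truncate_sd`` SDs — scanner noise in a fixed ROI is bounded and
    quantized, and an any-pixel threshold rule over thousands of pixels is
    only meaningful for bounded tails.  Cavitation events are bright blobs
    injected inside the lumen in a Bernoulli(p_event) subset of frames,
    ``event_contrast_sd`` temporal-noise-SDs above the local pattern.
    """

    frame_shape: tuple = (64, 64)
    n_frames: int = 100
    tube_center_px: tuple = (32, 32)
    tube_lumen_radius_px: float = 6.0
    tube_wall_px: float = 3.0
    speckle_mean: float = 50.0
    speckle_sd: float = 5.0  # spatial SD of the frozen pattern
    temporal_noise_sd: float = 2.0
    truncate_sd: float = 1.5
    wall_intensity: float = 150.0
    p_event: float = 0.3
    event_contrast_sd: float = 6.0
    event_size_px: int = 2
    event_margin_px: float = 3.0  # keep event centres clear of the wall mask
    noise_family: str = "gaussian"  # "gaussian" | "rayleigh" (pattern family)
    seed: int = 0
    pattern_seed: int | None = None  # defaults to ``seed``

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_event <= 1.0:
            raise ParameterError("p_event must lie in [0, 1]")
        if self.event_contrast_sd <= 0:
            raise ParameterError("event contrast must be positive")
        if self.noise_family not in ("gaussian", "rayleigh"):
            raise ParameterError("noise family must be 'gaussian' or 'rayleigh'")
        r, c = self.tube_center_px
        rad = self.tube_lumen_radius_px + self.tube_wall_px
        if (
            r - rad < 0
            or c - rad < 0
            or r + rad >= self.frame_shape[0]
            or c + rad >= self.frame_shape[1]
        ):
            raise ParameterError("tube geometry extends outside the frame")


@dataclass(frozen=True)
class OctGenConfig:
    """Repeated-B-scan OCT series generator settings.

    Static tissue pixels share one speckle realization across repeats (up to
    small jitter); vessel pixels are redrawn independently per repeat
    (maximal flow decorrelation).  ``treated_fraction_retained`` converts the
    complementary fraction of vessel voxels to static tissue in the treated
    series, programming a treated/untreated density ratio.
    """

    n_positions: int = 64
    depth_px: int = 128
    lateral_px: int = 64
    lateral_extent_mm: tuple = (8.0, 8.0)
    axial_pitch_um: float = 3.0
    n_repeats: int = 3
    vessel_fraction: float = 0.12
    speckle_mean: float = 100.0
    flow_decorrelation_sd: float = 25.0
    static_jitter_sd: float = 1.0
    treated_fraction_retained: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.treated_fraction_retained <= 1.0:
            raise ParameterError("treated_fraction_retained must lie in [0, 1]")
        if not 0.0 <= self.vessel_fraction <= 1.0:
            raise ParameterError("vessel fraction must lie in [0, 1]")
        if self.n_repeats < 2:
            raise ParameterError("need at least 2 repeats")
        if self.seed is None:
            raise ParameterError("seed is mandatory")


def _speckle(rng: np.random.Generator, shape, mean: float, sd: float, family: str) -> np.ndarray:
    if family == "rayleigh":
        scale = mean / math.sqrt(math.pi / 2.0)
        return rng.rayleigh(scale, size=shape)
    return np.clip(rng.normal(mean, sd, size=shape), 0.0, None)


def gen_bmode_stack(cfg: BmodeGenConfig) -> tuple:
    """Generate a tube-phantom stack; returns (FrameStack, truth).

    ``truth`` is a dict with the per-frame event indicator, the event pixel
    coordinates per frame, and the tube wall mask.
    """
    rng_pat = np.random.default_rng(cfg.pattern_seed if cfg.pattern_seed is not None else cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.frame_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dist = np.hypot(rr - cfg.tube_center_px[0], cc - cfg.tube_center_px[1])
    lumen = dist <= cfg.tube_lumen_radius_px
    wall = (dist > cfg.tube_lumen_radius_px) & (
        dist <= cfg.tube_lumen_radius_px + cfg.tube_wall_px
    )

    # frozen phantom speckle pattern, bright static tube walls
    pattern = _speckle(rng_pat, (rows, cols), cfg.speckle_mean, cfg.speckle_sd, cfg.noise_family)
    pattern[wall] += cfg.wall_intensity - cfg.speckle_mean

    noise = rng.normal(0.0, cfg.temporal_noise_sd, size=(cfg.n_frames, rows, cols))
    bound = cfg.truncate_sd * cfg.temporal_noise_sd
    np.clip(noise, -bound, bound, out=noise)
    frames = np.clip(pattern[None] + noise, 0.0, None)

    events = rng.random(cfg.n_frames) < cfg.p_event
    core = dist <= max(cfg.tube_lumen_radius_px - cfg.event_margin_px, 1.0)
    core_idx = np.argwhere(core)
    event_pixels = []
    half = cfg.event_size_px // 2
    for i in np.nonzero(events)[0]:
        r0, c0 = core_idx[rng.integers(len(core_idx))]
        rs = slice(max(r0 - half, 0), min(r0 + half + 1, rows))
        cs = slice(max(c0 - half, 0), min(c0 + half + 1, cols))
        frames[i, rs, cs] = (
            pattern[rs, cs] + cfg.event_contrast_sd * cfg.temporal_noise_sd
        )
        event_pixels.append((int(i), int(r0), int(c0)))

    stack = FrameStack(frames=frames)
    truth = {
        "event_frames": events,
        "event_pixels": event_pixels,
        "wall_mask": wall,
        "lumen_mask": lumen,
        "pattern": pattern,
    }
    return stack, truth


def _make_volume(
    rng: np.random.Generator,
    cfg: OctGenConfig,
    vessel_mask: np.ndarray,
) -> np.ndarray:
    """One (position, repeat, depth, lateral) volume for a given vessel mask."""
    shape = (cfg.n_positions, cfg.depth_px, cfg.lateral_px)
    static_base = rng.normal(cfg.speckle_mean, cfg.flow_decorrelation_sd, size=shape)
    vol = np.empty((cfg.n_positions, cfg.n_repeats, cfg.depth_px, cfg.lateral_px))
    for rep in range(cfg.n_repeats):
        frame = static_base + rng.normal(0.0, cfg.static_jitter_sd, size=shape)
        flow = rng.normal(cfg.speckle_mean, cfg.flow_decorrelation_sd, size=shape)
        frame = np.where(vessel_mask, flow, frame)
        vol[:, rep] = np.clip(frame, 0.0, None)
    return vol


def gen_oct_series(cfg: OctGenConfig, *, region_id: str = "R1", side: str = "top",
                   timepoint: str = "day7") -> tuple:
    """Generate an (untreated, treated) OCT series pair with ground truth.

    The treated series keeps ``treated_fraction_retained`` of the vessel
    voxels (chosen at random with the config seed) and converts the rest to
    static tissue.  Returns ``(untreated, treated, truth)`` where truth holds
    both vessel masks and the programmed percent reduction of vessel volume.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_positions, cfg.depth_px, cfg.lateral_px)
    vessel = rng.random(shape) < cfg.vessel_fraction
    keep = rng.random(shape) < cfg.treated_fraction_retained
    vessel_treated = vessel & keep

    untreated = OctScanSeries(
        volumes=_make_volume(rng, cfg, vessel),
        lateral_extent_mm=cfg.lateral_extent_mm,
        axial_pitch_um=cfg.axial_pitch_um,
        region_id=region_id,
        side=side,
        timepoint=timepoint,
        arm="untreated",
    )
    treated = OctScanSeries(
        volumes=_make_volume(rng, cfg, vessel_treated),
        lateral_extent_mm=cfg.lateral_extent_mm,
        axial_pitch_um=cfg.axial_pitch_um,
        region_id=region_id,
        side=side,
        timepoint=timepoint,
        arm="treated",
    )
    n_v = int(vessel.sum())
    truth = {
        "vessel_mask": vessel,
        "vessel_mask_treated": vessel_treated,
        "programmed_reduction_pct": (1.0 - cfg.treated_fraction_retained) * 100.0,
        "realized_reduction_pct": (1.0 - vessel_treated.sum() / n_v) * 100.0 if n_v else 0.0,
    }
    return untreated, treated, truth


def oct_config_for_reduction(reduction_pct: float, seed: int, **overrides) -> OctGenConfig:
    """Config programming a target percent reduction in vessel density."""
    return OctGenConfig(
        treated_fraction_retained=1.0 - reduction_pct / 100.0, seed=seed, **overrides
    )
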