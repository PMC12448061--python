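"""Active cavitation detection from B-mode frame stacks.

Implements the phantom-study statistic: per-pixel baseline mean and SD are
fitted on a zero-fluence stack, the static tube structure is masked, and a
frame counts as containing cavitation once any unmasked pixel exceeds
µ_b + k·σ_b (k = 3 by default).  The cavitation probability (CP) of a stack
is the fraction of flagged frames; CP over a pressure × fluence grid of
stacks forms the CP map.

B-mode speckle is spatially inhomogeneous, so per-pixel baseline statistics
are the default; a global-baseline switch preserves the alternative reading
(one mean/SD pooled over all unmasked pixels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .pa_source import ParameterError

__all__ = [
    "FrameStack",
    "BaselineModel",
    "CavitationProbabilityMap",
    "fit_baseline",
    "auto_tube_mask",
    "detect_frame",
    "cavitation_probability",
    "cp_map",
    "load_stack",
]


class InputError(ValueError):
    """Shape or content problem in image inputs."""


@dataclass(frozen=True)
class FrameStack:
    """n_frames × rows × cols intensity raster with acquisition labels."""

    frames: np.ndarray
    pixel_size_mm: float = 0.05
    pressure_MPa: float | None = None
    fluence_mJ_cm2: float | None = None
    role: str = "test"  # "baseline" | "test"

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3 or f.shape[0] < 1:
            raise InputError("frames must be a (n_frames, rows, cols) array")
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise InputError("intensities must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class BaselineModel:
    """Per-pixel (or global) baseline statistics plus the structure mask.

    ``mask`` is True on *excluded* (structure) pixels.
    """

    mean: np.ndarray
    sd: np.ndarray
    mask: np.ndarray
    k: float = 3.0
    global_baseline: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape or self.mean.shape != self.mask.shape:
            raise InputError("baseline mean/sd/mask shapes must match")
        if np.any(self.sd < 0):
            raise InputError("baseline SD must be non-negative")
        if self.k <= 0:
            raise ParameterError("SD multiplier k must be positive")

    @property
    def threshold(self) -> np.ndarray:
        return self.mean + self.k * self.sd


@dataclass(frozen=True)
class CavitationProbabilityMap:
    """CP ∈ [0, 1] per (pressure, fluence) cell."""

    table: pd.DataFrame  # columns: pressure_MPa, fluence_mJcm2, cp, n_frames

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def auto_tube_mask(
    baseline_stack: FrameStack, dilate_px: int = 2, threshold: float | None = None
) -> np.ndarray:
    """Mask of the bright static tube structure in the baseline stack.

    The temporal-mean image is thresholded (Otsu-style two-class split by
    default) and dilated by ``dilate_px``.
    """
    mean_img = baseline_stack.frames.mean(axis=0)
    if threshold is None:
        threshold = _otsu(mean_img)
    mask = mean_img > threshold
    if dilate_px > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate_px)
    return mask


def _otsu(img: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold on a float image (between-class variance maximizer)."""
    hist, edges = np.histogram(img.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_all = cum_m[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mean_all * cum_w - cum_m) ** 2 / (cum_w * (total - cum_w))
    between[~np.isfinite(between)] = -1.0
    return float(centers[int(np.argmax(between))])


def fit_baseline(
    stack: FrameStack,
    mask: np.ndarray | None = None,
    k: float = 3.0,
    *,
    global_baseline: bool = False,
    auto_mask: bool = False,
    dilate_px: int = 2,
) -> BaselineModel:
    """Per-pixel temporal mean and SD of a zero-fluence baseline stack.

    ``mask`` marks structure pixels to exclude; with ``auto_mask`` it is
    derived from the temporal-mean image.  At least two frames are required
    for the SD.
    """
    if stack.n_frames < 2:
        raise InputError("baseline needs at least 2 frames for SD estimation")
    if mask is None:
        mask = (
            auto_tube_mask(stack, dilate_px)
            if auto_mask
            else np.zeros(stack.frame_shape, dtype=bool)
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.frame_shape:
        raise InputError("mask shape must match frames")
    mean = stack.frames.mean(axis=0)
    sd = stack.frames.std(axis=0, ddof=1)
    meta = {"n_frames": stack.n_frames}
    if global_baseline:
        valid = ~mask
        g_mean = float(mean[valid].mean())
        g_sd = float(stack.frames[:, valid].std(ddof=1))
        mean = np.full(stack.frame_shape, g_mean)
        sd = np.full(stack.frame_shape, g_sd)
    return BaselineModel(mean=mean, sd=sd, mask=mask, k=k, global_baseline=global_baseline, meta=meta)


def detect_frame(frame: np.ndarray, baseline: BaselineModel) -> dict:
    """Flag a frame if any unmasked pixel exceeds µ_b + k·σ_b.

    Returns ``{"flagged": bool, "n_suprathreshold_pixels": int}``.
    """
    frame = np.asarray(frame)
    if frame.shape != baseline.mean.shape:
        raise InputError(f"frame shape {frame.shape} != baseline shape {baseline.mean.shape}")
    supra = (frame > baseline.threshold) & ~baseline.mask
    n = int(np.count_nonzero(supra))
    return {"flagged": n > 0, "n_suprathreshold_pixels": n}


def cavitation_probability(stack: FrameStack, baseline: BaselineModel) -> float:
    """Fraction of frames in the stack with detected cavitation."""
    if stack.n_frames < 1:
        raise InputError("empty stack")
    flagged = flagged_frames(stack, baseline)
    return float(flagged.size) / stack.n_frames


def flagged_frames(stack: FrameStack, baseline: BaselineModel) -> np.ndarray:
    """Indices of frames with at least one unmasked suprathreshold pixel."""
    if stack.frame_shape != baseline.mean.shape:
        raise InputError("stack geometry does not match baseline")
    supra = (stack.frames > baseline.threshold[None]) & ~baseline.mask[None]
    return np.nonzero(supra.any(axis=(1, 2)))[0]


def cp_map(
    stacks: list[FrameStack],
    baseline: BaselineModel | dict | None = None,
) -> CavitationProbabilityMap:
    """CP per (pressure, fluence) cell.

    ``baseline`` is either one model for all stacks or a mapping keyed by
    ``(pressure_MPa,)`` series; a missing baseline is a configuration error.
    Stacks with role="baseline" and fluence 0 are used to fit per-series
    baselines when none is given.
    """
    if baseline is None:
        baseline = {}
        for s in stacks:
            if s.role == "baseline":
                baseline[s.pressure_MPa] = fit_baseline(s)
        if not baseline:
            raise ParameterError("no baseline model and no baseline-role stacks supplied")
    rows = []
    for s in stacks:
        if s.role == "baseline":
            continue
        b = baseline if isinstance(baseline, BaselineModel) else baseline.get(s.pressure_MPa)
        if b is None:
            raise ParameterError(f"no baseline for pressure {s.pressure_MPa} MPa series")
        rows.append(
            {
                "pressure_MPa": s.pressure_MPa,
                "fluence_mJcm2": s.fluence_mJ_cm2,
                "cp": cavitation_probability(s, b),
                "n_frames": s.n_frames,
            }
        )
    return CavitationProbabilityMap(pd.DataFrame(rows))


def load_stack(
    path: str | Path,
    pressure_MPa: float | None = None,
    fluence_mJ_cm2: float | None = None,
    role: str = "test",
) -> FrameStack:
    """Read a multi-page TIFF (or a directory of single-page TIFFs) stack."""
    import tifffile

    path = Path(path)
    if path.is_dir():
        pages = [tifffile.imread(p) for p in sorted(path.glob("*.tif*"))]
        if not pages:
            raise InputError(f"no TIFF pages in {path}")
        frames = np.stack(pages)
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    return FrameStack(
        frames=np.asarray(frames, dtype=float),
        pressure_MPa=pressure_MPa,
        fluence_mJ_cm2=fluence_mJ_cm2,
        role=role,
    )


def stack_report(stack: FrameStack, baseline: BaselineModel) -> dict:
    """JSON-serializable per-stack detection summary."""
    flagged = flagged_frames(stack, baseline)
    return {
        "pressure_MPa": stack.pressure_MPa,
        "fluence_mJcm2": stack.fluence_mJ_cm2,
        "cp": float(flagged.size) / stack.n_frames,
        "flagged_frames": flagged.tolist(),
        "n_frames": stack.n_frames,
        "n_pixels": int(np.prod(stack.frame_shape)),
        "k": baseline.k,
    }


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
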