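"""Speckle-variance OCT angiography and vessel-density quantification.

Flow decorrelates OCT speckle between repeated B-scans at the same position,
while static tissue speckle does not; the per-pixel temporal variance across
N_rep repeats (population convention, divide by N_rep) is therefore an
angiography contrast.  Vessel density is the mean OCT-A value inside an axial
depth gate (150–300 µm in the treatment study), treatment effect is the
percent reduction relative to the untreated control, and treated/untreated
group differences are assessed with a paired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pa_source import ParameterError

__all__ = [
    "OctScanSeries",
    "OctaImage",
    "VesselDensityResult",
    "PairedTestResult",
    "speckle_variance",
    "vessel_density",
    "percent_reduction",
    "paired_compare",
]


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class OctScanSeries:
    """Repeated B-scans: (position, repeat, depth, lateral) intensity array."""

    volumes: np.ndarray
    lateral_extent_mm: tuple = (8.0, 8.0)
    axial_pitch_um: float = 3.0
    region_id: str = ""
    side: str = "top"  # "top" | "bottom"
    timepoint: str = "pre"  # "pre" | "day1" | "day7"
    arm: str = "untreated"  # "treated" | "untreated"

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes)
        if v.ndim != 4:
            raise InputError("volumes must be (position, repeat, depth, lateral)")
        if v.shape[1] < 2:
            raise InputError("need at least 2 repeats per position for speckle variance")
        if self.axial_pitch_um <= 0:
            raise ParameterError("axial pitch must be positive")

    @property
    def n_repeats(self) -> int:
        return self.volumes.shape[1]

    @property
    def depth_px(self) -> int:
        return self.volumes.shape[2]


@dataclass(frozen=True)
class OctaImage:
    """Per-(position, depth, lateral) speckle-variance values."""

    variance: np.ndarray
    axial_pitch_um: float
    n_repeats: int
    meta: dict = field(default_factory=dict)

    def depth_gate_slice(self, gate_um: tuple) -> slice:
        lo_um, hi_um = gate_um
        if hi_um <= lo_um:
            raise ParameterError("depth gate must have positive extent")
        lo = int(math.floor(lo_um / self.axial_pitch_um))
        hi = int(math.ceil(hi_um / self.axial_pitch_um))
        lo = max(lo, 0)
        hi = min(hi, self.variance.shape[1])
        if hi <= lo:
            raise ParameterError(
                f"depth gate {gate_um} µm is outside the scan "
                f"(0–{self.variance.shape[1] * self.axial_pitch_um:.0f} µm)"
            )
        return slice(lo, hi)


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    p_value: float
    n: int
    mean_difference: float
    degenerate: bool = False
    note: str = ""


@dataclass(frozen=True)
class VesselDensityResult:
    """Tidy densities with normalized values, reductions and paired test."""

    table: pd.DataFrame  # region_id, side, timepoint, arm, density, normalized_density
    reductions: pd.DataFrame  # side, timepoint, percent_reduction
    tests: dict  # (side, timepoint) -> PairedTestResult


def speckle_variance(series: OctScanSeries) -> OctaImage:
    """Per-pixel variance across repeats (population convention, ÷ N_rep)."""
    v = np.asarray(series.volumes, dtype=float)
    var = v.var(axis=1, ddof=0)
    return OctaImage(
        variance=var,
        axial_pitch_um=series.axial_pitch_um,
        n_repeats=series.n_repeats,
        meta={
            "variance_convention": "population",
            "region_id": series.region_id,
            "side": series.side,
            "timepoint": series.timepoint,
            "arm": series.arm,
        },
    )


def vessel_density(
    octa: OctaImage,
    depth_gate_um: tuple = (150.0, 300.0),
    *,
    binarize: bool = False,
) -> float:
    """Area-normalized OCT-A intensity inside the depth gate.

    Default is the raw-variance mean (total OCT-A signal over gated pixel
    count); ``binarize`` applies an Otsu threshold to the gated slab first and
    returns the suprathreshold areal fraction (sensitivity analysis only).
    """
    gate = octa.depth_gate_slice(depth_gate_um)
    slab = octa.variance[:, gate, :]
    if slab.size == 0:
        raise ParameterError("empty depth gate")
    if binarize:
        from .cavitation_detect import _otsu

        return float(np.mean(slab > _otsu(slab)))
    return float(slab.mean())


def percent_reduction(treated_density: float, untreated_density: float) -> float:
    """(1 − treated/untreated) × 100."""
    if untreated_density <= 0:
        raise ParameterError("untreated (reference) density must be positive")
    return (1.0 - treated_density / untreated_density) * 100.0


def paired_compare(group_a, group_b) -> PairedTestResult:
    """Paired t-test on equal-length samples, computed from the differences.

    t = d̄ / (s_d / √n) with n−1 degrees of freedom.  All-zero differences
    give t = 0, p = 1; zero-variance non-zero differences are reported as a
    degenerate case instead of a silent infinity.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired groups must be equal-length 1-D samples")
    n = a.size
    if n < 2:
        raise InputError("paired test needs n ≥ 2")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTestResult(0.0, 1.0, n, 0.0, degenerate=False, note="identical groups")
        return PairedTestResult(
            math.nan,
            math.nan,
            n,
            mean_d,
            degenerate=True,
            note="zero-variance non-zero differences; t undefined",
        )
    t = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t, float(p), n, mean_d)


def quantify_series(
    series_list: list[OctScanSeries],
    depth_gate_um: tuple = (150.0, 300.0),
    *,
    binarize: bool = False,
) -> VesselDensityResult:
    """Densities, normalization and reductions for a set of labelled series.

    Normalized density divides each measurement by the mean untreated density
    at the same (side, timepoint); percent reduction compares treated vs
    untreated means per (side, timepoint); the paired test pairs treated and
    untreated measurements by region where both arms exist, else compares the
    per-cell samples pairwise-truncated.
    """
    rows = []
    for s in series_list:
        octa = speckle_variance(s)
        rows.append(
            {
                "region_id": s.region_id,
                "side": s.side,
                "timepoint": s.timepoint,
                "arm": s.arm,
                "density": vessel_density(octa, depth_gate_um, binarize=binarize),
            }
        )
    table = pd.DataFrame(rows)
    norm = []
    for _, r in table.iterrows():
        ref = table[
            (table.side == r.side) & (table.timepoint == r.timepoint) & (table.arm == "untreated")
        ].density.mean()
        norm.append(r.density / ref if ref and ref > 0 else math.nan)
    table = table.assign(normalized_density=norm)

    red_rows, tests = [], {}
    for (side, tp), grp in table.groupby(["side", "timepoint"]):
        tr = grp[grp.arm == "treated"].density
        un = grp[grp.arm == "untreated"].density
        if len(tr) and len(un):
            red_rows.append(
                {
                    "side": side,
                    "timepoint": tp,
                    "percent_reduction": percent_reduction(tr.mean(), un.mean()),
                }
            )
            m = min(len(tr), len(un))
            if m >= 2:
                tests[(side, tp)] = paired_compare(tr.to_numpy()[:m], un.to_numpy()[:m])
    return VesselDensityResult(table, pd.DataFrame(red_rows), tests)
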