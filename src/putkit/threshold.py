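"""Rectified-diffusion cavitation thresholds and grow/dissolve regime maps.

The threshold pressure at a given light fluence and initial bubble radius is
found by bisection on the drive peak negative pressure over full bubble-
dynamics simulations: each candidate builds the combined drive (ultrasound
burst with the photoacoustic transient placed on a mid-burst rarefaction
peak), integrates the Keller–Miksis equation, and classifies the fate by the
sign of the cycle-averaged rectified-diffusion flux.  Higher fluence gives a
larger photoacoustic kick, so the threshold is non-increasing in fluence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .bubble import Fate, MediumProperties, SolverOptions, classify_fate, simulate
from .field import DriveWaveform, make_burst, rarefaction_delay, synchronize
from .pa_source import OpticalPulse, ParameterError, VesselAbsorber, pa_waveform

__all__ = [
    "DriveProtocol",
    "ThresholdResult",
    "ThresholdCurve",
    "RegimeMap",
    "standard_drive",
    "threshold_pressure",
    "threshold_curve",
    "regime_map",
]


@dataclass(frozen=True)
class DriveProtocol:
    """Drive-construction recipe shared by every cell of a study.

    100 drive cycles (shorter than the experimental 500-cycle burst, chosen
    for tractable fate evaluation; label stability versus 500 cycles is
    exercised in the test suite) at 0.25 MHz, 1 ns sampling, PA pulse on the
    rarefaction peak of the middle cycle.
    """

    frequency_MHz: float = 0.25
    cycles: int = 100
    prf_Hz: float = 10.0
    time_step_ns: float = 1.0
    sync_cycle: int | None = None  # None → mid-burst
    vessel: VesselAbsorber = dc_field(default_factory=VesselAbsorber)
    pulse: OpticalPulse = dc_field(default_factory=OpticalPulse)

    def build(self, pnp_MPa: float, fluence_mJ_cm2: float) -> DriveWaveform:
        burst = make_burst(
            self.frequency_MHz, pnp_MPa, self.cycles, self.prf_Hz, self.time_step_ns
        )
        pa = pa_waveform(self.vessel, self.pulse, fluence_mJ_cm2)
        delay = rarefaction_delay(burst, pa, self.sync_cycle)
        return synchronize(burst, pa, delay)


def standard_drive(
    pnp_MPa: float,
    fluence_mJ_cm2: float,
    protocol: DriveProtocol | None = None,
) -> DriveWaveform:
    """Combined drive at the given PNP and fluence under a protocol's recipe."""
    return (protocol or DriveProtocol()).build(pnp_MPa, fluence_mJ_cm2)


@dataclass(frozen=True)
class ThresholdResult:
    """Bisection outcome for one (fluence, R0) pair."""

    pressure_MPa: float | None  # None when out of range
    bracket_MPa: tuple
    fluence_mJ_cm2: float
    initial_radius_m: float
    n_evaluations: int
    fates: tuple  # (fate at bracket low, fate at bracket high)

    @property
    def out_of_range(self) -> bool:
        return self.pressure_MPa is None


@dataclass(frozen=True)
class ThresholdCurve:
    """Threshold PNP over an (R0, fluence) grid; NaN marks out-of-range cells."""

    initial_radii_m: np.ndarray
    fluences_mJ_cm2: np.ndarray
    pressures_MPa: np.ndarray  # shape (n_R0, n_fluence)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r0 in enumerate(self.initial_radii_m):
            for j, f in enumerate(self.fluences_mJ_cm2):
                rows.append(
                    {
                        "R0_nm": r0 * 1e9,
                        "fluence_mJcm2": f,
                        "threshold_MPa": self.pressures_MPa[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegimeMap:
    """Fate label per (pressure, fluence) cell at fixed R0."""

    pressures_MPa: np.ndarray
    fluences_mJ_cm2: np.ndarray
    fates: np.ndarray  # dtype=object of Fate, shape (n_pressure, n_fluence)
    initial_radius_m: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.pressures_MPa):
            for j, f in enumerate(self.fluences_mJ_cm2):
                rows.append(
                    {
                        "pressure_MPa": p,
                        "fluence_mJcm2": f,
                        "fate": self.fates[i, j].value,
                    }
                )
        return pd.DataFrame(rows)

    def boundary_pressure(self, fluence_index: int) -> float:
        """Lowest grid pressure whose fate is growth at the given fluence."""
        col = self.fates[:, fluence_index]
        for i, fate in enumerate(col):
            if fate in (Fate.GROW, Fate.PERIOD_DOUBLED_GROWTH):
                return float(self.pressures_MPa[i])
        return math.nan


def _fate_at(
    pnp: float,
    fluence: float,
    R0: float,
    medium: MediumProperties,
    protocol: DriveProtocol,
    options: SolverOptions,
) -> Fate:
    drive = protocol.build(pnp, fluence)
    traj = simulate(drive, R0, medium, options)
    return classify_fate(traj, medium)


def _grows(fate: Fate) -> bool:
    return fate in (Fate.GROW, Fate.PERIOD_DOUBLED_GROWTH)


def threshold_pressure(
    fluence_mJ_cm2: float,
    R0: float,
    medium: MediumProperties | None = None,
    *,
    tolerance_MPa: float = 0.01,
    p_max_MPa: float = 1.5,
    protocol: DriveProtocol | None = None,
    options: SolverOptions | None = None,
) -> ThresholdResult:
    """Bisection on drive PNP until the grow/dissolve bracket ≤ ``tolerance_MPa``.

    Returns the bracket midpoint; when both bracket ends share a fate the
    result is flagged out-of-range rather than raising.
    """
    if tolerance_MPa <= 0:
        raise ParameterError("tolerance must be positive")
    medium = medium or MediumProperties()
    protocol = protocol or DriveProtocol()
    options = options or SolverOptions()

    lo, hi = 0.0, p_max_MPa
    fate_lo = _fate_at(lo, fluence_mJ_cm2, R0, medium, protocol, options)
    fate_hi = _fate_at(hi, fluence_mJ_cm2, R0, medium, protocol, options)
    n_eval = 2
    if _grows(fate_lo):
        return ThresholdResult(0.0, (lo, lo), fluence_mJ_cm2, R0, n_eval, (fate_lo, fate_hi))
    if not _grows(fate_hi):
        return ThresholdResult(None, (lo, hi), fluence_mJ_cm2, R0, n_eval, (fate_lo, fate_hi))

    while hi - lo > tolerance_MPa:
        mid = 0.5 * (lo + hi)
        fate_mid = _fate_at(mid, fluence_mJ_cm2, R0, medium, protocol, options)
        n_eval += 1
        if _grows(fate_mid):
            hi, fate_hi = mid, fate_mid
        else:
            lo, fate_lo = mid, fate_mid
    return ThresholdResult(
        0.5 * (lo + hi), (lo, hi), fluence_mJ_cm2, R0, n_eval, (fate_lo, fate_hi)
    )


def threshold_curve(
    initial_radii_m,
    fluences_mJ_cm2,
    medium: MediumProperties | None = None,
    **kwargs,
) -> ThresholdCurve:
    """Element-wise :func:`threshold_pressure` over the given grids."""
    radii = np.atleast_1d(np.asarray(initial_radii_m, dtype=float))
    fluences = np.atleast_1d(np.asarray(fluences_mJ_cm2, dtype=float))
    if radii.size == 0 or fluences.size == 0:
        raise ParameterError("grids must be non-empty")
    out = np.full((radii.size, fluences.size), np.nan)
    for i, r0 in enumerate(radii):
        for j, f in enumerate(fluences):
            res = threshold_pressure(f, r0, medium, **kwargs)
            if not res.out_of_range:
                out[i, j] = res.pressure_MPa
    return ThresholdCurve(radii, fluences, out)


def regime_map(
    pressures_MPa,
    fluences_mJ_cm2,
    R0: float = 100e-9,
    medium: MediumProperties | None = None,
    *,
    protocol: DriveProtocol | None = None,
    options: SolverOptions | None = None,
) -> RegimeMap:
    """Fate label for every (PNP, fluence) grid cell at fixed R0."""
    medium = medium or MediumProperties()
    protocol = protocol or DriveProtocol()
    options = options or SolverOptions()
    pressures = np.atleast_1d(np.asarray(pressures_MPa, dtype=float))
    fluences = np.atleast_1d(np.asarray(fluences_mJ_cm2, dtype=float))
    fates = np.empty((pressures.size, fluences.size), dtype=object)
    for i, p in enumerate(pressures):
        for j, f in enumerate(fluences):
            fates[i, j] = _fate_at(p, f, R0, medium, protocol, options)
    return RegimeMap(pressures, fluences, fates, R0)
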