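"""Single-bubble dynamics, rectified-diffusion mass flux and fate labels.

The governing equation is the Keller–Miksis form (first-order liquid
compressibility) with a polytropic gas interior, van der Waals hard core,
surface tension and Newtonian viscosity.  Gas exchange is decoupled from the
radial dynamics within a burst: the cycle-averaged rectified-diffusion flux is
evaluated on the finished trajectory with the Eller–Flynn high-frequency
approximation, and its sign decides whether the bubble grows (net gas influx)
or dissolves.  A growing bubble whose radius spectrum carries a subharmonic at
half the drive frequency is labelled period-doubled growth.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from ._kmcore import OK, RUNAWAY, STEP_FLOOR, integrate_km
from .field import DriveWaveform
from .pa_source import ParameterError

__all__ = [
    "MediumProperties",
    "SolverOptions",
    "BubbleTrajectory",
    "Fate",
    "simulate",
    "mass_flux",
    "classify_fate",
    "subharmonic_ratio",
    "IntegrationError",
    "WindowingError",
    "ClassificationError",
]


class IntegrationError(RuntimeError):
    """Solver failed to produce a usable trajectory."""


class WindowingError(ValueError):
    """Trajectory does not cover the requested steady-state window."""


class ClassificationError(ValueError):
    """Fate cannot be assigned (e.g. drive without a defined period)."""


class Fate(enum.Enum):
    DISSOLVE = "dissolve"
    GROW = "grow"
    PERIOD_DOUBLED_GROWTH = "period_doubled_growth"


@dataclass(frozen=True)
class MediumProperties:
    """Liquid and dissolved-gas properties (SI units).

    Defaults describe the blood/water-like medium used throughout: density
    1000 kg/m³, an effective viscosity of 2 mPa·s (between water and
    high-shear whole blood; bubble-wall shear rates are extreme and blood is
    strongly shear-thinning), clean-interface surface tension 0.072 N/m,
    adiabatic air (κ = 1.4), air-saturated liquid.
    """

    density: float = 1000.0  # kg/m³
    viscosity: float = 0.002  # Pa·s
    surface_tension: float = 0.072  # N/m
    ambient_pressure: float = 101325.0  # Pa
    vapor_pressure: float = 2339.0  # Pa
    polytropic_exponent: float = 1.4
    sound_speed: float = 1500.0  # m/s
    gas_diffusivity: float = 2.0e-9  # m²/s
    gas_saturation_ratio: float = 1.0  # C_i / C_0
    saturation_concentration: float = 0.85  # mol/m³, air in water at p∞

    def __post_init__(self) -> None:
        for name in (
            "density",
            "viscosity",
            "ambient_pressure",
            "polytropic_exponent",
            "sound_speed",
            "gas_diffusivity",
            "saturation_concentration",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.surface_tension < 0 or self.vapor_pressure < 0:
            raise ParameterError("surface tension and vapor pressure must be non-negative")
        if not 0.0 < self.gas_saturation_ratio <= 1.5:
            raise ParameterError("gas saturation ratio must lie in (0, 1.5]")

    def equilibrium_gas_pressure(self, R0: float) -> float:
        """Gas pressure balancing ambient + Laplace pressure at radius R0."""
        return self.ambient_pressure - self.vapor_pressure + 2.0 * self.surface_tension / R0


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls for :func:`simulate`."""

    rtol: float = 1.0e-6
    atol_radius: float = 1.0e-13  # m
    atol_velocity: float = 1.0e-3  # m/s
    samples_per_cycle: int = 128
    max_steps: int = 200_000_000
    hard_core_ratio: float = 8.86  # R0 / hard-core radius (van der Waals)
    runaway_radius: float = 1.0e-3  # m; growth beyond this is unambiguous

    def refined(self, factor: float = 0.5) -> "SolverOptions":
        """Copy with tolerances scaled by ``factor`` (for convergence checks)."""
        return replace(self, rtol=self.rtol * factor, atol_radius=self.atol_radius * factor)


@dataclass(frozen=True)
class BubbleTrajectory:
    """R(t) solution with solver diagnostics.

    ``status`` 0: clean; 2: the radius hit the runaway cap (the remaining
    samples hold the last state — unambiguous growth); 1: the stepper was
    forced to its floor at some point.
    """

    time_s: np.ndarray
    radius_m: np.ndarray
    velocity_m_s: np.ndarray
    initial_radius_m: float
    drive_frequency_Hz: float | None
    status: int
    n_steps: int

    @property
    def ratio(self) -> np.ndarray:
        """R(t)/R0."""
        return self.radius_m / self.initial_radius_m

    @property
    def runaway(self) -> bool:
        return self.status == RUNAWAY

    def steady_window(self, discard_fraction: float = 0.25) -> np.ndarray:
        """Boolean mask selecting the steady-state portion of the trajectory."""
        t0 = self.time_s[0] + discard_fraction * (self.time_s[-1] - self.time_s[0])
        return self.time_s >= t0


def simulate(
    drive: DriveWaveform,
    R0: float,
    medium: MediumProperties | None = None,
    options: SolverOptions | None = None,
    *,
    r_init_ratio: float = 1.0,
    v_init: float = 0.0,
) -> BubbleTrajectory:
    """Integrate the Keller–Miksis equation under a sampled drive waveform.

    The bubble starts at ``r_init_ratio``·R0 with wall velocity ``v_init``;
    its gas content is set by pressure equilibrium at R0, so the default start
    is an equilibrium state.  Output is sampled on a uniform grid of
    ``options.samples_per_cycle`` points per drive cycle.
    """
    if R0 <= 0:
        raise ParameterError("R0 must be positive")
    medium = medium or MediumProperties()
    options = options or SolverOptions()

    t_s = drive.time_us * 1e-6
    p_pa = drive.pressure_MPa * 1e6
    dt_s = float(t_s[1] - t_s[0])
    grad = np.gradient(p_pa, dt_s)

    span = float(t_s[-1])
    n_cycles = max(drive.cycles_per_burst, 1)
    n_out = int(n_cycles * options.samples_per_cycle) + 1
    t_out = np.linspace(0.0, span, n_out)

    R_out, V_out, status, n_steps = integrate_km(
        t_out,
        dt_s,
        p_pa,
        grad,
        R0 * r_init_ratio,
        v_init,
        R0,
        medium.density,
        medium.viscosity,
        medium.surface_tension,
        medium.ambient_pressure,
        medium.vapor_pressure,
        medium.polytropic_exponent,
        medium.sound_speed,
        options.hard_core_ratio,
        options.rtol,
        options.atol_radius,
        options.atol_velocity,
        options.max_steps,
        options.runaway_radius,
    )
    if not np.all(np.isfinite(R_out)):
        raise IntegrationError(
            f"non-finite radius after {n_steps} steps (last t ≈ {t_out[-1]:.3e} s)"
        )
    freq = drive.center_frequency_MHz * 1e6 if drive.center_frequency_MHz > 0 else None
    return BubbleTrajectory(
        time_s=t_out,
        radius_m=R_out,
        velocity_m_s=V_out,
        initial_radius_m=R0,
        drive_frequency_Hz=freq,
        status=status,
        n_steps=n_steps,
    )


def mass_flux(
    trajectory: BubbleTrajectory,
    medium: MediumProperties,
    discard_fraction: float = 0.25,
    min_cycles: int = 2,
) -> float:
    """Cycle-averaged rectified-diffusion gas flux (mol/s), positive ⇒ growth.

    Eller–Flynn high-frequency approximation evaluated on the steady window:

        dn/dt = 4π·D·R0·C0·[ (Ci/C0)·⟨(R/R0)⁴⟩ − (1 + 2σ/(p∞·R0))·⟨R/R0⟩ ]

    The ⟨(R/R0)⁴⟩ term is the area- and concentration-stretching enhancement
    of influx during expansion; the ⟨R/R0⟩ term carries the Laplace-pressure
    driven efflux.  The classical growth threshold
    Ci/C0 = (1 + 2σ/(p∞R0))·⟨R/R0⟩/⟨(R/R0)⁴⟩ is the zero of this expression.
    """
    window = trajectory.steady_window(discard_fraction)
    if trajectory.drive_frequency_Hz is not None:
        t_win = trajectory.time_s[window]
        covered = (t_win[-1] - t_win[0]) * trajectory.drive_frequency_Hz
        if covered < min_cycles:
            raise WindowingError(
                f"steady window covers {covered:.2f} drive cycles; ≥ {min_cycles} required"
            )
    x = trajectory.ratio[window]
    mean_x = float(np.mean(x))
    mean_x4 = float(np.mean(x**4))
    R0 = trajectory.initial_radius_m
    sigma_term = 1.0 + 2.0 * medium.surface_tension / (medium.ambient_pressure * R0)
    return (
        4.0
        * math.pi
        * medium.gas_diffusivity
        * R0
        * medium.saturation_concentration
        * (medium.gas_saturation_ratio * mean_x4 - sigma_term * mean_x)
    )


def subharmonic_ratio(
    trajectory: BubbleTrajectory,
    discard_fraction: float = 0.25,
    bandwidth_fraction: float = 0.25,
) -> float:
    """Spectral amplitude near f_drive/2 relative to the one near f_drive.

    Hann-windowed magnitude spectrum of R(t)/R0 over the steady window; each
    line is taken as the maximum within ±``bandwidth_fraction``·(f/2) of its
    nominal frequency.  Returns 0 when the fundamental itself is negligible.
    """
    f = trajectory.drive_frequency_Hz
    if f is None:
        raise ClassificationError("drive has no defined period; cannot assess subharmonics")
    window = trajectory.steady_window(discard_fraction)
    x = trajectory.ratio[window]
    t = trajectory.time_s[window]
    if x.size < 16:
        raise WindowingError("steady window too short for spectral analysis")
    dt = float(t[1] - t[0])
    x = x - np.mean(x)
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size)))
    freqs = np.fft.rfftfreq(x.size, dt)

    def line(f0: float) -> float:
        half_bw = bandwidth_fraction * f / 2.0
        sel = (freqs >= f0 - half_bw) & (freqs <= f0 + half_bw)
        return float(np.max(spec[sel])) if np.any(sel) else 0.0

    fund = line(f)
    sub = line(f / 2.0)
    total = float(np.max(spec)) if spec.size else 0.0
    if fund <= 1e-12 * max(total, 1.0):
        return 0.0
    return sub / fund


def cycle_maxima(trajectory: BubbleTrajectory, discard_fraction: float = 0.25) -> np.ndarray:
    """Per-drive-cycle maxima of R/R0 over the steady window (PD cross-check)."""
    f = trajectory.drive_frequency_Hz
    if f is None:
        raise ClassificationError("drive has no defined period")
    window = trajectory.steady_window(discard_fraction)
    t = trajectory.time_s[window]
    x = trajectory.ratio[window]
    cyc = np.floor((t - t[0]) * f).astype(np.int64)
    out = np.zeros(int(cyc[-1]) + 1)
    np.maximum.at(out, cyc, x)
    return out[:-1] if cyc[-1] > 0 else out  # drop possibly partial last cycle


def classify_fate(
    trajectory: BubbleTrajectory,
    medium: MediumProperties,
    *,
    discard_fraction: float = 0.25,
    subharmonic_threshold: float = 0.10,
) -> Fate:
    """GROW if the cycle-averaged gas flux is positive, DISSOLVE otherwise;
    PERIOD_DOUBLED_GROWTH when growing with a subharmonic line at f/2
    exceeding ``subharmonic_threshold`` of the fundamental."""
    if trajectory.drive_frequency_Hz is None:
        raise ClassificationError("drive has no defined period; classification refused")
    if trajectory.runaway:
        # the radius passed the runaway cap: growth is unambiguous, but the
        # padded tail invalidates the spectrum
        return Fate.GROW
    flux = mass_flux(trajectory, medium, discard_fraction)
    if flux <= 0:
        return Fate.DISSOLVE
    if subharmonic_ratio(trajectory, discard_fraction) >= subharmonic_threshold:
        return Fate.PERIOD_DOUBLED_GROWTH
    return Fate.GROW
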