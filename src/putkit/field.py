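"""Ultrasound burst synthesis and laser/ultrasound synchronization.

Builds the sinusoidal therapy burst (0.25 MHz, 2 ms, 2 % duty cycle in the
treatment configuration), superimposes the photoacoustic transient at a
controlled delay onto a rarefaction phase, and expands the delay-to-depth
synchronization sweep used to cover vessels at different depths (500 ns of
extra delay per minute ≙ 0.75 mm of depth per minute at 1.5 mm/µs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pa_source import PAWaveform, ParameterError

__all__ = [
    "UltrasoundBurst",
    "SyncSchedule",
    "DriveWaveform",
    "make_burst",
    "synchronize",
    "rarefaction_delay",
    "delay_to_depth",
    "sweep_schedule",
]


@dataclass(frozen=True)
class UltrasoundBurst:
    """Sampled sinusoidal ultrasound burst.

    The pressure starts on the rarefaction half-cycle (p = -PNP·sin(2πft)),
    so rarefaction peaks fall at t = (k + 1/4)/f.
    """

    center_frequency_MHz: float
    peak_negative_MPa: float
    cycles_per_burst: int
    burst_repetition_Hz: float
    time_us: np.ndarray
    pressure_MPa: np.ndarray

    @property
    def burst_duration_us(self) -> float:
        return self.cycles_per_burst / self.center_frequency_MHz

    @property
    def duty_cycle(self) -> float:
        return self.burst_duration_us * 1e-6 * self.burst_repetition_Hz

    @property
    def dt_us(self) -> float:
        return float(self.time_us[1] - self.time_us[0])

    def rarefaction_peak_time_us(self, cycle: int) -> float:
        """Time of the rarefaction peak of the given (0-based) cycle."""
        if not 0 <= cycle < self.cycles_per_burst:
            raise ParameterError("cycle index outside burst")
        return (cycle + 0.25) / self.center_frequency_MHz


@dataclass(frozen=True)
class SyncSchedule:
    """Stepwise laser-trigger delay schedule over a treatment session."""

    base_delay_ns: float
    step_ns: float
    step_interval_s: float
    total_duration_s: float
    sound_speed_mm_us: float = 1.5

    windows: tuple = field(default_factory=tuple)  # (t_start_s, t_end_s, delay_ns, depth_mm)


@dataclass(frozen=True)
class DriveWaveform:
    """Combined drive: ultrasound burst with the PA pulse added at a delay."""

    time_us: np.ndarray
    pressure_MPa: np.ndarray
    center_frequency_MHz: float
    cycles_per_burst: int
    pa_delay_us: float
    pa_peak_MPa: float

    @property
    def dt_us(self) -> float:
        return float(self.time_us[1] - self.time_us[0])

    @property
    def peak_negative_MPa(self) -> float:
        """Peak rarefaction amplitude of the combined waveform (positive number)."""
        return float(-np.min(self.pressure_MPa))

    @property
    def burst_duration_us(self) -> float:
        return self.cycles_per_burst / self.center_frequency_MHz


def make_burst(
    frequency_MHz: float,
    pnp_MPa: float,
    cycles: int,
    prf_Hz: float,
    time_step_ns: float = 1.0,
) -> UltrasoundBurst:
    """Sinusoidal burst with the stated peak negative pressure.

    500 cycles at 0.25 MHz and 10 Hz repetition give the treatment's 2 ms
    burst and 2 % duty cycle.
    """
    if frequency_MHz <= 0 or pnp_MPa < 0 or cycles <= 0 or prf_Hz <= 0:
        raise ParameterError("frequency, PNP, cycle count and PRF must be positive")
    if time_step_ns <= 0:
        raise ParameterError("time step must be positive")
    duration_us = cycles / frequency_MHz
    duty = duration_us * 1e-6 * prf_Hz
    if duty > 1.0:
        raise ParameterError(f"duty cycle {duty:.2%} exceeds 100 %")
    dt_us = time_step_ns * 1e-3
    n = int(round(duration_us / dt_us)) + 1
    t = np.arange(n) * dt_us
    p = -pnp_MPa * np.sin(2.0 * math.pi * frequency_MHz * t)
    return UltrasoundBurst(
        center_frequency_MHz=frequency_MHz,
        peak_negative_MPa=pnp_MPa,
        cycles_per_burst=cycles,
        burst_repetition_Hz=prf_Hz,
        time_us=t,
        pressure_MPa=p,
    )


def synchronize(burst: UltrasoundBurst, pa: PAWaveform, delay_us: float) -> DriveWaveform:
    """Add the PA transient to the burst, its t = 0 sample landing at ``delay_us``.

    The PA samples are linearly interpolated onto the burst grid; the
    operation is additive in the PA waveform.
    """
    if not 0.0 <= delay_us <= burst.burst_duration_us:
        raise ParameterError(
            f"delay {delay_us} µs outside burst (0..{burst.burst_duration_us} µs)"
        )
    t = burst.time_us
    pa_t_us = pa.time_ns * 1e-3 + delay_us
    added = np.interp(t, pa_t_us, pa.pressure_MPa, left=0.0, right=0.0)
    return DriveWaveform(
        time_us=t,
        pressure_MPa=burst.pressure_MPa + added,
        center_frequency_MHz=burst.center_frequency_MHz,
        cycles_per_burst=burst.cycles_per_burst,
        pa_delay_us=delay_us,
        pa_peak_MPa=pa.peak_amplitude_MPa,
    )


def rarefaction_delay(burst: UltrasoundBurst, pa: PAWaveform, cycle: int | None = None) -> float:
    """Delay (µs) placing the PA tension peak on a burst rarefaction peak.

    ``cycle`` defaults to a mid-burst cycle (steady-state placement).
    """
    if cycle is None:
        cycle = burst.cycles_per_burst // 2
    return burst.rarefaction_peak_time_us(cycle) - pa.tension_peak_time_ns * 1e-3


def delay_to_depth(delay_ns: float, sound_speed_mm_us: float = 1.5) -> float:
    """Synchronization depth (mm) = delay × sound speed (500 ns → 0.75 mm)."""
    if delay_ns < 0:
        raise ParameterError("delay must be non-negative")
    return delay_ns * 1e-3 * sound_speed_mm_us


def sweep_schedule(
    base_delay_ns: float,
    step_ns: float,
    interval_s: float,
    total_s: float,
    sound_speed_mm_us: float = 1.5,
) -> SyncSchedule:
    """Expand the per-interval delay sweep into (window, delay, depth) entries.

    The treatment sweep (0 ns base, 500 ns step, 60 s interval, 240 s total)
    yields four windows at depths 0, 0.75, 1.5 and 2.25 mm.
    """
    if interval_s <= 0:
        raise ParameterError("step interval must be positive")
    if total_s < interval_s:
        raise ParameterError("total duration must cover at least one interval")
    if base_delay_ns < 0 or step_ns < 0:
        raise ParameterError("delays must be non-negative and non-decreasing")
    n = int(math.ceil(total_s / interval_s - 1e-12))
    windows = []
    for k in range(n):
        t0 = k * interval_s
        t1 = min((k + 1) * interval_s, total_s)
        delay = base_delay_ns + k * step_ns
        windows.append((t0, t1, delay, delay_to_depth(delay, sound_speed_mm_us)))
    return SyncSchedule(
        base_delay_ns=base_delay_ns,
        step_ns=step_ns,
        step_interval_s=interval_s,
        total_duration_s=total_s,
        sound_speed_mm_us=sound_speed_mm_us,
        windows=tuple(windows),
    )
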