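"""Bubble dynamics: analytic oracles, rectified-diffusion flux, fate labels."""

import math

import numpy as np
import pytest

from conftest import synthetic_trajectory
from putkit.bubble import (
    ClassificationError,
    Fate,
    MediumProperties,
    SolverOptions,
    WindowingError,
    classify_fate,
    cycle_maxima,
    mass_flux,
    simulate,
    subharmonic_ratio,
)
from putkit.field import make_burst
from putkit.threshold import DriveProtocol

R0_TREAT = 100e-9


def _zero_drive(span_us: float, samples_per_cycle: int = 4096):
    """Quiescent drive covering ``span_us`` (one 'cycle' = the whole span)."""
    return make_burst(1.0 / span_us, 0.0, 1, 1.0, time_step_ns=span_us)


def test_equilibrium_bubble_holds_radius(medium):
    """An undriven bubble at gas equilibrium stays at R0 (drift < 1e-6)."""
    drive = make_burst(0.25, 0.0, 10, 10.0)
    traj = simulate(drive, R0_TREAT, medium)
    assert np.max(np.abs(traj.ratio - 1.0)) < 1e-6


def test_linear_response_matches_oscillator_closed_form():
    """A 1 kPa drive far below resonance reproduces the linearized amplitude.

    Linearizing the radial equation about R0 gives
    ρR0²·ẍ + 4η·ẋ + k·x = −p_s(t),  k = 3κ·p_g0 − 2σ/R0,
    so the steady amplitude is P_A / √((k − ρR0²ω²)² + (4ηω)²).
    """
    medium = MediumProperties(viscosity=0.001)
    R0 = 5e-6
    freq_MHz = 0.05
    drive = make_burst(freq_MHz, 0.001, 30, 10.0, time_step_ns=4.0)
    traj = simulate(drive, R0, medium, SolverOptions(samples_per_cycle=256))
    window = traj.steady_window(0.5)
    measured = 0.5 * (traj.ratio[window].max() - traj.ratio[window].min())

    pg0 = medium.equilibrium_gas_pressure(R0)
    k = 3 * medium.polytropic_exponent * pg0 - 2 * medium.surface_tension / R0
    omega = 2 * math.pi * freq_MHz * 1e6
    expected = 1e3 / math.hypot(k - medium.density * R0**2 * omega**2, 4 * medium.viscosity * omega)
    assert measured == pytest.approx(expected, rel=0.05)


@pytest.mark.parametrize("R0", [1e-6, 3e-6, 10e-6])
def test_ringdown_matches_minnaert_with_surface_tension(R0):
    """Small-amplitude ringdown frequency vs the Minnaert formula within 5 %."""
    medium = MediumProperties(viscosity=0.001)
    pg0 = medium.equilibrium_gas_pressure(R0)
    k = 3 * medium.polytropic_exponent * pg0 - 2 * medium.surface_tension / R0
    f0 = math.sqrt(k / medium.density) / (2 * math.pi * R0)

    span_us = 30.0 / (f0 * 1e-6)  # 30 natural periods
    drive = _zero_drive(span_us)
    traj = simulate(
        drive, R0, medium, SolverOptions(samples_per_cycle=16384), r_init_ratio=1.02
    )
    x = traj.ratio - 1.0
    t = traj.time_s
    skip = x.size // 10
    x, t = x[skip:], t[skip:]
    crossings = np.nonzero(np.diff(np.signbit(x)))[0]
    assert crossings.size > 10
    t_first, t_last = t[crossings[0]], t[crossings[-1]]
    measured = (crossings.size - 1) / (2.0 * (t_last - t_first))
    assert measured == pytest.approx(f0, rel=0.05)


def test_rayleigh_collapse_time():
    """Collapse from rest at R_max under static p∞ vs 0.915·R_max·√(ρ/p∞)."""
    medium = MediumProperties(
        viscosity=1e-6, surface_tension=0.0, vapor_pressure=0.0
    )
    R0 = 2e-6
    ratio = 50.0  # gas pressure at R_max is ~(1/50)^4.2 of ambient: effectively empty
    t_rayleigh = 0.915 * (ratio * R0) * math.sqrt(medium.density / medium.ambient_pressure)
    span_us = 1.3 * t_rayleigh * 1e6
    drive = _zero_drive(span_us)
    traj = simulate(
        drive, R0, medium, SolverOptions(samples_per_cycle=16384), r_init_ratio=ratio
    )
    t_collapse = traj.time_s[int(np.argmin(traj.radius_m))]
    assert t_collapse == pytest.approx(t_rayleigh, rel=0.02)


class TestMassFlux:
    def test_undriven_bubble_dissolves_at_epstein_plesset_rate(self, medium):
        """Static Laplace-pressure dissolution: flux < 0 and equal to the
        quasi-static Epstein–Plesset rate 4πDR0C0(Ci/C0 − 1 − 2σ/(p∞R0))."""
        drive = make_burst(0.25, 0.0, 10, 10.0)
        traj = simulate(drive, R0_TREAT, medium)
        flux = mass_flux(traj, medium)
        ep = (
            4.0
            * math.pi
            * medium.gas_diffusivity
            * R0_TREAT
            * medium.saturation_concentration
            * (
                medium.gas_saturation_ratio
                - 1.0
                - 2.0 * medium.surface_tension / (medium.ambient_pressure * R0_TREAT)
            )
        )
        assert flux < 0
        assert flux == pytest.approx(ep, rel=0.01)

    def test_zero_surface_tension_saturated_is_neutral(self):
        medium = MediumProperties(surface_tension=0.0, gas_saturation_ratio=1.0)
        drive = make_burst(0.25, 0.0, 10, 10.0)
        traj = simulate(drive, R0_TREAT, medium)
        scale = 4 * math.pi * medium.gas_diffusivity * R0_TREAT * medium.saturation_concentration
        assert abs(mass_flux(traj, medium)) < 1e-6 * scale

    def test_short_trajectory_rejected(self, medium):
        drive = make_burst(0.25, 0.0, 2, 10.0)
        traj = simulate(drive, R0_TREAT, medium)
        with pytest.raises(WindowingError):
            mass_flux(traj, medium, min_cycles=4)


class TestSubharmonicDetector:
    def test_pure_fundamental_is_not_period_doubled(self):
        f = 1e6
        t = np.linspace(0, 64 / f, 64 * 64)
        x = 1.0 + 0.1 * np.sin(2 * math.pi * f * t)
        assert subharmonic_ratio(synthetic_trajectory(x, t, freq=f)) < 0.02

    def test_half_frequency_component_detected(self):
        f = 1e6
        t = np.linspace(0, 64 / f, 64 * 64)
        x = 1.0 + 0.1 * np.sin(2 * math.pi * f * t) + 0.05 * np.sin(math.pi * f * t)
        assert subharmonic_ratio(synthetic_trajectory(x, t, freq=f)) > 0.4

    def test_classification_refused_without_period(self, medium):
        t = np.linspace(0, 1e-4, 1000)
        traj = synthetic_trajectory(np.ones_like(t), t, freq=None)
        with pytest.raises(ClassificationError):
            classify_fate(traj, medium)


class TestFateLabels:
    """Reference treatment-parameter combinations (short bursts for speed)."""

    def _fate(self, pnp, fluence, medium, cycles=32, options=None):
        drive = DriveProtocol(cycles=cycles).build(pnp, fluence)
        traj = simulate(drive, R0_TREAT, medium, options)
        return classify_fate(traj, medium)

    def test_subthreshold_dissolves(self, medium):
        assert self._fate(0.6, 100.0, medium) is Fate.DISSOLVE

    def test_suprathreshold_grows(self, medium):
        assert self._fate(0.8, 120.0, medium) in (Fate.GROW, Fate.PERIOD_DOUBLED_GROWTH)

    def test_period_doubling_band(self, medium):
        """Just below the pure-ultrasound runaway threshold the PA-triggered
        oscillation locks into a period-2 orbit."""
        fate = self._fate(0.76, 120.0, medium, cycles=64)
        assert fate is Fate.PERIOD_DOUBLED_GROWTH
        drive = DriveProtocol(cycles=64).build(0.76, 120.0)
        traj = simulate(drive, R0_TREAT, medium)
        maxima = cycle_maxima(traj)
        odd, even = maxima[1::2], maxima[0::2][: maxima[1::2].size]
        alternation = np.abs(odd - even).mean() / maxima.mean()
        assert alternation > 0.05  # cycle-maxima alternation cross-check

    def test_fate_stable_under_tolerance_refinement(self, medium):
        """Halving solver tolerances must not flip labels at the printed combos."""
        tight = SolverOptions().refined(0.5)
        for pnp, fluence in [(0.6, 100.0), (0.8, 120.0), (1.0, 120.0)]:
            assert self._fate(pnp, fluence, medium, cycles=100) is self._fate(
                pnp, fluence, medium, cycles=100, options=tight
            )

    def test_fate_stable_at_experimental_burst_length(self, medium):
        """32-cycle labels match the experimental 500-cycle burst labels."""
        for pnp, fluence in [(0.6, 100.0), (0.8, 120.0)]:
            assert self._fate(pnp, fluence, medium, cycles=32) is self._fate(
                pnp, fluence, medium, cycles=500
            )


def test_radius_stays_positive_through_violent_collapse(medium):
    drive = DriveProtocol(cycles=32).build(1.0, 120.0)
    traj = simulate(drive, R0_TREAT, medium)
    assert np.all(traj.radius_m > 0)
    assert traj.ratio.max() > 10  # genuinely violent trajectory
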