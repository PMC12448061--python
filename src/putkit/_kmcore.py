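"""Compiled Keller–Miksis integrator.

Radial dynamics of a single spherical gas bubble with first-order liquid
compressibility (Keller–Miksis form), polytropic gas with a van der Waals
hard core, surface tension and Newtonian viscosity, driven by a sampled
far-field pressure waveform.

The stepper is an embedded Dormand–Prince 5(4) pair with PI-free standard
step control, written flat for numba.  Violent inertial collapses push wall
speeds toward the liquid sound speed; the compressibility factors are clamped
at |Ṙ|/c ≤ 0.95 on the expansion side to keep the equation regular, and the
hard core bounds gas compression.  Both guards are documented numerical
choices, not physics claims.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes
OK = 0
STEP_FLOOR = 1  # forced steps at the minimum step size (accuracy degraded)
RUNAWAY = 2  # radius exceeded the runaway cap; growth is unambiguous


@njit(cache=True, fastmath=False)
def _drive_at(t, dt, samples, grad):
    """Linear interpolation of the sampled drive and its time derivative."""
    n = samples.shape[0]
    x = t / dt
    i = int(x)
    if i < 0:
        return samples[0], 0.0
    if i >= n - 1:
        return samples[n - 1], 0.0
    w = x - i
    return samples[i] * (1.0 - w) + samples[i + 1] * w, grad[i] * (1.0 - w) + grad[i + 1] * w


@njit(cache=True, fastmath=False)
def _accel(t, R, V, dt_drv, p_drv, dp_drv, rho, eta, sigma, p_inf, p_v, kappa, c0, pg0, R0, h3):
    """Keller–Miksis radial acceleration R̈(t, R, Ṙ)."""
    ps, dps = _drive_at(t, dt_drv, p_drv, dp_drv)
    R3 = R * R * R
    pg = pg0 * ((R0 * R0 * R0 - h3) / (R3 - h3)) ** kappa
    pL = pg + p_v - 2.0 * sigma / R - 4.0 * eta * V / R
    # non-acceleration part of dpL/dt (the viscous R̈ term is folded into the
    # denominator below)
    dpg = -3.0 * kappa * pg * R * R * V / (R3 - h3)
    dpL = dpg + 2.0 * sigma * V / (R * R) + 4.0 * eta * V * V / (R * R)
    vc = V / c0
    if vc > 0.95:
        vc = 0.95
    num = (
        (1.0 + vc) * (pL - p_inf - ps) / rho
        + R * (dpL - dps) / (rho * c0)
        - 1.5 * V * V * (1.0 - vc / 3.0)
    )
    den = (1.0 - vc) * R + 4.0 * eta / (rho * c0)
    return num / den


@njit(cache=True, fastmath=False)
def integrate_km(
    t_out,
    dt_drv,
    p_drv,
    dp_drv,
    R_init,
    V_init,
    R0,
    rho,
    eta,
    sigma,
    p_inf,
    p_v,
    kappa,
    c0,
    hard_core_ratio,
    rtol,
    atol_R,
    atol_V,
    max_steps,
    runaway_R,
):
    """Integrate R(t), Ṙ(t) over ``t_out`` (uniform, starting at 0).

    Returns (R_out, V_out, status, n_steps).  Output samples are filled by
    linear interpolation across accepted steps.
    """
    n_out = t_out.shape[0]
    R_out = np.empty(n_out)
    V_out = np.empty(n_out)
    R_out[0] = R_init
    V_out[0] = V_init

    h_core = R0 / hard_core_ratio
    h3 = h_core * h_core * h_core
    pg0 = p_inf - p_v + 2.0 * sigma / R0

    # Dormand–Prince 5(4) tableau
    a21 = 1.0 / 5.0
    a31, a32 = 3.0 / 40.0, 9.0 / 40.0
    a41, a42, a43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
    a51, a52, a53, a54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
    a61, a62, a63, a64, a65 = (
        9017.0 / 3168.0,
        -355.0 / 33.0,
        46732.0 / 5247.0,
        49.0 / 176.0,
        -5103.0 / 18656.0,
    )
    b1, b3, b4, b5, b6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
    e1, e3, e4, e5, e6, e7 = (
        35.0 / 384.0 - 5179.0 / 57600.0,
        500.0 / 1113.0 - 7571.0 / 16695.0,
        125.0 / 192.0 - 393.0 / 640.0,
        -2187.0 / 6784.0 + 92097.0 / 339200.0,
        11.0 / 84.0 - 187.0 / 2100.0,
        -1.0 / 40.0,
    )
    c2, c3_, c4, c5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0

    t = t_out[0]
    t_end = t_out[n_out - 1]
    R = R_init
    V = V_init
    h = 1e-9
    h_min = 1e-17
    status = OK
    n_steps = 0
    i_out = 1
    floor_R = h_core * 1.0001

    kR1 = V
    kV1 = _accel(t, R, V, dt_drv, p_drv, dp_drv, rho, eta, sigma, p_inf, p_v, kappa, c0, pg0, R0, h3)

    while t < t_end and n_steps < max_steps:
        if h > t_end - t:
            h = t_end - t
        n_steps += 1

        R2 = R + h * a21 * kR1
        V2 = V + h * a21 * kV1
        if R2 < floor_R:
            R2 = floor_R
        kR2 = V2
        kV2 = _accel(t + c2 * h, R2, V2, dt_drv, p_drv, dp_drv, rho, eta, sigma, p_inf, p_v, kappa, c0, pg0, R0, h3)

        R3_ = R + h * (a31 * kR1 + a32 * kR2)
        V3 = V + h * (a31 * kV1 + a32 * kV2)
        if R3_ < floor_R:
            R3_ = floor_R
        kR3 = V3
        kV3 = _accel(t + c3_ * h, R3_, V3, dt_drv, p_drv, dp_drv, rho, eta, sigma, p_inf, p_v, kappa, c0, pg0, R0, h3)

        R4 = R + h * (a41 * kR1 + a42 * kR2 + a43 * kR3)
        V4 = V + h * (a41 * kV1 + a42 * kV2 + a43 * kV3)
        if R4 < floor_R:
            R4 = floor_R
        kR4 = V4
        kV4 = _accel(t + c4 * h, R4, V4, dt_drv, p_drv, dp_drv, rho, eta, sigma, p_inf, p_v, kappa, c0, pg0, R0, h3)

        R5 = R + h * (a51 * kR1 + a52 * kR2 + a53 * kR3 + a54 * kR4)
        V5 = V + h * (a51 * kV1 + a52 * kV2 + a53 * kV3 + a54 * kV4)
        if R5 < floor_R:
            R5 = floor_R
        kR5 = V5
        kV5 = _accel(t + c5 * h, R5, V5, dt_drv, p_drv, dp_drv, rho, eta, sigma, p_inf, p_v, kappa, c0, pg0, R0, h3)

        R6 = R + h * (a61 * kR1 + a62 * kR2 + a63 * kR3 + a64 * kR4 + a65 * kR5)
        V6 = V + h * (a61 * kV1 + a62 * kV2 + a63 * kV3 + a64 * kV4 + a65 * kV5)
        if R6 < floor_R:
            R6 = floor_R
        kR6 = V6
        kV6 = _accel(t + h, R6, V6, dt_drv, p_drv, dp_drv, rho, eta, sigma, p_inf, p_v, kappa, c0, pg0, R0, h3)

        R_new = R + h * (b1 * kR1 + b3 * kR3 + b4 * kR4 + b5 * kR5 + b6 * kR6)
        V_new = V + h * (b1 * kV1 + b3 * kV3 + b4 * kV4 + b5 * kV5 + b6 * kV6)
        bad = not (np.isfinite(R_new) and np.isfinite(V_new)) or R_new < floor_R

        if bad:
            err_norm = 2.0
            kR7 = 0.0
            kV7 = 0.0
        else:
            kR7 = V_new
            kV7 = _accel(t + h, R_new, V_new, dt_drv, p_drv, dp_drv, rho, eta, sigma, p_inf, p_v, kappa, c0, pg0, R0, h3)
            errR = h * (e1 * kR1 + e3 * kR3 + e4 * kR4 + e5 * kR5 + e6 * kR6 + e7 * kR7)
            errV = h * (e1 * kV1 + e3 * kV3 + e4 * kV4 + e5 * kV5 + e6 * kV6 + e7 * kV7)
            sR = atol_R + rtol * max(abs(R), abs(R_new))
            sV = atol_V + rtol * max(abs(V), abs(V_new))
            err_norm = np.sqrt(0.5 * ((errR / sR) ** 2 + (errV / sV) ** 2))
            if not np.isfinite(err_norm):
                err_norm = 2.0

        if err_norm <= 1.0 or h <= h_min:
            if h <= h_min and err_norm > 1.0:
                status = STEP_FLOOR
                if bad:  # clamp to keep the state finite
                    R_new = max(R, floor_R)
                    V_new = 0.0
                    kR7 = V_new
                    kV7 = kV1
            t_new = t + h
            # fill output samples crossed by this step (linear interpolation)
            while i_out < n_out and t_out[i_out] <= t_new:
                w = (t_out[i_out] - t) / (t_new - t) if t_new > t else 1.0
                R_out[i_out] = R + w * (R_new - R)
                V_out[i_out] = V + w * (V_new - V)
                i_out += 1
            t = t_new
            R = R_new
            V = V_new
            kR1 = kR7  # FSAL
            kV1 = kV7
            if R > runaway_R:
                status = RUNAWAY
                break
            fac = 0.9 * err_norm ** -0.2 if err_norm > 1e-10 else 5.0
            if fac > 5.0:
                fac = 5.0
            h = h * fac
        else:
            fac = 0.9 * err_norm ** -0.2
            if fac < 0.1:
                fac = 0.1
            h = h * fac
        if h < h_min:
            h = h_min

    if n_steps >= max_steps and t < t_end:
        status = STEP_FLOOR
    # pad any unfilled tail (runaway / aborted)
    while i_out < n_out:
        R_out[i_out] = R
        V_out[i_out] = V
        i_out += 1
    return R_out, V_out, status, n_steps
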