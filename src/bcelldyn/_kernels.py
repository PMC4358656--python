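"""Compiled integration kernels for the agent engine.

The integrated surrogate model is smooth and only mildly stiff (fastest
relaxation rates of a few per hour against a 144-h horizon), so the engine
integrates each agent with a fixed-step classical Runge-Kutta (RK4) scheme
at a small step (default 0.005 h).  Threshold crossings (death: cPARP up
through 25,000 molecules/cell; division: the mitosis readout up through 0.2)
are detected by sign change across a step and then located by bisection on
the step fraction, far below the 1e-3 h timing tolerance the analytics need.

All kernels are compiled with numba when available and fall back to the same
pure-Python code otherwise.
"""

from __future__ import annotations

import numpy as np

from .model_core import _rhs_core, N_SPECIES, CPARP, CDH1, MASS

try:  # pragma: no cover
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

# fate status codes
CENSORED = 0
DIVIDED = 1
DIED = 2

_N_BISECT = 20  # locates crossings to dt / 2**20


@njit(cache=False)
def _rk4_step(t, y, p, h, k1, k2, k3, k4, ytmp, out):
    _rhs_core(t, y, p, k1)
    for i in range(N_SPECIES):
        ytmp[i] = y[i] + 0.5 * h * k1[i]
    _rhs_core(t + 0.5 * h, ytmp, p, k2)
    for i in range(N_SPECIES):
        ytmp[i] = y[i] + 0.5 * h * k2[i]
    _rhs_core(t + 0.5 * h, ytmp, p, k3)
    for i in range(N_SPECIES):
        ytmp[i] = y[i] + h * k3[i]
    _rhs_core(t + h, ytmp, p, k4)
    for i in range(N_SPECIES):
        out[i] = y[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=False)
def _locate_crossing(t0, y0, p, dt, idx, thresh, k1, k2, k3, k4, ytmp, ycross):
    """Bisect the step fraction at which species ``idx`` crosses ``thresh``
    upward inside (t0, t0+dt]; fills ``ycross`` with the state at the
    located time and returns that time."""
    lo = 0.0
    hi = dt
    for _ in range(_N_BISECT):
        mid = 0.5 * (lo + hi)
        _rk4_step(t0, y0, p, mid, k1, k2, k3, k4, ytmp, ycross)
        if ycross[idx] >= thresh:
            hi = mid
        else:
            lo = mid
    _rk4_step(t0, y0, p, hi, k1, k2, k3, k4, ytmp, ycross)
    return t0 + hi


@njit(cache=False)
def simulate_lifetime(y0, p, t_birth, t_end, dt, grid_step, debounce,
                      parp_thresh, cdh1_thresh, tie_tol):
    """Integrate one agent from birth until its first fate event or ``t_end``.

    Returns ``(status, t_final, y_final, grid_t, grid_mass, n_grid)`` where
    the grid arrays hold mass samples on the output grid up to and including
    the event/censoring time.
    """
    n_grid_max = int((t_end - t_birth) / grid_step) + 3
    grid_t = np.empty(n_grid_max)
    grid_mass = np.empty(n_grid_max)
    k1 = np.empty(N_SPECIES)
    k2 = np.empty(N_SPECIES)
    k3 = np.empty(N_SPECIES)
    k4 = np.empty(N_SPECIES)
    ytmp = np.empty(N_SPECIES)
    ynew = np.empty(N_SPECIES)
    ycross = np.empty(N_SPECIES)
    ycross2 = np.empty(N_SPECIES)

    y = y0.copy()
    t = t_birth
    grid_t[0] = t
    grid_mass[0] = y[MASS]
    n_grid = 1
    next_grid = t_birth + grid_step
    # last time the mitosis readout was at/above threshold (birth acts as the
    # reference so a division cannot fire within the debounce window of birth)
    prev_above = t_birth

    status = CENSORED
    while t < t_end - 1e-12:
        h = dt
        if t + h > t_end:
            h = t_end - t
        _rk4_step(t, y, p, h, k1, k2, k3, k4, ytmp, ynew)

        death_hit = y[CPARP] < parp_thresh and ynew[CPARP] >= parp_thresh
        div_cross = y[CDH1] < cdh1_thresh and ynew[CDH1] >= cdh1_thresh

        t_death = -1.0
        if death_hit:
            t_death = _locate_crossing(t, y, p, h, CPARP, parp_thresh,
                                       k1, k2, k3, k4, ytmp, ycross)
        t_div = -1.0
        if div_cross:
            t_div = _locate_crossing(t, y, p, h, CDH1, cdh1_thresh,
                                     k1, k2, k3, k4, ytmp, ycross2)
            if t_div - prev_above < debounce:
                t_div = -1.0  # debounced: readout was above too recently

        if t_death >= 0.0 and t_div >= 0.0:
            # simultaneous crossings: death wins ties within tie_tol
            if t_death <= t_div + tie_tol:
                status = DIED
                t = t_death
                for i in range(N_SPECIES):
                    y[i] = ycross[i]
            else:
                status = DIVIDED
                t = t_div
                for i in range(N_SPECIES):
                    y[i] = ycross2[i]
            break
        elif t_death >= 0.0:
            status = DIED
            t = t_death
            for i in range(N_SPECIES):
                y[i] = ycross[i]
            break
        elif t_div >= 0.0:
            status = DIVIDED
            t = t_div
            for i in range(N_SPECIES):
                y[i] = ycross2[i]
            break

        if ynew[CDH1] >= cdh1_thresh:
            prev_above = t + h
        t = t + h
        for i in range(N_SPECIES):
            y[i] = ynew[i]
        if t >= next_grid - 1e-9:
            grid_t[n_grid] = t
            grid_mass[n_grid] = y[MASS]
            n_grid += 1
            next_grid += grid_step

    if grid_t[n_grid - 1] < t - 1e-9:
        grid_t[n_grid] = t
        grid_mass[n_grid] = y[MASS]
        n_grid += 1
    return status, t, y, grid_t, grid_mass, n_grid


@njit(cache=False)
def equilibrate_kernel(y0, p, dt, min_hours, max_hours, tol, scale, cdh1_thresh):
    """Integrate under equilibration conditions until the state drifts less
    than ``tol`` (relative to each species' scale) over a 1-h window.

    Returns ``(y, hours, converged, cycle_entered)``; ``cycle_entered`` is
    set if the mitosis readout ever reached threshold (the parameterization
    is then not quiescent).
    """
    k1 = np.empty(N_SPECIES)
    k2 = np.empty(N_SPECIES)
    k3 = np.empty(N_SPECIES)
    k4 = np.empty(N_SPECIES)
    ytmp = np.empty(N_SPECIES)
    ynew = np.empty(N_SPECIES)
    y = y0.copy()
    yprev = np.empty(N_SPECIES)
    steps_per_hour = int(round(1.0 / dt))
    hours = 0.0
    converged = False
    cycle_entered = False
    while hours < max_hours - 1e-9:
        for i in range(N_SPECIES):
            yprev[i] = y[i]
        for s in range(steps_per_hour):
            _rk4_step(hours + s * dt, y, p, dt, k1, k2, k3, k4, ytmp, ynew)
            for i in range(N_SPECIES):
                y[i] = ynew[i]
            if y[CDH1] >= cdh1_thresh:
                cycle_entered = True
        hours += 1.0
        if hours >= min_hours:
            drift = 0.0
            for i in range(N_SPECIES):
                d = abs(y[i] - yprev[i]) / scale[i]
                if d > drift:
                    drift = d
            if drift < tol:
                converged = True
                break
    return y, hours, converged, cycle_entered


@njit(cache=False)
def integrate_grid(y0, p, t0, grid, dt):
    """Integrate without event handling, returning the full state at each
    time in ``grid`` (used by tests and diagnostics)."""
    k1 = np.empty(N_SPECIES)
    k2 = np.empty(N_SPECIES)
    k3 = np.empty(N_SPECIES)
    k4 = np.empty(N_SPECIES)
    ytmp = np.empty(N_SPECIES)
    ynew = np.empty(N_SPECIES)
    y = y0.copy()
    out = np.empty((grid.shape[0], N_SPECIES))
    t = t0
    for j in range(grid.shape[0]):
        target = grid[j]
        while t < target - 1e-12:
            h = dt
            if t + h > target:
                h = target - t
            _rk4_step(t, y, p, h, k1, k2, k3, k4, ytmp, ynew)
            for i in range(N_SPECIES):
                y[i] = ynew[i]
            t += h
        for i in range(N_SPECIES):
            out[j, i] = y[i]
    return out
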