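"""Independent fixed-step reference integrator used as an oracle in tests.

Classic fourth-order Runge-Kutta at a fixed 1 µs step: no adaptivity, no
error control, no shared code with the pacing engine's LSODA path.  At this
step size the discretisation error is orders of magnitude below the test
tolerances, so disagreement indicates a defect in the adaptive solve.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def rk4_pace(rhs, y, p, period, dt, sample_every):
    """One pacing cycle by fixed-step RK4; returns (end state, sampled V)."""
    n = int(round(period / dt))
    stride = int(round(sample_every / dt))
    vout = np.empty(n // stride + 1)
    vout[0] = y[0]
    k = 1
    t = 0.0
    for i in range(n):
        k1 = rhs(t, y, p)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1, p)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2, p)
        k4 = rhs(t + dt, y + dt * k3, p)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (i + 1) * dt
        if (i + 1) % stride == 0:
            vout[k] = y[0]
            k += 1
    return y, vout


def fit_pic50_grid_oracle(conc, frac, lo=0.0, hi=12.0, n=120001):
    """Brute-force SSE grid search for the one-parameter Hill fit."""
    grid = np.linspace(lo, hi, n)
    conc = np.asarray(conc)[:, None]
    pred = 1.0 / (1.0 + conc * 10.0 ** (grid[None, :] - 6.0))
    sse = np.sum((pred - np.asarray(frac)[:, None]) ** 2, axis=0)
    return float(grid[np.argmin(sse)])
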