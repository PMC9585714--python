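"""Standard (Tofts) compartmental contrast-agent kinetics.

Ct(t) = Ktrans * int_0^t Cp(u) exp(-(Ktrans/ve) (t - u)) du

with Ktrans in 1/min and time grids in seconds. The convolution treats Cp as
piecewise linear between grid points and integrates each segment in closed
form, so the result is exact for piecewise-linear inputs; on a uniform grid
the linear recurrence is evaluated with a C-speed IIR filter.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

__all__ = ["tofts_concentration"]


def _segment_weights(kep_s: float, dt: float):
    """Closed-form weights for a linear Cp segment convolved with exp(-kep t).

    For Cp(u) = c0 + (c1 - c0) u/dt on [0, dt], the increment to the running
    integral is w0*c0 + w1*c1 with the previous integral damped by E.
    """
    if kep_s * dt < 1e-12:
        return 1.0, dt / 2.0, dt / 2.0
    e = np.exp(-kep_s * dt)
    f = (1.0 - e) / kep_s
    g = (dt - f) / (kep_s * dt)
    # integral = c0 * (f - g) + c1 * g
    return e, f - g, g


def tofts_concentration(ktrans: float, ve: float, cp_curve, t_grid):
    """Tissue concentration Ct (mM) on `t_grid` (s) for plasma input `cp_curve` (mM).

    Time origin is the first grid point (Ct = 0 there). Raises for ve <= 0 or
    negative ktrans.
    """
    if ve <= 0:
        raise ValueError("ve must be positive")
    if ktrans < 0:
        raise ValueError("ktrans must be non-negative")
    t = np.asarray(t_grid, dtype=float)
    cp = np.asarray(cp_curve, dtype=float)
    if t.shape != cp.shape or t.ndim != 1:
        raise ValueError("cp_curve and t_grid must be 1-D arrays of equal length")
    if t.size < 2:
        return np.zeros_like(t)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("t_grid must be strictly increasing")

    kep_s = (ktrans / ve) / 60.0
    kt_s = ktrans / 60.0

    if np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        e, w0, w1 = _segment_weights(kep_s, float(dt[0]))
        # increments c_j = w0*cp[j-1] + w1*cp[j]; I_j = e*I_{j-1} + c_j
        c = w0 * cp[:-1] + w1 * cp[1:]
        integral = np.empty_like(t)
        integral[0] = 0.0
        integral[1:] = lfilter([1.0], [1.0, -e], c)
        return kt_s * integral

    integral = np.zeros_like(t)
    acc = 0.0
    for j in range(1, t.size):
        e, w0, w1 = _segment_weights(kep_s, float(dt[j - 1]))
        acc = e * acc + w0 * cp[j - 1] + w1 * cp[j]
        integral[j] = acc
    return kt_s * integral
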