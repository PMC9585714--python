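"""SPGR signal physics, native-T1 mapping, and FXR water-exchange relaxation.

Longitudinal relaxation observed during contrast passage is modelled in the
fast-exchange-regime (FXR) simplification of the two-site
(intracellular/extracellular) water-exchange model: only the slowly relaxing
eigenvalue of the 2x2 exchange-relaxation matrix is retained, with unit
apparent population. Water population fractions are approximated by volume
fractions (p_i = 1 - v_e, p_e = v_e).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "spgr_signal",
    "signal_ratio_dce_pd",
    "solve_r1_from_ratio",
    "estimate_t10_map",
    "fxr_longitudinal_rate",
]

R1_BRACKET = (0.05, 20.0)  # s^-1 search interval for native R1 recovery


def spgr_signal(r1, flip_angle_deg: float, tr_ms: float, s0=1.0):
    """Steady-state spoiled gradient-echo signal.

    S = s0 * sin(a) * (1 - E) / (1 - cos(a) * E),  E = exp(-TR * R1)

    with TR in ms and R1 in s^-1. The echo-time/T2* factor is treated as
    constant and absorbed into ``s0``.
    """
    r1 = np.asarray(r1, dtype=float)
    if np.any(r1 < 0):
        raise ValueError("longitudinal rate r1 must be non-negative")
    if not 0.0 < flip_angle_deg < 90.0:
        raise ValueError("flip angle must lie in (0, 90) degrees")
    if tr_ms <= 0:
        raise ValueError("TR must be positive")
    a = np.deg2rad(flip_angle_deg)
    e = np.exp(-(tr_ms / 1000.0) * r1)
    out = s0 * np.sin(a) * (1.0 - e) / (1.0 - np.cos(a) * e)
    return out if out.ndim else float(out)


def signal_ratio_dce_pd(r1, acq) -> float:
    """Ratio of dynamic-frame to proton-density-frame SPGR signal; s0 cancels."""
    return spgr_signal(r1, acq.flip_angle_dce, acq.tr_dce) / spgr_signal(
        r1, acq.flip_angle_pd, acq.tr_pd
    )


def solve_r1_from_ratio(ratio: float, acq, bracket=R1_BRACKET) -> float:
    """Invert the dual-acquisition signal ratio for the native rate R10 (s^-1).

    Returns NaN when the observed ratio is outside the range attainable on the
    bracket (the caller flags the voxel invalid).
    """
    lo, hi = bracket
    f_lo = signal_ratio_dce_pd(lo, acq) - ratio
    f_hi = signal_ratio_dce_pd(hi, acq) - ratio
    if not np.isfinite(ratio) or f_lo * f_hi > 0:
        return float("nan")
    return float(brentq(lambda r: signal_ratio_dce_pd(r, acq) - ratio,
                        lo, hi, xtol=1e-12, rtol=1e-14))


def estimate_t10_map(dce_baseline_volume, pd_volume, acq, mask=None):
    """Native T1 map from the second-baseline dynamic frame and the PD volume.

    Per voxel, the ratio S_dce/S_pd (in which the common signal scale cancels)
    is inverted for R10 by bracketed root finding on [0.05, 20] s^-1;
    T10 = 1/R10. Voxels with non-positive PD signal or a ratio outside the
    attainable range are flagged invalid.

    Returns
    -------
    t10 : ndarray
        T10 in seconds; NaN at invalid voxels.
    valid : ndarray of bool
    """
    dce = np.asarray(dce_baseline_volume, dtype=float)
    pd_vol = np.asarray(pd_volume, dtype=float)
    if dce.shape != pd_vol.shape:
        raise ValueError("baseline and proton-density volumes must share a shape")
    if mask is None:
        mask = np.ones(dce.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    t10 = np.full(dce.shape, np.nan)
    valid = np.zeros(dce.shape, dtype=bool)
    for idx in np.argwhere(mask):
        i = tuple(idx)
        if pd_vol[i] <= 0 or dce[i] <= 0:
            continue
        r10 = solve_r1_from_ratio(dce[i] / pd_vol[i], acq)
        if np.isfinite(r10):
            t10[i] = 1.0 / r10
            valid[i] = True
    return t10, valid


def fxr_longitudinal_rate(ct_value, ve: float, tau_i: float, r10: float,
                          r1_relaxivity: float):
    """Observed longitudinal rate R1L (s^-1) under FXR water exchange.

    With extracellular rate R1e = r10 + r * Ct / v_e, intracellular rate
    R1i = r10, efflux k_ie = 1/tau_i and influx k_ei = k_ie (1 - v_e)/v_e:

        2 R1L = (R1i + R1e + k_ie + k_ei)
                - sqrt((R1i + k_ie - R1e - k_ei)^2 + 4 k_ie k_ei)

    the smaller (slowly relaxing) eigenvalue. Equals r10 at Ct = 0 and is
    nondecreasing in Ct.
    """
    ct = np.asarray(ct_value, dtype=float)
    if np.any(ct < 0):
        raise ValueError("tissue concentration must be non-negative")
    if not 0.0 < ve <= 1.0:
        raise ValueError("ve must lie in (0, 1]")
    if tau_i <= 0:
        raise ValueError("tau_i must be positive")
    r1e = r10 + r1_relaxivity * ct / ve
    r1i = r10
    k_ie = 1.0 / tau_i
    k_ei = k_ie * (1.0 - ve) / ve
    s = r1i + r1e + k_ie + k_ei
    d = r1i + k_ie - r1e - k_ei
    disc = np.sqrt(d * d + 4.0 * k_ie * k_ei)
    out = 0.5 * (s - disc)
    return out if out.ndim else float(out)
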