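"""Per-voxel Shutter-Speed (FXR) pharmacokinetic model and its estimation.

The forward model chains: population AIF -> Tofts tissue concentration (time
origin at the injection frame) -> FXR longitudinal rate -> SPGR signal, with
the signal scale s0 fixed from the pre-injection baseline mean. Estimation is
bounded nonlinear least squares on (Ktrans, ve, tau_i) with a fixed 3x3x3
multi-start grid; kep = Ktrans/ve is derived, never fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .acquisition import AcquisitionParams
from .aif import AIFModel
from .kinetics import tofts_concentration
from .relaxometry import fxr_longitudinal_rate, spgr_signal

__all__ = [
    "PKParams",
    "FitBounds",
    "compute_kep",
    "fxr_forward_timecourse",
    "ShutterSpeedVoxelModel",
    "VoxelFitResults",
    "fit_voxel_fxr",
    "summarize_roi",
]


def compute_kep(ktrans: float, ve: float) -> float:
    """Efflux rate constant kep = Ktrans / ve (1/min)."""
    if ve <= 0:
        raise ValueError("ve must be positive")
    return ktrans / ve


@dataclass(frozen=True)
class PKParams:
    """Voxel (or ROI-mean) pharmacokinetic parameters.

    ktrans in 1/min, ve dimensionless in (0, 1], tau_i in seconds; kep is
    derived as ktrans/ve and populated automatically.
    """

    ktrans: float
    ve: float
    tau_i: float
    kep: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("ktrans must be non-negative")
        if not 0.0 < self.ve <= 1.0:
            raise ValueError("ve must lie in (0, 1]")
        if self.tau_i <= 0:
            raise ValueError("tau_i must be positive")
        kep = compute_kep(self.ktrans, self.ve)
        if self.kep is None:
            object.__setattr__(self, "kep", kep)
        elif abs(self.kep - kep) > 1e-12 * max(1.0, abs(kep)):
            raise ValueError("kep inconsistent with ktrans/ve")


@dataclass(frozen=True)
class FitBounds:
    ktrans: tuple = (0.0, 5.0)      # 1/min
    ve: tuple = (0.01, 1.0)         # fraction
    tau_i: tuple = (0.05, 5.0)      # s

    @property
    def lower(self):
        return np.array([self.ktrans[0], self.ve[0], self.tau_i[0]])

    @property
    def upper(self):
        return np.array([self.ktrans[1], self.ve[1], self.tau_i[1]])


# Fixed multi-start grid (log-ish spread inside the default bounds). Order is
# the tie-break order: C-order over (ktrans, ve, tau_i).
DEFAULT_START_GRID = {
    "ktrans": (0.02, 0.1, 0.5),
    "ve": (0.2, 0.5, 0.8),
    "tau_i": (0.2, 0.6, 1.5),
}


def _fine_tau_grid(acq: AcquisitionParams, dt: float = 1.0) -> np.ndarray:
    """Internal oversampled grid of time-since-injection, including 0."""
    t_end = float(acq.frame_times[-1]) - acq.injection_time
    n = max(2, int(np.ceil(t_end / dt)) + 1)
    return np.linspace(0.0, max(t_end, dt), n)


def fxr_forward_timecourse(pk: PKParams, t10: float, acq: AcquisitionParams,
                           aif: AIFModel, s0: float = 1.0,
                           sampling_dt: float = 1.0) -> np.ndarray:
    """Noise-free SPGR signal time-course at the acquisition frame times.

    Frames before the injection frame carry the pre-contrast baseline signal;
    later frames follow the AIF -> Tofts -> FXR -> SPGR chain with the time
    origin at the start of the injection frame. The tissue concentration is
    computed on an internal 1 s grid and linearly interpolated at frame times.
    """
    if t10 <= 0:
        raise ValueError("t10 must be positive")
    r10 = 1.0 / t10
    tau = _fine_tau_grid(acq, sampling_dt)
    cp = aif.plasma_concentration(tau)
    ct_fine = tofts_concentration(pk.ktrans, pk.ve, cp, tau)

    frame_tau = acq.frame_times - acq.injection_time
    ct_frames = np.interp(frame_tau, tau, ct_fine)
    ct_frames[frame_tau < 0] = 0.0

    r1 = fxr_longitudinal_rate(ct_frames, pk.ve, pk.tau_i, r10, acq.relaxivity_r1)
    return spgr_signal(r1, acq.flip_angle_dce, acq.tr_dce, s0)


@dataclass
class VoxelFitResults:
    """Estimates and diagnostics from one voxel's FXR fit."""

    params: PKParams
    s0: float
    residual_norm: float
    converged: bool
    n_starts: int
    best_start_index: int
    cost_per_start: np.ndarray = field(repr=False)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Shutter-Speed (FXR) voxel fit",
            f"  Ktrans  {p.ktrans:10.5f}  1/min",
            f"  ve      {p.ve:10.5f}",
            f"  tau_i   {p.tau_i:10.5f}  s",
            f"  kep     {p.kep:10.5f}  1/min  (Ktrans/ve)",
            f"  s0      {self.s0:10.3f}",
            f"  ||r||   {self.residual_norm:10.5g}",
            f"  converged: {self.converged} "
            f"(best of {self.n_starts} starts, index {self.best_start_index})",
        ]
        return "\n".join(lines)


class ShutterSpeedVoxelModel:
    """FXR model for one voxel's dynamic signal, statsmodels-style.

    Parameters
    ----------
    signal : array
        Measured SPGR signal per frame.
    t10 : float
        Native T1 of the voxel, seconds (from the dual-acquisition map).
    acq, aif
        Acquisition settings and population AIF.
    s0 : float, optional
        Signal scale. When omitted it is fixed from the pre-injection
        baseline mean (the default estimation convention).
    """

    def __init__(self, signal, t10: float, acq: AcquisitionParams, aif: AIFModel,
                 s0: float | None = None, sampling_dt: float = 1.0):
        self.signal = np.asarray(signal, dtype=float)
        if self.signal.ndim != 1 or self.signal.size != acq.n_frames:
            raise ValueError("signal must be 1-D with one sample per frame")
        if self.signal.size < 10:
            raise ValueError("need at least 10 frames to fit")
        if acq.n_baseline_frames < 2:
            raise ValueError("need at least 2 pre-injection frames to fix s0")
        if t10 <= 0:
            raise ValueError("t10 must be positive")
        self.t10 = float(t10)
        self.r10 = 1.0 / self.t10
        self.acq = acq
        self.aif = aif
        self.sampling_dt = float(sampling_dt)

        baseline = self.signal[: acq.n_baseline_frames].mean()
        unit = spgr_signal(self.r10, acq.flip_angle_dce, acq.tr_dce, 1.0)
        self.s0 = float(s0) if s0 is not None else float(baseline / unit)

        # cache the injection-referenced fine grid and Cp once per voxel
        self._tau = _fine_tau_grid(acq, self.sampling_dt)
        self._cp = aif.plasma_concentration(self._tau)
        self._frame_tau = acq.frame_times - acq.injection_time
        self._pre = self._frame_tau < 0

    def predict(self, ktrans: float, ve: float, tau_i: float) -> np.ndarray:
        ct = tofts_concentration(ktrans, ve, self._cp, self._tau)
        ct_frames = np.interp(self._frame_tau, self._tau, ct)
        ct_frames[self._pre] = 0.0
        r1 = fxr_longitudinal_rate(ct_frames, ve, tau_i, self.r10,
                                   self.acq.relaxivity_r1)
        return spgr_signal(r1, self.acq.flip_angle_dce, self.acq.tr_dce, self.s0)

    def _residuals(self, theta) -> np.ndarray:
        return self.predict(theta[0], theta[1], theta[2]) - self.signal

    def fit(self, bounds: FitBounds = FitBounds(),
            start_grid: dict | None = None) -> VoxelFitResults:
        """Bounded least squares from every start on the grid; best cost wins.

        Ties are broken by grid order (C-order over ktrans, ve, tau_i).
        """
        grid = start_grid or DEFAULT_START_GRID
        starts = [
            (kt, ve, ti)
            for kt in grid["ktrans"]
            for ve in grid["ve"]
            for ti in grid["tau_i"]
        ]
        lo, hi = bounds.lower, bounds.upper
        best = None
        costs = np.full(len(starts), np.inf)
        for i, x0 in enumerate(starts):
            x0 = np.clip(np.asarray(x0, dtype=float), lo + 1e-12, hi - 1e-12)
            try:
                sol = least_squares(self._residuals, x0, bounds=(lo, hi),
                                    method="trf", xtol=1e-10, ftol=1e-10,
                                    gtol=1e-10)
            except Exception:
                continue
            costs[i] = sol.cost
            if sol.success and (best is None or sol.cost < best[1].cost):
                best = (i, sol)
        if best is None:
            raise RuntimeError("FXR fit failed to converge from every start")
        i, sol = best
        kt, ve, ti = sol.x
        ve = min(max(ve, 1e-12), 1.0)
        params = PKParams(ktrans=max(kt, 0.0), ve=ve, tau_i=max(ti, 1e-12))
        return VoxelFitResults(
            params=params,
            s0=self.s0,
            residual_norm=float(np.sqrt(2.0 * sol.cost)),
            converged=bool(sol.success),
            n_starts=len(starts),
            best_start_index=i,
            cost_per_start=costs,
        )


def fit_voxel_fxr(timecourse, t10: float, acq: AcquisitionParams, aif: AIFModel,
                  bounds: FitBounds = FitBounds(),
                  start_grid: dict | None = None) -> VoxelFitResults:
    """Functional wrapper: build the voxel model and fit it."""
    return ShutterSpeedVoxelModel(timecourse, t10, acq, aif).fit(bounds, start_grid)


def summarize_roi(param_maps: dict, roi_mask, valid_mask=None):
    """ROI-mean parameters: arithmetic mean over valid in-mask voxels.

    `param_maps` maps names (must include ktrans, ve, tau_i; kep included if
    present, else derived voxelwise) to arrays of the mask's shape. Returns
    (PKParams of means, n_voxels). kep is summarized as the mean of voxel kep
    values, not the ratio of means.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if valid_mask is not None:
        mask = mask & np.asarray(valid_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no valid voxels in ROI")
    kt = np.asarray(param_maps["ktrans"], dtype=float)[mask]
    ve = np.asarray(param_maps["ve"], dtype=float)[mask]
    ti = np.asarray(param_maps["tau_i"], dtype=float)[mask]
    if "kep" in param_maps:
        kep = np.asarray(param_maps["kep"], dtype=float)[mask]
    else:
        kep = kt / ve
    means = {
        "ktrans": float(kt.mean()),
        "ve": float(ve.mean()),
        "tau_i": float(ti.mean()),
        "kep": float(kep.mean()),
    }
    return means, int(mask.sum())
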