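"""Acquisition geometry and timing shared by the forward model, T1 mapping and fitting.

The dynamic series is a spoiled-gradient-echo (SPGR) acquisition; a companion
proton-density-weighted volume (low flip angle, long TR) acquired with otherwise
identical settings supports native-T1 mapping by signal-intensity ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["AcquisitionParams", "default_frame_times"]


def default_frame_times(n_frames: int = 32, frame_interval_s: float = 15.0) -> np.ndarray:
    """Uniformly spaced frame start times in seconds since scan start."""
    if n_frames < 3:
        raise ValueError("need at least 3 frames (2 baseline + injection frame)")
    if frame_interval_s <= 0:
        raise ValueError("frame interval must be positive")
    return np.arange(n_frames, dtype=float) * frame_interval_s


@dataclass(frozen=True)
class AcquisitionParams:
    """SPGR acquisition settings for one dynamic study.

    Parameters
    ----------
    flip_angle_dce : float
        Flip angle of the dynamic frames, degrees.
    flip_angle_pd : float
        Flip angle of the proton-density-weighted companion volume, degrees.
    tr_dce, tr_pd : float
        Repetition times, milliseconds.
    te : float
        Echo time, milliseconds (the T2* factor is absorbed into the signal
        scale and cancels in the T1-mapping ratio).
    frame_times : ndarray
        Frame start times, seconds since scan start, strictly increasing.
    injection_frame : int
        1-based index of the frame at whose start the contrast bolus is
        injected; frames before it are pre-contrast baseline.
    relaxivity_r1 : float
        Longitudinal relaxivity of the contrast agent at field strength,
        s^-1 mM^-1.
    """

    flip_angle_dce: float = 10.0
    flip_angle_pd: float = 5.0
    tr_dce: float = 6.2
    tr_pd: float = 50.0
    te: float = 2.9
    frame_times: np.ndarray = field(default_factory=default_frame_times)
    injection_frame: int = 3
    relaxivity_r1: float = 3.7

    def __post_init__(self) -> None:
        for name in ("flip_angle_dce", "flip_angle_pd"):
            a = getattr(self, name)
            if not 0.0 < a < 90.0:
                raise ValueError(f"{name} must lie in (0, 90) degrees, got {a}")
        for name in ("tr_dce", "tr_pd", "te"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        t = np.asarray(self.frame_times, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("frame_times must be a 1-D array of >= 3 times")
        if not np.all(np.diff(t) > 0):
            raise ValueError("frame_times must be strictly increasing")
        object.__setattr__(self, "frame_times", t)
        if not 3 <= self.injection_frame <= t.size:
            raise ValueError(
                f"injection_frame must lie in [3, n_frames]; got {self.injection_frame}"
            )
        if self.relaxivity_r1 <= 0:
            raise ValueError("relaxivity_r1 must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    @property
    def injection_time(self) -> float:
        """Seconds since scan start at which the bolus injection begins."""
        return float(self.frame_times[self.injection_frame - 1])

    @property
    def n_baseline_frames(self) -> int:
        return self.injection_frame - 1

    def with_frame_times(self, frame_times: np.ndarray) -> "AcquisitionParams":
        return replace(self, frame_times=np.asarray(frame_times, dtype=float))
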