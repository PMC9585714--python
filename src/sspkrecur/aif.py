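"""Population arterial input function (AIF).

The cohort-average measured AIF underlying the original analysis is not
distributable, so the package ships the standard parametric population AIF of
Parker et al. (Magn Reson Med 2006): a sum of two Gaussian bolus passes plus an
exponential washout modulated by a sigmoid. Parameters are expressed in the
minutes-based units in which that form is conventionally quoted; evaluation is
in seconds to match frame timing. Whole-blood concentration is converted to
plasma concentration by dividing by (1 - hematocrit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AIFModel", "population_aif"]


@dataclass(frozen=True)
class AIFModel:
    """Parametric population AIF: two gamma-like Gaussian passes + sigmoidal washout.

    Cb(t) = sum_n A_n / (sigma_n sqrt(2 pi)) exp(-(t - T_n)^2 / (2 sigma_n^2))
            + alpha exp(-beta t) / (1 + exp(-s (t - tau)))        [t in minutes]

    Cp(t) = Cb(t) / (1 - hematocrit), and Cp = 0 before `bolus_arrival_s`.
    """

    a1: float = 0.809      # mM * min
    a2: float = 0.330      # mM * min
    t1: float = 0.17046    # min
    t2: float = 0.365      # min
    sigma1: float = 0.0563  # min
    sigma2: float = 0.132   # min
    alpha: float = 1.050   # mM
    beta: float = 0.1685   # 1/min
    s: float = 38.078      # 1/min
    tau: float = 0.483     # min
    hematocrit: float = 0.45
    bolus_arrival_s: float = 0.0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0 or self.alpha < 0:
            raise ValueError("AIF amplitudes must be non-negative")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("AIF bolus widths must be positive")
        if self.beta < 0 or self.s < 0:
            raise ValueError("AIF washout rate and sigmoid steepness must be non-negative")
        if not 0.0 <= self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in [0, 1)")

    def blood_concentration(self, t_seconds: np.ndarray) -> np.ndarray:
        """Whole-blood concentration (mM) at times in seconds since bolus arrival origin."""
        t = np.asarray(t_seconds, dtype=float)
        tm = (t - self.bolus_arrival_s) / 60.0
        pre = tm < 0
        tm = np.where(pre, 0.0, tm)
        g = np.zeros_like(tm)
        for a, c, w in ((self.a1, self.t1, self.sigma1), (self.a2, self.t2, self.sigma2)):
            g += a / (w * np.sqrt(2.0 * np.pi)) * np.exp(-((tm - c) ** 2) / (2.0 * w**2))
        washout = self.alpha * np.exp(-self.beta * tm) / (1.0 + np.exp(-self.s * (tm - self.tau)))
        cb = g + washout
        cb[pre] = 0.0
        return cb

    def plasma_concentration(self, t_seconds: np.ndarray) -> np.ndarray:
        """Plasma concentration Cp (mM) at times in seconds."""
        return self.blood_concentration(t_seconds) / (1.0 - self.hematocrit)


def population_aif(t_grid_s: np.ndarray, model: AIFModel | None = None) -> np.ndarray:
    """Evaluate the plasma AIF Cp (mM) on an increasing time grid in seconds."""
    t = np.asarray(t_grid_s, dtype=float)
    if t.ndim != 1 or (t.size > 1 and not np.all(np.diff(t) > 0)):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    model = model if model is not None else AIFModel()
    return model.plasma_concentration(t)
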