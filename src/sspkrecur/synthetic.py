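"""Synthetic NACT breast-cancer cohort and matching DCE-MRI voxel data.

The generator emulates the published cohort margins (47 patients, 7
recurrences, receptor-subtype and residual-cancer-burden distributions) and
the group-wise tumor MRI-metric distributions (longest diameter and
Shutter-Speed parameters at the pre- and post-treatment visits), and emits
voxel-level dynamic series that follow the package's own FXR forward model
plus i.i.d. Gaussian signal noise. It provides ground truth for
parameter-recovery and end-to-end tests; it does not emulate k-space
acquisition, motion, coil profiles, or spatial textures of real tumors.

Group-wise parameter distributions are lognormal, moment-matched to the
configured natural-scale means/SDs, and coupled through a Gaussian copula
with a configurable correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .acquisition import AcquisitionParams
from .aif import AIFModel
from .morphometry import RoiMask
from .pkfit import PKParams, fxr_forward_timecourse
from .relaxometry import spgr_signal

__all__ = [
    "CohortConfig",
    "ImagingConfig",
    "DCEStudy",
    "generate_cohort",
    "generate_patient_imaging",
    "metrics_from_truth",
    "METRIC_COLUMNS",
]

GROUPS = ("nonrecurrence", "recurrence")
PARAMS = ("ktrans", "ve", "tau_i", "ld")
VISITS = ("V1", "V4")

# Published-cohort calibration: per-group, per-visit natural-scale mean/SD.
DEFAULT_PK_GROUP_PARAMS = {
    "nonrecurrence": {
        "V1": {"ktrans": (0.14, 0.10), "ve": (0.54, 0.11),
               "tau_i": (0.78, 0.30), "ld": (38.73, 20.37)},
        "V4": {"ktrans": (0.03, 0.03), "ve": (0.63, 0.19),
               "tau_i": (0.99, 0.44), "ld": (16.23, 14.28)},
    },
    "recurrence": {
        "V1": {"ktrans": (0.30, 0.25), "ve": (0.57, 0.07),
               "tau_i": (0.69, 0.20), "ld": (48.83, 35.64)},
        "V4": {"ktrans": (0.14, 0.17), "ve": (0.56, 0.13),
               "tau_i": (0.67, 0.39), "ld": (34.09, 27.18)},
    },
}

# RCB class probabilities {0, I, II, III} per outcome group (cohort margins).
DEFAULT_RCB_PROBS = {
    "nonrecurrence": (12 / 40, 9 / 40, 16 / 40, 3 / 40),
    "recurrence": (0 / 7, 1 / 7, 2 / 7, 4 / 7),
}

# Receptor-subtype joint cells per group: (triple-negative, HR+ only,
# HER2+ only, HR+ and HER2+); counts chosen to reproduce the cohort margins
# 27 HR+, 24 HER2+, 8 TN exactly at the default group sizes.
DEFAULT_SUBTYPE_CELLS = {
    "nonrecurrence": (7, 12, 10, 11),
    "recurrence": (1, 3, 2, 1),
}

DEFAULT_TUMOR_TYPE_CELLS = {  # (IDC, ILC, IMC)
    "nonrecurrence": (36, 2, 2),
    "recurrence": (6, 0, 1),
}

DEFAULT_AGE = {"nonrecurrence": (48.6, 13.3), "recurrence": (39.7, 8.2)}

# Gaussian-copula correlations on the log scale, order
# (ktrans, ve, tau_i, ld) within a visit; same-parameter cross-visit
# coupling on the block off-diagonal. Moderate positive ktrans couplings,
# weak elsewhere — a modelling choice, not a published fact.
DEFAULT_WITHIN_VISIT_CORR = np.array([
    [1.0, 0.1, -0.2, 0.2],
    [0.1, 1.0, 0.1, 0.0],
    [-0.2, 0.1, 1.0, 0.0],
    [0.2, 0.0, 0.0, 1.0],
])
DEFAULT_CROSS_VISIT_CORR = 0.3

# Default logistic effect model linking truth to recurrence probability
# (generator plumbing, not a published model).
DEFAULT_EFFECT_MODEL = {
    "intercept": 2.4,
    "log_ktrans_v4": 1.5,
    "rcb": 0.8,
    "age_centered": -0.05,
}


def _lognormal_mu_sigma(mean: float, sd: float) -> tuple:
    """Moment-match a lognormal to a natural-scale mean/SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("natural-scale mean and sd must be positive")
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation settings; defaults are the published margins."""

    n_patients: int = 47
    recurrence_count: int = 7
    age_by_group: dict = field(default_factory=lambda: dict(DEFAULT_AGE))
    rcb_probs_by_group: dict = field(default_factory=lambda: dict(DEFAULT_RCB_PROBS))
    subtype_cells_by_group: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_CELLS))
    tumor_type_cells_by_group: dict = field(
        default_factory=lambda: dict(DEFAULT_TUMOR_TYPE_CELLS))
    pk_group_params: dict = field(
        default_factory=lambda: {g: {v: dict(DEFAULT_PK_GROUP_PARAMS[g][v])
                                     for v in VISITS} for g in GROUPS})
    effect_model: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MODEL))
    within_visit_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_WITHIN_VISIT_CORR.copy())
    cross_visit_corr: float = DEFAULT_CROSS_VISIT_CORR
    stage3_prob_by_group: dict = field(
        default_factory=lambda: {"nonrecurrence": 0.45, "recurrence": 0.7})
    t10_mean_s: float = 1.4
    t10_sd_s: float = 0.15
    recurrence_time_median_months: float = 5.0
    followup_median_months: float = 85.5
    followup_log_sd: float = 0.4
    fixed_margin: bool = True
    noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.recurrence_count <= self.n_patients:
            raise ValueError("need n_patients >= recurrence_count >= 0")
        for g, probs in self.rcb_probs_by_group.items():
            p = np.asarray(probs, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"RCB probabilities for {g} must sum to 1")
        for g in GROUPS:
            for v in VISITS:
                for name, (m, s) in self.pk_group_params[g][v].items():
                    if m <= 0 or s <= 0:
                        raise ValueError(
                            f"scale parameters must be positive ({g}/{v}/{name})")
        corr = self.correlation_matrix()
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("copula correlation matrix is not positive semidefinite")

    def correlation_matrix(self) -> np.ndarray:
        """8x8 copula correlation over (V1, V4) x (ktrans, ve, tau_i, ld)."""
        w = np.asarray(self.within_visit_corr, dtype=float)
        c = np.eye(4) * self.cross_visit_corr
        return np.block([[w, c], [c, w]])


def _exact_counts(cells, n: int, rng) -> np.ndarray:
    """Per-patient category codes realizing counts `cells` (scaled to n), shuffled."""
    cells = np.asarray(cells, dtype=float)
    base = cells / cells.sum() * n
    counts = np.floor(base).astype(int)
    # distribute remainder by largest fractional part, ties by category order
    rem = n - counts.sum()
    frac_order = np.argsort(-(base - np.floor(base)), kind="stable")
    for j in range(rem):
        counts[frac_order[j % len(cells)]] += 1
    codes = np.repeat(np.arange(len(cells)), counts)
    rng.shuffle(codes)
    return codes


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patient table, truth table) for one cohort.

    In fixed-margin mode the distribution-group sizes, receptor-subtype and
    tumor-type cells are realized exactly and recurrence labels are assigned
    to the `recurrence_count` highest effect-model probabilities; in sampled
    mode group membership and labels are Bernoulli draws.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # distribution-group assignment
    if config.fixed_margin:
        group_codes = np.zeros(n, dtype=int)
        group_codes[: config.recurrence_count] = 1
        rng.shuffle(group_codes)
    else:
        group_codes = (rng.random(n) < config.recurrence_count / n).astype(int)
    groups = np.array(GROUPS)[group_codes]

    corr = config.correlation_matrix()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))

    rows = []
    for g in GROUPS:
        idx = np.flatnonzero(groups == g)
        m = idx.size
        if m == 0:
            continue
        z = rng.standard_normal((m, 8)) @ chol.T
        vals = {}
        for vi, visit in enumerate(VISITS):
            for pi, name in enumerate(PARAMS):
                mu, sig = _lognormal_mu_sigma(*config.pk_group_params[g][visit][name])
                x = np.exp(mu + sig * z[:, 4 * vi + pi])
                if name == "ve":
                    x = np.minimum(x, 0.99)
                vals[f"{name}_{visit.lower()}"] = x
        age_m, age_s = config.age_by_group[g]
        vals["age"] = rng.normal(age_m, age_s, m).clip(18.0, 90.0)
        vals["rcb_class"] = rng.choice(4, size=m,
                                       p=np.asarray(config.rcb_probs_by_group[g]))
        if config.fixed_margin:
            sub_codes = _exact_counts(config.subtype_cells_by_group[g], m, rng)
            tt_codes = _exact_counts(config.tumor_type_cells_by_group[g], m, rng)
        else:
            sub_p = np.asarray(config.subtype_cells_by_group[g], dtype=float)
            tt_p = np.asarray(config.tumor_type_cells_by_group[g], dtype=float)
            sub_codes = rng.choice(4, size=m, p=sub_p / sub_p.sum())
            tt_codes = rng.choice(3, size=m, p=tt_p / tt_p.sum())
        vals["subtype_code"] = sub_codes
        vals["tumor_type"] = np.array(["IDC", "ILC", "IMC"])[tt_codes]
        vals["stage"] = np.where(
            rng.random(m) < config.stage3_prob_by_group[g], 3, 2)
        vals["t10_v1"] = rng.normal(config.t10_mean_s, config.t10_sd_s, m).clip(0.8, 2.5)
        vals["t10_v4"] = rng.normal(config.t10_mean_s, config.t10_sd_s, m).clip(0.8, 2.5)
        frame = pd.DataFrame(vals, index=idx)
        frame["group"] = g
        rows.append(frame)
    truth = pd.concat(rows).sort_index()
    truth.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(n)])

    # effect-model probabilities and recurrence labels
    em = config.effect_model
    eta = (em.get("intercept", 0.0)
           + em.get("log_ktrans_v4", 0.0) * np.log(truth["ktrans_v4"])
           + em.get("rcb", 0.0) * truth["rcb_class"]
           + em.get("age_centered", 0.0) * (truth["age"] - 47.6))
    prob = expit(eta.to_numpy())
    if config.fixed_margin:
        order = np.argsort(-prob, kind="stable")
        label = np.zeros(n, dtype=int)
        label[order[: config.recurrence_count]] = 1
    else:
        label = (rng.random(n) < prob).astype(int)
    truth["recurrence_prob"] = prob
    truth["recurrence"] = label

    # event times: exponential recurrence times, lognormal censoring follow-up
    scale = config.recurrence_time_median_months / np.log(2.0)
    rec_time = rng.exponential(scale, n)
    followup = np.exp(rng.normal(np.log(config.followup_median_months),
                                 config.followup_log_sd, n))
    time = np.where(label == 1, rec_time, followup)
    truth["time_to_event_months"] = np.maximum(time, 0.1)
    truth["event"] = label

    for v in ("v1", "v4"):
        truth[f"kep_{v}"] = truth[f"ktrans_{v}"] / truth[f"ve_{v}"]

    patients = pd.DataFrame({
        "patient_id": truth["patient_id"],
        "age": truth["age"],
        "tumor_type": truth["tumor_type"],
        "hormone_receptor_positive": truth["subtype_code"].isin([1, 3]).astype(int),
        "her2_positive": truth["subtype_code"].isin([2, 3]).astype(int),
        "triple_negative": (truth["subtype_code"] == 0).astype(int),
        "stage": truth["stage"],
        "rcb_class": truth["rcb_class"],
        "recurrence": truth["recurrence"],
        "time_to_event_months": truth["time_to_event_months"],
        "event": truth["event"],
    })
    truth_cols = (["patient_id", "group"]
                  + [f"{p}_{v.lower()}" for v in VISITS for p in PARAMS]
                  + ["kep_v1", "kep_v4", "t10_v1", "t10_v4",
                     "recurrence_prob", "recurrence",
                     "time_to_event_months", "event"])
    return patients.reset_index(drop=True), truth[truth_cols].reset_index(drop=True)


METRIC_COLUMNS = [
    "ld_v1", "ld_v4", "ld_v41",
    "ktrans_v1", "ve_v1", "kep_v1", "tau_i_v1",
    "ktrans_v4", "ve_v4", "kep_v4", "tau_i_v4",
    "ktrans_v41", "ve_v41", "kep_v41", "tau_i_v41",
]


def metrics_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-patient MRI metric table (15 columns: V1, V4, percent changes)."""
    out = pd.DataFrame({"patient_id": truth["patient_id"]})
    for p in ("ld", "ktrans", "ve", "kep", "tau_i"):
        out[f"{p}_v1"] = truth[f"{p}_v1"]
        out[f"{p}_v4"] = truth[f"{p}_v4"]
        v1 = truth[f"{p}_v1"].to_numpy()
        v4 = truth[f"{p}_v4"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            pc = np.where(v1 > 0, (v4 - v1) / v1, np.nan)
        out[f"{p}_v41"] = pc
    return out[["patient_id"] + METRIC_COLUMNS]


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    """Voxel-grid settings for the synthetic dynamic studies."""

    in_plane_mm: float = 1.0
    slice_mm: float = 1.4
    axis_ratios: tuple = (0.7, 0.4)   # (second in-plane, through-plane) vs LD/2
    max_slices: int = 7
    max_ld_mm: float = 80.0
    voxel_jitter_cv: float = 0.2
    t10_jitter_cv: float = 0.05
    s0: float = 1000.0
    background_t10_s: float = 0.35
    grid_margin: int = 3
    n_frames_range: tuple = (28, 38)
    frame_interval_range_s: tuple = (14.0, 20.0)
    injection_frame: int = 3
    sampling_dt_s: float = 1.0


@dataclass
class DCEStudy:
    """One visit's synthetic study: dynamic series + companions + truth maps."""

    patient_id: str
    visit: str
    dce: np.ndarray            # (x, y, z, t) signal
    pd_volume: np.ndarray      # (x, y, z) proton-density-weighted signal
    roi: RoiMask
    t10_true: np.ndarray       # (x, y, z), s; NaN outside ROI
    truth_maps: dict           # name -> (x, y, z) true parameter maps
    acq: AcquisitionParams
    s0: float


def _ellipsoid_mask(ld_mm: float, img: ImagingConfig) -> np.ndarray:
    a = min(ld_mm, img.max_ld_mm) / 2.0
    b = max(a * img.axis_ratios[0], img.in_plane_mm)
    c = max(min(a * img.axis_ratios[1], img.max_slices * img.slice_mm / 2.0),
            img.slice_mm / 2.0)
    dx = dy = img.in_plane_mm
    dz = img.slice_mm
    nx = 2 * int(np.ceil(a / dx)) + 1 + 2 * img.grid_margin
    ny = 2 * int(np.ceil(b / dy)) + 1 + 2 * img.grid_margin
    nz = 2 * int(np.ceil(c / dz)) + 1 + 2
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    r2 = (((X - cx) * dx / a) ** 2 + ((Y - cy) * dy / b) ** 2
          + ((Z - cz) * dz / c) ** 2)
    return r2 <= 1.0


def generate_patient_imaging(truth_row, noise_sd: float, seed,
                             aif: AIFModel | None = None,
                             img: ImagingConfig = ImagingConfig(),
                             visits=("V1", "V4")) -> dict:
    """Synthesize per-visit dynamic studies for one patient's truth record.

    Voxel time-courses are the FXR forward signal plus i.i.d. Gaussian noise;
    pre-injection frames carry only baseline signal, and a co-registered
    proton-density volume is emitted with the companion low-flip-angle,
    long-TR settings. Deterministic given (`truth_row`, `seed`).
    """
    if not (3 <= img.injection_frame):
        raise ValueError("injection frame must be >= 3")
    aif = aif or AIFModel()
    out = {}
    row = truth_row if isinstance(truth_row, dict) else truth_row.to_dict()
    seed_key = [int(seed)] if np.isscalar(seed) else [int(s) for s in seed]
    for vi, visit in enumerate(visits):
        v = visit.lower()
        rng = np.random.default_rng(seed_key + [vi])
        n_frames = int(rng.integers(img.n_frames_range[0], img.n_frames_range[1] + 1))
        if img.injection_frame >= n_frames:
            raise ValueError("injection frame must precede the last frame")
        interval = float(rng.uniform(*img.frame_interval_range_s))
        acq = AcquisitionParams(
            frame_times=np.arange(n_frames) * interval,
            injection_frame=img.injection_frame,
        )
        mask = _ellipsoid_mask(float(row[f"ld_{v}"]), img)
        shape = mask.shape
        nvox = int(mask.sum())

        def jitter(value, cv, size):
            if cv <= 0:
                return np.full(size, value)
            sig = np.sqrt(np.log1p(cv**2))
            return value * np.exp(rng.normal(-sig**2 / 2.0, sig, size))

        kt = jitter(float(row[f"ktrans_{v}"]), img.voxel_jitter_cv, nvox)
        ve = np.minimum(jitter(float(row[f"ve_{v}"]), img.voxel_jitter_cv, nvox), 0.99)
        ti = jitter(float(row[f"tau_i_{v}"]), img.voxel_jitter_cv, nvox)
        t10 = jitter(float(row[f"t10_{v}"]), img.t10_jitter_cv, nvox).clip(0.3, 4.0)

        maps = {}
        for name, arr in (("ktrans", kt), ("ve", ve), ("tau_i", ti)):
            m = np.full(shape, np.nan)
            m[mask] = arr
            maps[name] = m
        maps["kep"] = maps["ktrans"] / maps["ve"]
        t10_map = np.full(shape, np.nan)
        t10_map[mask] = t10

        dce = np.empty(shape + (n_frames,), dtype=np.float32)
        bg = spgr_signal(1.0 / img.background_t10_s, acq.flip_angle_dce,
                         acq.tr_dce, img.s0)
        dce[...] = bg
        for i, idx in enumerate(np.argwhere(mask)):
            pk = PKParams(ktrans=float(kt[i]), ve=float(ve[i]), tau_i=float(ti[i]))
            dce[tuple(idx)] = fxr_forward_timecourse(
                pk, float(t10[i]), acq, aif, img.s0, img.sampling_dt_s)

        pd_vol = np.full(shape, spgr_signal(1.0 / img.background_t10_s,
                                            acq.flip_angle_pd, acq.tr_pd, img.s0),
                         dtype=np.float32)
        pd_vol[mask] = spgr_signal(1.0 / t10, acq.flip_angle_pd, acq.tr_pd, img.s0)

        if noise_sd > 0:
            dce += rng.normal(0.0, noise_sd, dce.shape).astype(np.float32)
            pd_vol += rng.normal(0.0, noise_sd, pd_vol.shape).astype(np.float32)

        out[visit] = DCEStudy(
            patient_id=str(row.get("patient_id", "P000")),
            visit=visit,
            dce=dce,
            pd_volume=pd_vol,
            roi=RoiMask(mask, (img.in_plane_mm, img.in_plane_mm, img.slice_mm),
                        visit=visit),
            t10_true=t10_map,
            truth_maps=maps,
            acq=acq,
            s0=img.s0,
        )
    return out
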