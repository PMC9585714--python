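"""Reproducible simulate -> fit -> metrics -> stats -> report pipeline.

Each stage reads and writes files under a run directory so stages can be
re-run independently; one global seed controls every source of randomness and
the manifest records it together with a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import AcquisitionParams
from .aif import AIFModel
from .morphometry import RoiMask, longest_diameter, percent_change
from .pkfit import FitBounds, ShutterSpeedVoxelModel, summarize_roi
from .recurrence import (
    backwards_stepwise_aic,
    delong_analysis,
    equal_variance_ttest,
    evaluate_model,
    pc1_of_metrics,
)
from .relaxometry import estimate_t10_map
from .synthetic import (
    METRIC_COLUMNS,
    CohortConfig,
    ImagingConfig,
    generate_cohort,
    generate_patient_imaging,
    metrics_from_truth,
)
from . import nifti_io

__all__ = ["FitOptions", "StatsOptions", "RunConfig", "RunManifest",
           "run_pipeline", "write_report", "demo_config"]

GROUP_TABLE_COLUMNS = ["metric", "nonrecurrence_mean", "nonrecurrence_sd",
                       "recurrence_mean", "recurrence_sd", "ttest_p",
                       "ulr_c", "ci_low", "ci_high", "n"]
MODEL_TABLE_COLUMNS = ["model", "added_metric", "wald_p", "roc_auc",
                       "ci_low", "ci_high", "cv_auc", "delong_vs_base_p", "n"]


@dataclass(frozen=True)
class FitOptions:
    starts_per_param: int = 3
    max_fit_voxels: int = 0        # 0 = fit every ROI voxel
    use_true_t10: bool = False
    sampling_dt_s: float = 1.0


@dataclass(frozen=True)
class StatsOptions:
    cv_repeats: int = 100
    cv_folds: int = 5
    stepwise_candidates: tuple = ("rcb_class", "stage", "age")
    stage_ordinal: bool = True
    metrics_source: str = "fitted"   # "fitted" | "truth"


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    aif: AIFModel = field(default_factory=AIFModel)
    fit: FitOptions = field(default_factory=FitOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    seed: int = 0
    visits: tuple = ("V1", "V4")
    write_imaging: bool = True


def demo_config(seed: int = 0) -> RunConfig:
    """Small, fast configuration: 12 patients on a coarse demo voxel grid."""
    return RunConfig(
        cohort=CohortConfig(n_patients=12, recurrence_count=3, seed=seed),
        imaging=ImagingConfig(in_plane_mm=3.0, slice_mm=3.0, max_slices=5,
                              max_ld_mm=60.0),
        fit=FitOptions(starts_per_param=2, max_fit_voxels=30),
        stats=StatsOptions(cv_repeats=20, cv_folds=3),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain({
        "cohort": asdict(config.cohort),
        "imaging": asdict(config.imaging),
        "aif": asdict(config.aif),
        "fit": asdict(config.fit),
        "stats": asdict(config.stats),
        "seed": config.seed,
        "visits": list(config.visits),
        "write_imaging": config.write_imaging,
    })


def config_from_dict(d: dict) -> RunConfig:
    cohort = dict(d.get("cohort", {}))
    if "within_visit_corr" in cohort:
        cohort["within_visit_corr"] = np.asarray(cohort["within_visit_corr"])
    for key in ("pk_group_params",):
        if key in cohort:
            cohort[key] = {
                g: {v: {p: tuple(ms) for p, ms in visits.items()}
                    for v, visits in groups.items()}
                for g, groups in cohort[key].items()
            }
    stats = dict(d.get("stats", {}))
    if "stepwise_candidates" in stats:
        stats["stepwise_candidates"] = tuple(stats["stepwise_candidates"])
    imaging = {k: tuple(v) if isinstance(v, list) else v
               for k, v in dict(d.get("imaging", {})).items()}
    return RunConfig(
        cohort=CohortConfig(**cohort),
        imaging=ImagingConfig(**imaging),
        aif=AIFModel(**d.get("aif", {})),
        fit=FitOptions(**d.get("fit", {})),
        stats=StatsOptions(**stats),
        seed=int(d.get("seed", 0)),
        visits=tuple(d.get("visits", ("V1", "V4"))),
        write_imaging=bool(d.get("write_imaging", True)),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, run_dir: Path) -> None:
    patients, truth = generate_cohort(config.cohort)
    patients.to_csv(run_dir / "cohort.csv", index=False)
    truth.to_csv(run_dir / "truth.csv", index=False)
    if config.write_imaging:
        img_dir = run_dir / "imaging"
        for i, row in truth.iterrows():
            studies = generate_patient_imaging(
                row, noise_sd=config.cohort.noise_sd,
                seed=[config.seed, 1000 + i], aif=config.aif,
                img=config.imaging, visits=config.visits)
            for study in studies.values():
                nifti_io.save_study(study, img_dir)


def _start_grid(levels: int) -> dict:
    full = {"ktrans": (0.02, 0.1, 0.5), "ve": (0.2, 0.5, 0.8),
            "tau_i": (0.2, 0.6, 1.5)}
    if levels >= 3:
        return full
    return {k: (v[0], v[2]) for k, v in full.items()}


def stage_fit(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    truth = pd.read_csv(run_dir / "truth.csv")
    img_dir = run_dir / "imaging"
    grid = _start_grid(config.fit.starts_per_param)
    rows = []
    failures = 0
    for i, row in truth.iterrows():
        rec = {"patient_id": row["patient_id"]}
        for visit in config.visits:
            v = visit.lower()
            dce, pd_vol, mask, frame_times, spacing = nifti_io.load_study_arrays(
                img_dir, row["patient_id"], visit)
            acq = AcquisitionParams(frame_times=frame_times,
                                    injection_frame=config.imaging.injection_frame)
            vox = np.argwhere(mask)
            if config.fit.max_fit_voxels and len(vox) > config.fit.max_fit_voxels:
                rng = np.random.default_rng([config.seed, 2000 + i])
                vox = vox[rng.choice(len(vox), config.fit.max_fit_voxels,
                                     replace=False)]
            sub_mask = np.zeros_like(mask)
            sub_mask[tuple(vox.T)] = True
            if config.fit.use_true_t10:
                t10_map = np.full(mask.shape, float(row[f"t10_{v}"]))
                valid_t10 = sub_mask.copy()
            else:
                baseline = dce[..., 1]  # second baseline frame
                t10_map, valid_t10 = estimate_t10_map(baseline, pd_vol, acq,
                                                      mask=sub_mask)
            maps = {name: np.full(mask.shape, np.nan)
                    for name in ("ktrans", "ve", "tau_i", "kep")}
            fit_ok = np.zeros(mask.shape, dtype=bool)
            for idx in vox:
                j = tuple(idx)
                if not valid_t10[j]:
                    failures += 1
                    continue
                try:
                    res = ShutterSpeedVoxelModel(
                        dce[j], t10_map[j], acq, config.aif,
                        sampling_dt=config.fit.sampling_dt_s,
                    ).fit(FitBounds(), grid)
                except (RuntimeError, ValueError):
                    failures += 1
                    continue
                maps["ktrans"][j] = res.params.ktrans
                maps["ve"][j] = res.params.ve
                maps["tau_i"][j] = res.params.tau_i
                maps["kep"][j] = res.params.kep
                fit_ok[j] = True
            if not fit_ok.any():
                raise StageError("fit", f"no voxel converged for "
                                        f"{row['patient_id']} {visit}")
            maps_dir = run_dir / "maps"
            for name, arr in maps.items():
                nifti_io.save_volume(
                    maps_dir / f"{row['patient_id']}_{visit}_{name}.nii.gz",
                    np.nan_to_num(arr, nan=0.0).astype(np.float32), spacing)
            means, nvox = summarize_roi(maps, sub_mask, fit_ok)
            for name, val in means.items():
                rec[f"{name}_{v}"] = val
            rec[f"n_voxels_{v}"] = nvox
            rec[f"ld_{v}"] = longest_diameter(
                RoiMask(mask, spacing, visit=visit))
        rows.append(rec)
    fitted = pd.DataFrame(rows)
    fitted.to_csv(run_dir / "roi_summary.csv", index=False)
    (run_dir / "fit_log.json").write_text(
        json.dumps({"voxel_fit_failures": failures}, indent=2))
    return fitted


def stage_metrics(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    if config.stats.metrics_source == "truth":
        truth = pd.read_csv(run_dir / "truth.csv")
        metrics = metrics_from_truth(truth)
    else:
        fitted = pd.read_csv(run_dir / "roi_summary.csv")
        metrics = pd.DataFrame({"patient_id": fitted["patient_id"]})
        for p in ("ld", "ktrans", "ve", "kep", "tau_i"):
            metrics[f"{p}_v1"] = fitted[f"{p}_v1"]
            metrics[f"{p}_v4"] = fitted[f"{p}_v4"]
            metrics[f"{p}_v41"] = [
                percent_change(a, b)
                for a, b in zip(fitted[f"{p}_v1"], fitted[f"{p}_v4"])
            ]
        metrics = metrics[["patient_id"] + METRIC_COLUMNS]
    metrics.to_csv(run_dir / "metrics.csv", index=False)
    return metrics


def stage_stats(config: RunConfig, run_dir: Path) -> dict:
    cohort = pd.read_csv(run_dir / "cohort.csv")
    metrics = pd.read_csv(run_dir / "metrics.csv")
    df = cohort.merge(metrics, on="patient_id")
    y = df["recurrence"].to_numpy().astype(int)

    # per-metric group summaries + univariable discrimination
    t2_rows = []
    for metric in METRIC_COLUMNS:
        x = df[metric].to_numpy()
        ok = np.isfinite(x)
        g0 = x[ok & (y == 0)]
        g1 = x[ok & (y == 1)]
        row = {"metric": metric,
               "nonrecurrence_mean": g0.mean() if g0.size else np.nan,
               "nonrecurrence_sd": g0.std(ddof=1) if g0.size > 1 else np.nan,
               "recurrence_mean": g1.mean() if g1.size else np.nan,
               "recurrence_sd": g1.std(ddof=1) if g1.size > 1 else np.nan,
               "n": int(ok.sum())}
        if g0.size >= 2 and g1.size >= 2:
            _, p, _ = equal_variance_ttest(g0, g1)
            dl = delong_analysis(x[ok], y[ok])
            row.update(ttest_p=p, ulr_c=dl.auc, ci_low=dl.ci[0], ci_high=dl.ci[1])
        else:
            row.update(ttest_p=np.nan, ulr_c=np.nan, ci_low=np.nan,
                       ci_high=np.nan)
        t2_rows.append(row)
    group_table = pd.DataFrame(t2_rows)[GROUP_TABLE_COLUMNS]

    # clinicopathological base model and metric-augmented models
    candidates = [c for c in config.stats.stepwise_candidates if c in df.columns]
    if not config.stats.stage_ordinal and "stage" in candidates:
        dummies = pd.get_dummies(df["stage"], prefix="stage", drop_first=True)
        df = pd.concat([df.drop(columns=["stage"]), dummies.astype(float)], axis=1)
        candidates = [c for c in candidates if c != "stage"] + list(dummies.columns)
    selected, _ = backwards_stepwise_aic(df, "recurrence", candidates)
    if not selected:
        selected = ["rcb_class", "age"]
    base = evaluate_model(df, "recurrence", selected,
                          cv_repeats=config.stats.cv_repeats,
                          cv_folds=config.stats.cv_folds, seed=config.seed)
    base_scores = pd.Series(base.scores,
                            index=df[["recurrence"] + selected].dropna().index)

    t3_rows = [{
        "model": "+".join(selected), "added_metric": "",
        "wald_p": np.nan, "roc_auc": base.auc, "ci_low": base.auc_ci[0],
        "ci_high": base.auc_ci[1], "cv_auc": base.cv_auc,
        "delong_vs_base_p": np.nan, "n": base.nobs,
    }]
    for metric in METRIC_COLUMNS:
        if df[metric].notna().sum() < len(df) // 2:
            continue
        rep = evaluate_model(df, "recurrence", selected + [metric],
                             added_metric=metric, reference_scores=base_scores,
                             cv_repeats=config.stats.cv_repeats,
                             cv_folds=config.stats.cv_folds, seed=config.seed)
        t3_rows.append({
            "model": "+".join(selected) + f"+{metric}", "added_metric": metric,
            "wald_p": rep.added_metric_wald_p, "roc_auc": rep.auc,
            "ci_low": rep.auc_ci[0], "ci_high": rep.auc_ci[1],
            "cv_auc": rep.cv_auc, "delong_vs_base_p": rep.delong_vs_reference_p,
            "n": rep.nobs,
        })
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca = pc1_of_metrics(df[METRIC_COLUMNS])
    except ValueError:
        pca = None  # PCA needs more patients than metrics; small demo cohorts skip it
    if pca is not None:
        df["pc1"] = pca.scores.to_numpy()
        rep = evaluate_model(df, "recurrence", selected + ["pc1"],
                             added_metric="pc1", reference_scores=base_scores,
                             cv_repeats=config.stats.cv_repeats,
                             cv_folds=config.stats.cv_folds, seed=config.seed)
        t3_rows.append({
            "model": "+".join(selected) + "+pc1", "added_metric": "pc1",
            "wald_p": rep.added_metric_wald_p, "roc_auc": rep.auc,
            "ci_low": rep.auc_ci[0], "ci_high": rep.auc_ci[1],
            "cv_auc": rep.cv_auc, "delong_vs_base_p": rep.delong_vs_reference_p,
            "n": rep.nobs,
        })
    model_table = pd.DataFrame(t3_rows)[MODEL_TABLE_COLUMNS]
    tables = {"group_comparisons": group_table, "model_performance": model_table}
    write_report(tables, run_dir)
    return tables


def write_report(tables: dict, destination) -> list:
    """Write report tables as CSV plus a human-readable Markdown summary."""
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    written = []
    schema = {"group_comparisons": GROUP_TABLE_COLUMNS, "model_performance": MODEL_TABLE_COLUMNS}
    for name, df in tables.items():
        required = schema.get(name)
        if required is not None and list(df.columns) != required:
            raise ValueError(f"{name} violates the report schema: "
                             f"{list(df.columns)} != {required}")
        path = destination / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    md = ["# Recurrence-prediction report", ""]
    for name, df in tables.items():
        md += [f"## {name}", "", df.to_markdown(index=False), ""]
    report_path = destination / "report.md"
    report_path.write_text("\n".join(md))
    written.append(report_path)
    return written


STAGES = ("simulate", "fit", "metrics", "stats")


def run_pipeline(config: RunConfig, run_dir, stages=STAGES) -> RunManifest:
    """Execute the requested stages in order and write the run manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, run_dir / "config.yaml")
    cfg_yaml = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        version=__version__,
        seed=config.seed,
    )
    funcs = {"simulate": stage_simulate, "fit": stage_fit,
             "metrics": stage_metrics, "stats": stage_stats}
    needs_fit = config.stats.metrics_source == "fitted" and config.write_imaging
    for stage in stages:
        if stage == "fit" and not needs_fit:
            manifest.stages[stage] = "skipped (truth metrics)"
            continue
        try:
            funcs[stage](config, run_dir)
        except StageError:
            manifest.stages[stage] = "failed"
            manifest.save(run_dir / "manifest.json")
            raise
        except Exception as exc:
            manifest.stages[stage] = "failed"
            manifest.save(run_dir / "manifest.json")
            raise StageError(stage, str(exc)) from exc
        manifest.stages[stage] = "ok"
    manifest.outputs = sorted(
        str(p.relative_to(run_dir)) for p in run_dir.rglob("*") if p.is_file())
    manifest.save(run_dir / "manifest.json")
    return manifest
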