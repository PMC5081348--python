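"""End-to-end orchestration: simulate -> qc -> glm -> mvpa -> inference.

``run_pipeline`` executes the whole analysis on synthetic data from a single
config and writes a structured report plus artifact tables.  Individual
stages are also exposed so the CLI can run them separately on artifact
directories.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import DEFAULT_ROI_SIZES, GridSpec, ROI_LABELS, RoiMask, build_atlas
from .bold import BoldRun, EffectSpec, HrfParams, NoiseParams, RoiEffect, simulate_subject
from .design import DesignParams, ExperimentDesign, make_experiment_design
from .glm import (
    CONTRAST_ADAPTATION,
    CONTRAST_LARGE_MINUS_SMALL,
    GlmConfig,
    GlmFit,
    compute_contrast,
    fit_run,
    smooth_volume,
)
from .inference import InferenceConfig, group_voxel_contrast, paired_t, signflip_maxt
from .mvpa import MvpaConfig, accuracy_vs_size, loro_accuracy, sample_set_from_betas
from .oculo import BadBehavior, OculoParams, simulate_trace
from .qc import SaccadeClassRules, apply_exclusions, qc_run, qc_table

log = logging.getLogger("saccdecode")

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    n_subjects: int = 17
    seed: int = 0
    design: DesignParams = field(default_factory=DesignParams)
    oculo: OculoParams = field(default_factory=OculoParams)
    effects: EffectSpec = field(default_factory=EffectSpec.paper_like)
    noise: NoiseParams = field(default_factory=NoiseParams)
    glm: GlmConfig = field(default_factory=GlmConfig)
    mvpa: MvpaConfig = field(default_factory=MvpaConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    roi_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROI_SIZES))
    runs_per_subject_schedule: tuple[int, ...] | None = None  # e.g. 13 x 5 + 4 x 6
    bad_behavior: BadBehavior = field(default_factory=BadBehavior)
    feature_curves: bool = False
    run_univariate: bool = True
    run_eye_qc: bool = True
    n_background_voxels: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.runs_per_subject_schedule is not None and len(
            self.runs_per_subject_schedule
        ) != self.n_subjects:
            raise ValueError("runs_per_subject_schedule length must equal n_subjects")

    def runs_for(self, subject_index: int) -> int:
        if self.runs_per_subject_schedule is not None:
            return self.runs_per_subject_schedule[subject_index]
        return self.design.runs_per_subject


# --------------------------------------------------------------------------
# config (de)serialisation

_SECTION_TYPES = {
    "design": DesignParams,
    "oculo": OculoParams,
    "noise": NoiseParams,
    "glm": GlmConfig,
    "mvpa": MvpaConfig,
    "inference": InferenceConfig,
    "grid": GridSpec,
    "bad_behavior": BadBehavior,
}


def _tupleise(cls, data: dict):
    """Build a dataclass from a dict, converting lists back to tuples."""
    kwargs = {}
    for key, value in data.items():
        kwargs[key] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    out = asdict(config)
    out["effects"] = {
        "mixed_rule": config.effects.mixed_rule,
        "subject_gain_sd": config.effects.subject_gain_sd,
        "rois": {label: asdict(eff) for label, eff in config.effects.rois.items()},
    }
    return out


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _tupleise(cls, data.pop(name))
    if "effects" in data:
        eff = data.pop("effects")
        rois = {label: RoiEffect(**spec) for label, spec in eff.get("rois", {}).items()}
        kwargs["effects"] = EffectSpec(
            rois=rois,
            mixed_rule=eff.get("mixed_rule", "mean"),
            subject_gain_sd=eff.get("subject_gain_sd", 0.0),
        )
    if "runs_per_subject_schedule" in data and data["runs_per_subject_schedule"] is not None:
        data["runs_per_subject_schedule"] = tuple(data["runs_per_subject_schedule"])
    return PipelineConfig(**data, **kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# --------------------------------------------------------------------------
# per-subject processing

def _subject_id(i: int) -> str:
    return f"sub-{i + 1:02d}"


@dataclass
class SubjectResult:
    subject_id: str
    design: ExperimentDesign
    qc: pd.DataFrame | None
    block_fits: dict[int, GlmFit]
    localizer: dict[int, np.ndarray]  # run -> all-saccades>rest map (atlas voxels)
    condition_betas: dict[str, np.ndarray]  # condition -> mean map across runs
    behavioral: dict[str, float]
    voxel_indices: np.ndarray


def process_subject(
    config: PipelineConfig,
    masks: dict[str, RoiMask],
    subject_index: int,
    seed_seq: np.random.SeedSequence,
) -> SubjectResult:
    subject_id = _subject_id(subject_index)
    design_seed, oculo_seed, bold_seed = seed_seq.spawn(3)
    design = make_experiment_design(
        config.design,
        subject_id=subject_id,
        seed=design_seed,
        n_runs=config.runs_for(subject_index),
    )

    qc_df = None
    behavioral: dict[str, float] = {}
    if config.run_eye_qc:
        rules = SaccadeClassRules()
        results = {}
        amp_small, amp_large, vel_small, vel_large = [], [], [], []
        trace_seeds = oculo_seed.spawn(len(design.runs))
        for run, tseed in zip(design.runs, trace_seeds):
            trace = simulate_trace(
                run, config.oculo, tseed, bad=config.bad_behavior, subject_id=subject_id
            )
            res = qc_run(trace, run, rules)
            results[(subject_id, run.run_id)] = res
            for blk_res, block in zip(res, run.blocks):
                if not blk_res.valid or block.size_class not in ("small", "large"):
                    continue
                outward = blk_res.events[0::2]
                amps = [e.endpoint_deg for e in outward]
                vels = [e.peak_velocity_deg_s for e in outward]
                (amp_small if block.size_class == "small" else amp_large).extend(amps)
                (vel_small if block.size_class == "small" else vel_large).extend(vels)
        qc_df = qc_table(results)
        behavioral = {
            "endpoint_var_small": float(np.var(amp_small, ddof=1)) if len(amp_small) > 1 else np.nan,
            "endpoint_var_large": float(np.var(amp_large, ddof=1)) if len(amp_large) > 1 else np.nan,
            "velocity_small": float(np.mean(vel_small)) if vel_small else np.nan,
            "velocity_large": float(np.mean(vel_large)) if vel_large else np.nan,
        }

    bold_runs, _ = simulate_subject(
        design,
        masks,
        effects=config.effects,
        noise=config.noise,
        seed=bold_seed,
        n_background_voxels=config.n_background_voxels,
    )

    block_fits: dict[int, GlmFit] = {}
    localizer: dict[int, np.ndarray] = {}
    per_block = replace(config.glm, mode="per_block")
    for run, bold in zip(design.runs, bold_runs):
        fit = fit_run(bold, run, per_block)
        block_fits[run.run_id] = fit
        main = np.array([fit.beta(f"block_{b.index:02d}") for b in run.blocks])
        localizer[run.run_id] = main.mean(axis=0)

    condition_betas: dict[str, np.ndarray] = {}
    if config.run_univariate:
        per_cond = replace(config.glm, mode="per_condition")
        acc: dict[str, list[np.ndarray]] = {}
        for run, bold in zip(design.runs, bold_runs):
            fit = fit_run(bold, run, per_cond)
            for cond in {b.condition for b in run.blocks}:
                acc.setdefault(cond, []).append(fit.beta(cond))
        condition_betas = {c: np.mean(v, axis=0) for c, v in acc.items()}

    return SubjectResult(
        subject_id=subject_id,
        design=design,
        qc=qc_df,
        block_fits=block_fits,
        localizer=localizer,
        condition_betas=condition_betas,
        behavioral=behavioral,
        voxel_indices=bold_runs[0].voxel_indices,
    )


def _roi_slices(masks: dict[str, RoiMask]) -> dict[str, slice]:
    slices = {}
    pos = 0
    for label in ROI_LABELS:
        if label in masks:
            slices[label] = slice(pos, pos + masks[label].size)
            pos += masks[label].size
    return slices


def _smooth_roi_maps(
    values: np.ndarray, voxel_indices: np.ndarray, grid: GridSpec, fwhm_mm: float
) -> np.ndarray:
    """Embed atlas-voxel values in the full grid, smooth, re-extract."""
    vol = np.zeros(grid.shape)
    vol.reshape(-1)[voxel_indices] = values
    return smooth_volume(vol, fwhm_mm, grid).reshape(-1)[voxel_indices]


# --------------------------------------------------------------------------
# full pipeline

def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return the report dict (also written to disk)."""
    t_start = time.time()
    timings: dict[str, float] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    atlas_seed, *subject_seeds = ss.spawn(config.n_subjects + 1)

    t0 = time.time()
    masks = build_atlas(config.grid, config.roi_sizes, seed=atlas_seed.generate_state(1)[0])
    slices = _roi_slices(masks)
    timings["atlas"] = time.time() - t0

    t0 = time.time()
    subjects = [
        process_subject(config, masks, i, subject_seeds[i]) for i in range(config.n_subjects)
    ]
    timings["simulate+glm"] = time.time() - t0

    # ---- exclusions --------------------------------------------------------
    t0 = time.time()
    retained_by_subject: dict[str, dict[int, set[int]]] = {}
    if config.run_eye_qc:
        full_qc = pd.concat([s.qc for s in subjects], ignore_index=True)
        retained, exclusion_report = apply_exclusions(full_qc)
        for _, row in retained.iterrows():
            retained_by_subject.setdefault(row["subject"], {}).setdefault(
                int(row["run"]), set()
            ).add(int(row["block"]))
    else:
        full_qc = pd.DataFrame(columns=["subject", "run", "block", "valid", "reason"])
        exclusion_report = pd.DataFrame(columns=["level", "subject", "run", "block", "reason"])
        for s in subjects:
            retained_by_subject[s.subject_id] = {
                r.run_id: {b.index for b in r.blocks} for r in s.design.runs
            }
    kept_subjects = [s for s in subjects if retained_by_subject.get(s.subject_id)]
    timings["qc"] = time.time() - t0

    # ---- MVPA --------------------------------------------------------------
    t0 = time.time()
    acc_rows = []
    curve_rows = []
    for s in kept_subjects:
        designs = {r.run_id: r for r in s.design.runs}
        retained_runs = retained_by_subject[s.subject_id]
        for label in slices:
            samples = sample_set_from_betas(
                {r: f for r, f in s.block_fits.items() if r in retained_runs},
                designs,
                slices[label],
                retained_blocks=retained_runs,
                subject_id=s.subject_id,
                roi=label,
            )
            acc = loro_accuracy(samples, config.mvpa)
            acc_rows.append(
                {"subject": s.subject_id, "roi": label, "n_features": samples.n_features,
                 "accuracy_pct": acc}
            )
            if config.feature_curves:
                localizer = {
                    r: s.localizer[r][slices[label]] for r in sorted(retained_runs)
                }
                curve = accuracy_vs_size(samples, localizer, config.mvpa)
                for _, row in curve.iterrows():
                    curve_rows.append(
                        {"subject": s.subject_id, "roi": label,
                         "n_features": int(row["n_features"]),
                         "accuracy_pct": row["accuracy_pct"]}
                    )
    accuracy = pd.DataFrame(acc_rows)
    curves = pd.DataFrame(curve_rows)
    timings["mvpa"] = time.time() - t0

    # ---- group inference ---------------------------------------------------
    t0 = time.time()
    acc_wide = accuracy.pivot(index="subject", columns="roi", values="accuracy_pct")
    acc_wide = acc_wide[[label for label in ROI_LABELS if label in acc_wide.columns]]
    perm = signflip_maxt(acc_wide, config.inference)
    roi_stats = perm.frame()
    roi_stats.insert(1, "mean_accuracy_pct", acc_wide.mean(axis=0).to_numpy())

    curve_stats = pd.DataFrame()
    if config.feature_curves and not curves.empty:
        stat_rows = []
        for k, grp in curves.groupby("n_features"):
            wide = grp.pivot(index="subject", columns="roi", values="accuracy_pct").dropna(axis=1)
            if wide.shape[0] < 2:
                continue
            res = signflip_maxt(wide, config.inference)
            for label, t, p in zip(res.labels, res.t_obs, res.p_fwe):
                stat_rows.append(
                    {"n_features": int(k), "roi": label, "t_obs": t, "p_fwe": p,
                     "critical_t": res.critical_t}
                )
        curve_stats = pd.DataFrame(stat_rows)
    timings["inference"] = time.time() - t0

    # ---- univariate and adaptation contrasts -------------------------------
    t0 = time.time()
    contrast_summary = []
    if config.run_univariate and kept_subjects:
        voxel_indices = kept_subjects[0].voxel_indices
        for name, weights, tail in (
            ("large_minus_small", CONTRAST_LARGE_MINUS_SMALL, "greater"),
            ("adaptation_mixed_minus_same", CONTRAST_ADAPTATION, "greater"),
        ):
            maps = []
            for s in kept_subjects:
                cmap = compute_contrast(s.condition_betas, weights)
                if config.glm.smoothing_fwhm_mm > 0:
                    cmap = _smooth_roi_maps(
                        cmap, voxel_indices, config.grid, config.glm.smoothing_fwhm_mm
                    )
                maps.append(cmap)
            maps = np.array(maps)
            for label in slices:
                res = group_voxel_contrast(
                    maps[:, slices[label]], masks[label], config.inference, tail=tail
                )
                contrast_summary.append(
                    {
                        "contrast": name,
                        "roi": label,
                        "n_survivors": int(res.survivors.sum()),
                        "max_t": float(res.t.max()) if res.t.size else np.nan,
                        "n_clusters": len(res.clusters),
                        "largest_cluster": len(res.clusters[0]) if res.clusters else 0,
                    }
                )
    contrasts = pd.DataFrame(contrast_summary)
    timings["contrasts"] = time.time() - t0

    # ---- behavioural comparisons -------------------------------------------
    behavioral = {}
    if config.run_eye_qc:
        beh = pd.DataFrame([s.behavioral for s in kept_subjects]).dropna()
        if len(beh) >= 2:
            var_test = paired_t(beh["endpoint_var_large"], beh["endpoint_var_small"])
            vel_test = paired_t(beh["velocity_large"], beh["velocity_small"])
            from scipy import stats as sps

            behavioral = {
                "endpoint_variance_t": var_test.t,
                "endpoint_variance_df": var_test.df,
                "endpoint_variance_p": float(sps.t.sf(var_test.t, var_test.df)),
                "velocity_t": vel_test.t,
                "velocity_df": vel_test.df,
                "velocity_p": float(sps.t.sf(vel_test.t, vel_test.df)),
            }

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "n_subjects_retained": len(kept_subjects),
        "exclusions": exclusion_report.to_dict(orient="records"),
        "accuracy_table": accuracy.to_dict(orient="records"),
        "roi_stats": roi_stats.to_dict(orient="records"),
        "significant_rois": [
            label for label, sig in zip(perm.labels, perm.significant) if sig
        ],
        "feature_curve_stats": curve_stats.to_dict(orient="records"),
        "contrasts": contrasts.to_dict(orient="records"),
        "behavioral": behavioral,
        "centering": config.mvpa.centering,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t_start, 3),
        "config": config_to_dict(config),
    }

    if out is not None:
        accuracy.to_csv(out / "accuracy.tsv", sep="\t", index=False)
        if not curves.empty:
            curves.to_csv(out / "accuracy_curves.tsv", sep="\t", index=False)
        full_qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        roi_stats.to_csv(out / "roi_stats.tsv", sep="\t", index=False)
        if not curve_stats.empty:
            curve_stats.to_csv(out / "curve_stats.tsv", sep="\t", index=False)
        if not contrasts.empty:
            contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)
        save_config(config, out / "config.yaml")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        log.info("report written to %s", out / "report.json")

    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
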