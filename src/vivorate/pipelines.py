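"""Reproducible, config-driven runs over the measurement modules.

Each run takes a validated configuration (unknown keys rejected), an
explicit seed for anything random, and writes its artifacts plus a run
manifest (config hash, package version, timestamp, output list) into the
requested directory. On failure, partial outputs are removed. There is no
command-line layer: configurations are plain dicts (or the pydantic
models below) passed to :func:`run` from Python, as in the ``examples/``
scripts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import tempfile
import time
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

__all__ = [
    "SimulateVideoConfig",
    "RespirometryConfig",
    "LungCtConfig",
    "SimulateCohortConfig",
    "CohortAnalysisConfig",
    "RunResult",
    "run",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateVideoConfig(_StrictModel):
    task: Literal["simulate_video"] = "simulate_video"
    out_dir: str
    seed: int = 0
    rate_bpm: float = 150.0
    amplitude_px: float = 2.0
    fps: float = 30.0
    duration_s: float = 20.0
    jitter_cv: float = 0.0
    noise_sd: float = 0.0


class RespirometryConfig(_StrictModel):
    task: Literal["respirate"] = "respirate"
    out_dir: str
    videos: list[str]                  # clip directories (PNG stack + sidecar)
    roi: str = "auto"                  # "auto" or path to a JSON polygon list
    band_bpm: tuple[float, float] = (60.0, 400.0)
    min_clips: int = 5


class LungCtConfig(_StrictModel):
    task: Literal["lungct"] = "lungct"
    out_dir: str
    volume: str
    units: Literal["density", "hu"] = "density"


class SimulateCohortConfig(_StrictModel):
    task: Literal["simulate_cohort"] = "simulate_cohort"
    out_dir: str
    seed: int = 0
    field_multiplier: float = 1.0
    n_per_dose: int = 20
    doses_gy: tuple[float, ...] = (0.0, 9.0, 10.0, 10.5, 11.0, 12.0, 13.0)
    ed50_gy: float = 11.0
    hill_slope: float = 12.0


class CohortAnalysisConfig(_StrictModel):
    task: Literal["cohort"] = "cohort"
    out_dir: str
    cohort_csv: str
    control_dose: float = 0.0
    timepoint: int = 5
    fallback: int = 4
    k_sd: float = 3.0


RunConfig = Union[
    SimulateVideoConfig,
    RespirometryConfig,
    LungCtConfig,
    SimulateCohortConfig,
    CohortAnalysisConfig,
]

_TASKS: dict[str, type[_StrictModel]] = {
    "simulate_video": SimulateVideoConfig,
    "respirate": RespirometryConfig,
    "lungct": LungCtConfig,
    "simulate_cohort": SimulateCohortConfig,
    "cohort": CohortAnalysisConfig,
}


@dataclasses.dataclass
class RunResult:
    out_dir: Path
    outputs: list[Path]
    manifest: dict


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=float))


def run(config: dict | RunConfig) -> RunResult:
    """Execute one configured task and write artifacts plus a manifest.

    Raises ``ValueError``/``ValidationError`` for an unknown task or
    unknown/invalid fields; outputs are staged in a temporary directory
    and only moved into ``out_dir`` on success.
    """
    if isinstance(config, _StrictModel):
        cfg = config
    else:
        task = config.get("task")
        if task not in _TASKS:
            raise ValueError(f"unknown task {task!r}; expected one of {sorted(_TASKS)}")
        cfg = _TASKS[task].model_validate(config)

    out_dir = Path(cfg.out_dir)
    parent = out_dir.parent if out_dir.parent.exists() else None
    staging = Path(tempfile.mkdtemp(prefix=".vivorate-", dir=parent))
    try:
        outputs = _DISPATCH[cfg.task](cfg, staging)
        from . import __version__

        manifest = {
            "task": cfg.task,
            "config": cfg.model_dump(),
            "config_hash": _config_hash(cfg.model_dump()),
            "package_version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": [p.name for p in outputs],
        }
        _json_dump(manifest, staging / "manifest.json")
        out_dir.mkdir(parents=True, exist_ok=True)
        final = []
        for p in [*outputs, staging / "manifest.json"]:
            dest = out_dir / p.name
            if dest.exists():
                shutil.rmtree(dest) if dest.is_dir() else dest.unlink()
            shutil.move(str(p), dest)
            final.append(dest)
        return RunResult(out_dir=out_dir, outputs=final[:-1], manifest=manifest)
    finally:
        shutil.rmtree(staging, ignore_errors=True)


# ---------------------------------------------------------------------------
# Task implementations


def _run_simulate_video(cfg: SimulateVideoConfig, staging: Path) -> list[Path]:
    from .synthetic_video import BreathingScenario, render_breathing_clip, write_frames

    scenario = BreathingScenario(
        rate_bpm=cfg.rate_bpm,
        amplitude_px=cfg.amplitude_px,
        fps=cfg.fps,
        duration_s=cfg.duration_s,
        jitter_cv=cfg.jitter_cv,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )
    seq, truth = render_breathing_clip(scenario)
    clip_dir = staging / "clip"
    write_frames(clip_dir, seq)
    _json_dump(
        {
            "true_rate_bpm": truth.true_rate_bpm,
            "breath_onsets_s": truth.breath_onsets_s.tolist(),
            "displacement_series": truth.displacement_series.tolist(),
        },
        staging / "ground_truth.json",
    )
    return [clip_dir, staging / "ground_truth.json"]


def _run_respirate(cfg: RespirometryConfig, staging: Path) -> list[Path]:
    from . import respirometry as rp
    from .video import read_frames

    estimates = []
    outputs = []
    for i, video in enumerate(cfg.videos):
        seq = read_frames(video)
        if cfg.roi == "auto":
            rois = [rp.auto_roi(seq)]
        else:
            polys = json.loads(Path(cfg.roi).read_text())
            rois = [rp.RoiContour(np.asarray(p)) for p in polys]
        seeds = rp.detect_features(seq, rois)
        tracks = rp.track_features(seq, seeds)
        wave = rp.build_waveform(tracks, seq.fps)
        est = rp.estimate_rate(wave, band_bpm=cfg.band_bpm)
        est.n_points_used = len(tracks)
        estimates.append(est)
        wave_csv = staging / f"waveform_{i:02d}.csv"
        pd.DataFrame(
            {"t_s": np.arange(len(wave.samples)) / wave.fps, "amplitude": wave.samples}
        ).to_csv(wave_csv, index=False)
        outputs.append(wave_csv)
    summary = rp.summarize_mouse(estimates, min_clips=cfg.min_clips)
    _json_dump(
        {
            "summary_bpm": summary.summary_bpm,
            "n_qc_passing_clips": summary.n_clips,
            "clips": [dataclasses.asdict(e) for e in summary.clip_estimates],
        },
        staging / "rates.json",
    )
    return [*outputs, staging / "rates.json"]


def _run_lungct(cfg: LungCtConfig, staging: Path) -> list[Path]:
    from .lung_cbct import compute_lung_metrics
    from .volume_io import read_volume

    vol = read_volume(cfg.volume, units=cfg.units)
    metrics = compute_lung_metrics(vol)
    _json_dump(
        {
            "healthy_volume_cm3": metrics.healthy_volume_cm3,
            "roi_densities_gcc": metrics.roi_densities,
            "mean_density_gcc": metrics.mean_density,
        },
        staging / "lung_metrics.json",
    )
    return [staging / "lung_metrics.json"]


def _run_simulate_cohort(cfg: SimulateCohortConfig, staging: Path) -> list[Path]:
    from .cohort_stats import CohortConfig, simulate_cohort, write_cohort_csv

    records, truth = simulate_cohort(
        CohortConfig(
            seed=cfg.seed,
            field_multiplier=cfg.field_multiplier,
            n_per_dose=cfg.n_per_dose,
            doses_gy=cfg.doses_gy,
            ed50_gy=cfg.ed50_gy,
            hill_slope=cfg.hill_slope,
        )
    )
    write_cohort_csv(staging / "cohort.csv", records)
    _json_dump(
        {
            "responder": truth.responder,
            "ed50_by_field": {str(k): v for k, v in truth.ed50_by_field.items()},
        },
        staging / "cohort_truth.json",
    )
    return [staging / "cohort.csv", staging / "cohort_truth.json"]


def _run_cohort_analysis(cfg: CohortAnalysisConfig, staging: Path) -> list[Path]:
    from . import cohort_stats as cs

    records = cs.read_cohort_csv(cfg.cohort_csv)
    frame = cs.records_to_frame(records)
    cutoffs = cs.cutoffs_from_controls(
        frame, timepoint=cfg.timepoint, k=cfg.k_sd, control_dose=cfg.control_dose
    )
    dich = cs.dichotomize(records, cutoffs, timepoint=cfg.timepoint, fallback=cfg.fallback)

    pd.DataFrame(
        [{"metric": c.metric, "cutoff": c.value, "direction": c.direction} for c in cutoffs.values()]
    ).to_csv(staging / "cutoffs.csv", index=False)

    results: dict = {"cutoffs": {c.metric: c.value for c in cutoffs.values()}}
    response_tables = []
    for metric in cs.METRIC_DIRECTIONS:
        if f"{metric}_abnormal" not in dich.columns:
            continue
        pct = cs.response_percentages(dich, metric)
        pct.insert(0, "metric", metric)
        response_tables.append(pct)
        try:
            comp = cs.ed50_comparison_from_cohort(
                records, cutoffs, metric=metric, timepoint=cfg.timepoint, fallback=cfg.fallback
            )
            results[metric] = {
                "ed50_0t_gy": comp.ed50_0t,
                "ed50_15t_gy": comp.ed50_15t,
                "f_stat": comp.f_stat,
                "p_value": comp.p_value,
            }
        except ValueError as exc:
            results[metric] = {"error": str(exc)}
    pd.concat(response_tables).to_csv(staging / "dose_response.csv", index=False)

    anim = frame.drop_duplicates("id")
    arm0 = anim[anim["field_t"] == 0.0]
    arm15 = anim[anim["field_t"] == 1.5]
    chi2, p = cs.km_logrank(
        arm0["survival_days"], arm0["event"], arm15["survival_days"], arm15["event"]
    )
    results["logrank_0t_vs_15t"] = {"chi2": chi2, "p_value": p}
    _json_dump(results, staging / "analysis.json")
    return [staging / "cutoffs.csv", staging / "dose_response.csv", staging / "analysis.json"]


_DISPATCH = {
    "simulate_video": _run_simulate_video,
    "respirate": _run_respirate,
    "lungct": _run_lungct,
    "simulate_cohort": _run_simulate_cohort,
    "cohort": _run_cohort_analysis,
}
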