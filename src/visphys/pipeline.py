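"""YAML-configured pipeline orchestration with stage resume and manifests.

Two pipelines: ``run_rf_pipeline`` (epochs -> site selection -> maps and RF
estimates -> subsampling analysis) and ``run_behavior_pipeline`` (gaze
calibration -> session quality -> psychometric fits).  Each stage writes its
artifacts into the output directory and is skipped on rerun if they already
exist, so a pipeline resumes from the first missing stage.  A manifest with
the config hash and per-artifact digests is written at the end; reruns with
identical config and inputs produce identical digests for deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as vio
from . import __version__
from .eye_tracking import (
    estimate_cluster_anchors,
    fit_calibration,
    apply_calibration,
    session_accuracy_precision,
    CalibrationModel,
    CalibrationTargets,
)
from .geometry import MonitorSpec
from .neural_preproc import reject_artifacts, select_responsive_sites
from .psychometrics import summarize_conditions, fit_logistic, acuity_threshold
from .rf_mapping import (
    condition_profiles,
    fit_gaussian_profile,
    fit_vonmises_profile,
    rf_estimate,
    reverse_correlation_map,
    combine_maps,
    subsample_analysis,
)
from .simulate import (
    GroundTruthRF,
    GazeSessionSpec,
    ObserverSpec,
    simulate_rf_epochs,
    simulate_gaze_session,
    simulate_observer,
)
from .stimuli import build_catalog

log = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MonitorConfig(_Strict):
    width_px: int = 1680
    height_px: int = 1050
    px_per_deg: float = 27.854
    distance_mm: float = 450.0
    refresh_hz: float = 120.0
    raster_scale: float = 0.1  # analysis raster downscaling factor

    def spec(self) -> MonitorSpec:
        return MonitorSpec(
            width_px=self.width_px,
            height_px=self.height_px,
            px_per_deg=self.px_per_deg,
            distance_mm=self.distance_mm,
            refresh_hz=self.refresh_hz,
        ).scaled(self.raster_scale)


class CatalogConfig(_Strict):
    step_deg: float = 4.5
    subtense_deg: float = 9.0
    inner_start_deg: float = 0.5


class RFSimConfig(_Strict):
    eccentricity: float = 6.0
    polar_angle: float = 120.0
    fwhm_e: float = 2.0
    fwhm_c: float = 2.0
    gain: float = 5.0
    baseline: float = 1.0
    noise_sd: float = 1.0
    n_reps: int = 20

    def truth(self) -> GroundTruthRF:
        return GroundTruthRF(
            eccentricity=self.eccentricity,
            polar_angle=self.polar_angle,
            fwhm_e=self.fwhm_e,
            fwhm_c=self.fwhm_c,
            gain=self.gain,
            baseline=self.baseline,
            noise_sd=self.noise_sd,
        )


class PreprocConfig(_Strict):
    artifact_factor: float = 10.0
    alpha: float = 0.01
    min_conditions: int = 3


class AnalysisConfig(_Strict):
    response_window: tuple[float, float] = (0.0, 100.0)
    baseline_window: tuple[float, float] = (-100.0, 0.0)
    max_reps: int = 9
    n_draws: int = 100
    n_boot: int = 10000
    run_subsample: bool = True


class GazeSimConfig(_Strict):
    n_trials: int = 200
    noise_sd_deg: float = 0.3
    drift_sd_deg: float = 0.0


class ObserverSimConfig(_Strict):
    n_trials: int = 5000
    hit_alpha: float = 6.4
    hit_lambda: float = 95.0
    hit_beta: float = 5.0
    rt_alpha: float = 5.2
    rt_beta: float = 5.0
    rt_low_ms: float = 132.0
    rt_high_ms: float = 245.0
    rt_noise_sd: float = 20.0


class PipelineConfig(_Strict):
    """Validated configuration for both pipelines; unknown keys rejected."""

    monitor: MonitorConfig = MonitorConfig()
    catalog: CatalogConfig = CatalogConfig()
    rf_sim: RFSimConfig = RFSimConfig()
    preproc: PreprocConfig = PreprocConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    gaze_sim: GazeSimConfig = GazeSimConfig()
    observer_sim: ObserverSimConfig = ObserverSimConfig()
    seed: int = 0
    epochs_path: Optional[str] = None  # load instead of simulating
    gaze_path: Optional[str] = None
    trials_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()


def _write_manifest(out_dir: Path, config: PipelineConfig, artifacts: dict[str, Path]) -> dict:
    manifest = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "seed": config.seed,
        "artifacts": {name: _digest(p) for name, p in artifacts.items() if p.exists()},
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    tmp = out_dir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=1))
    tmp.replace(out_dir / "manifest.json")  # atomic at run end
    return manifest


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_rf_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Simulated-or-loaded epochs -> sites -> RF estimates -> subsampling."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    monitor = config.monitor.spec()
    catalog = build_catalog(
        monitor,
        step_deg=config.catalog.step_deg,
        subtense_deg=config.catalog.subtense_deg,
        inner_start_deg=config.catalog.inner_start_deg,
    )
    artifacts: dict[str, Path] = {}

    epochs_bin = out / "epochs.bin"
    artifacts["epochs"] = epochs_bin
    try:
        if not epochs_bin.exists():
            if config.epochs_path:
                epochs = vio.read_epochs(config.epochs_path)
            else:
                epochs = simulate_rf_epochs(
                    config.rf_sim.truth(), catalog, n_reps=config.rf_sim.n_reps, rng_seed=config.seed
                )
            vio.write_epochs(epochs, epochs_bin)
        else:
            log.info("resuming: epochs exist")
        epochs = vio.read_epochs(epochs_bin)
    except (OSError, ValueError) as e:
        raise StageError("epochs", str(e)) from e

    sites_json = out / "sites.json"
    artifacts["sites"] = sites_json
    try:
        if not sites_json.exists():
            epochs = reject_artifacts(epochs, factor=config.preproc.artifact_factor)
            mask = select_responsive_sites(
                epochs,
                catalog.annulus_ids,
                catalog.wedge_ids,
                alpha=config.preproc.alpha,
                min_conditions=config.preproc.min_conditions,
            )
            sites_json.write_text(json.dumps({"selected": mask.astype(int).tolist()}))
            log.info("site selection: %d/%d channels kept", int(mask.sum()), mask.size)
        selected = np.array(json.loads(sites_json.read_text())["selected"], dtype=bool)
    except ValueError as e:
        raise StageError("site_selection", str(e)) from e

    est_csv = out / "estimates.csv"
    artifacts["estimates"] = est_csv
    try:
        if not est_csv.exists():
            if not selected.any():
                log.warning("no stimulus-driven sites; estimate tables will be empty")
            rows = []
            for ch in np.where(selected)[0]:
                ann, wdg = condition_profiles(epochs, catalog, channel=int(ch))
                gfit = fit_gaussian_profile(ann)
                vfit = fit_vonmises_profile(wdg)
                est = rf_estimate(gfit, vfit)
                amap, wmap = reverse_correlation_map(epochs, catalog, channel=int(ch))
                combined = combine_maps(amap, wmap)
                rows.append(
                    {
                        "site": int(ch),
                        "eccentricity": est.peak_eccentricity,
                        "polar_angle": est.polar_angle,
                        "rfs_e": est.rfs_e,
                        "rfs_c": est.rfs_c,
                        "rf_size": est.rf_size,
                        "map_max": combined.values.max(),
                        "flags": ";".join(est.flags),
                    }
                )
            pd.DataFrame.from_records(rows).to_csv(est_csv, index=False)
    except ValueError as e:
        raise StageError("estimates", str(e)) from e

    if config.analysis.run_subsample:
        sub_csv = out / "subsample.csv"
        artifacts["subsample"] = sub_csv
        try:
            if not sub_csv.exists():
                frames = []
                for ch in np.where(selected)[0]:
                    _, summary, _ = subsample_analysis(
                        epochs,
                        catalog,
                        channel=int(ch),
                        max_reps=config.analysis.max_reps,
                        n_draws=config.analysis.n_draws,
                        n_boot=config.analysis.n_boot,
                        rng_seed=config.seed,
                    )
                    summary["site"] = int(ch)
                    frames.append(summary)
                table = (
                    pd.concat(frames, ignore_index=True)
                    if frames
                    else pd.DataFrame(columns=["r", "measure", "mean", "ci_lo", "ci_hi", "site"])
                )
                table.to_csv(sub_csv, index=False)
        except ValueError as e:
            raise StageError("subsample", str(e)) from e

    return _write_manifest(out, config, artifacts)


def run_behavior_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Gaze calibration + session quality + psychometric threshold report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    gaze_csv = out / "gaze_raw.csv"
    artifacts["gaze_raw"] = gaze_csv
    spec = GazeSessionSpec(
        noise_sd_deg=config.gaze_sim.noise_sd_deg, drift_sd_deg=config.gaze_sim.drift_sd_deg
    )
    try:
        if not gaze_csv.exists():
            if config.gaze_path:
                gaze = vio.read_gaze(config.gaze_path)
                targets = CalibrationTargets()
            else:
                gaze, targets, _ = simulate_gaze_session(
                    spec, n_trials=config.gaze_sim.n_trials, rng_seed=config.seed
                )
            vio.write_gaze(gaze, gaze_csv)
        gaze = vio.read_gaze(gaze_csv)
        targets = CalibrationTargets()
    except (OSError, ValueError) as e:
        raise StageError("gaze", str(e)) from e

    model_json = out / "calibration.json"
    artifacts["calibration"] = model_json
    try:
        if not model_json.exists():
            anchors = estimate_cluster_anchors(gaze, targets, mode="auto")
            model = fit_calibration(anchors)
            model.to_json(model_json)
        model = CalibrationModel.from_json(model_json)
    except ValueError as e:
        raise StageError("calibration", str(e)) from e

    quality_csv = out / "quality.csv"
    artifacts["quality"] = quality_csv
    try:
        if not quality_csv.exists():
            calibrated = apply_calibration(model, gaze)
            q = session_accuracy_precision(calibrated)
            pd.DataFrame.from_records(
                [
                    {
                        "session_id": 0,
                        "subject": "sim",
                        "offset_x": q.offset_x,
                        "offset_y": q.offset_y,
                        "sigma_x": q.sigma_x,
                        "sigma_y": q.sigma_y,
                        "absolute_offset": q.absolute_offset,
                        "absolute_sigma": q.absolute_sigma,
                    }
                ]
            ).to_csv(quality_csv, index=False)
    except ValueError as e:
        raise StageError("quality", str(e)) from e

    trials_csv = out / "trials.csv"
    artifacts["trials"] = trials_csv
    psych_json = out / "psychfit.json"
    artifacts["psychfit"] = psych_json
    try:
        if not trials_csv.exists():
            if config.trials_path:
                trials = vio.read_trials(config.trials_path)
            else:
                from .psychometrics import LogisticParams

                ob = config.observer_sim
                observer = ObserverSpec(
                    hit_params=LogisticParams(12.5, ob.hit_lambda, ob.hit_alpha, ob.hit_beta, mode="hit_rate"),
                    rt_params=LogisticParams(ob.rt_high_ms, ob.rt_low_ms, ob.rt_alpha, ob.rt_beta, mode="rt"),
                    rt_noise_sd=ob.rt_noise_sd,
                )
                trials = simulate_observer(observer, n_trials=ob.n_trials, rng_seed=config.seed)
            vio.write_trials(trials, trials_csv)
        trials = vio.read_trials(trials_csv)
        if not psych_json.exists():
            summary = summarize_conditions(trials, n_boot=min(config.analysis.n_boot, 10000), rng_seed=config.seed)
            hit_fit = fit_logistic(summary, mode="hit_rate")
            rt_fit = fit_logistic(summary, mode="rt")
            psych_json.write_text(
                json.dumps(
                    {
                        "hit_rate": {
                            "gamma": hit_fit.gamma, "lambda": hit_fit.lam,
                            "alpha": hit_fit.alpha, "beta": hit_fit.beta,
                            "threshold": acuity_threshold(hit_fit), "flags": hit_fit.flags,
                        },
                        "rt": {
                            "gamma": rt_fit.gamma, "lambda": rt_fit.lam,
                            "alpha": rt_fit.alpha, "beta": rt_fit.beta,
                            "threshold": acuity_threshold(rt_fit), "flags": rt_fit.flags,
                        },
                    },
                    indent=1,
                )
            )
    except (OSError, ValueError) as e:
        raise StageError("psychometrics", str(e)) from e

    return _write_manifest(out, config, artifacts)
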