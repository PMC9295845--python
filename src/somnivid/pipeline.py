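"""End-to-end orchestration: simulate → detect → stage → compare.

`run_video_pipeline` is the in-memory workhorse used by the tests and the
acceptance script: frames are rendered lazily only at the analysis sample
times, so multi-hour synthetic recordings run in bounded memory.
`run_pipeline` is the file-based entry point behind the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifier import (PatchClassifier, TrainConfig, harvest_training_patches,
                         train_classifier)
from .hypnogram import Hypnogram
from .io import (config_digest, read_scenario, read_staging_params,
                 write_ground_truth, write_manifest)
from .metrics import AgreementResult, compare_staging, sleep_time_summary
from .simulate import (GroundTruth, SimScenario, StateModel,
                       emit_reference_hypnogram, render_frame,
                       simulate_state_sequence)
from .staging import (ActivityTrace, StagingParams, activity_from_detections,
                      epoch_hypnogram, stage_sleep_wake, sweep_merge_threshold)
from .vision import VisionParams, detect_frames

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Bundle returned by the end-to-end runs."""

    hypnogram_s: Hypnogram            # per-second staged labels
    hypnogram_epoch: Hypnogram        # epoch-level staged labels
    reference: Hypnogram | None
    agreement: AgreementResult | None
    activity: ActivityTrace
    sweep: "object | None" = None     # DataFrame when requested
    digest: str = ""


def default_classifier_for(truth: GroundTruth, scenario: SimScenario,
                           seed: int = 0, n_patches: int = 120) -> PatchClassifier:
    """Train a quick logistic patch classifier from the simulation itself."""
    patches = harvest_training_patches(truth, scenario, n_pos=n_patches,
                                       n_neg=n_patches, seed=seed)
    clf, report = train_classifier(patches, TrainConfig(seed=seed))
    logger.info("fixture classifier: train acc %.3f, val acc %.3f",
                report.train_accuracy, report.validation_accuracy)
    return clf


def run_video_pipeline(truth: GroundTruth, scenario: SimScenario,
                       classifier, params: StagingParams | None = None,
                       with_sweep: bool = False) -> PipelineResult:
    """Detect, judge activity, stage, epoch, and score one synthetic recording.

    Frames are rendered only at the analysis sample times (one frame per
    ``params.sample_period_s``), which is what keeps a 2 h run tractable.
    """
    params = params or StagingParams(fps=scenario.fps)
    vis = VisionParams(expected_mouse_area_px=scenario.expected_mouse_area_px())
    n_samples = int(truth.duration_s / params.sample_period_s)
    frame_ids = [min(int(round(k * params.sample_period_s * scenario.fps)),
                     truth.trajectory.shape[0] - 1) for k in range(n_samples)]

    def frames():
        for k in frame_ids:
            yield k, render_frame(truth, scenario, k)

    detections = detect_frames(frames(), classifier, vis, fps=scenario.fps)
    activity = activity_from_detections(detections, params)
    hyp_s = stage_sleep_wake(activity, params)
    hyp_epoch = epoch_hypnogram(hyp_s, params.epoch_s)
    reference = emit_reference_hypnogram(truth, params.epoch_s)
    agreement = compare_staging(hyp_epoch, reference)
    sweep = sweep_merge_threshold(activity, reference, params=params) if with_sweep else None
    return PipelineResult(hyp_s, hyp_epoch, reference, agreement, activity,
                          sweep, digest=config_digest(params, vis))


@dataclass
class RunConfig:
    """File-based pipeline configuration (CLI surface)."""

    scenario_path: str | None = None
    params_path: str | None = None
    classifier_path: str | None = None
    video_path: str | None = None       # analyze an existing recording instead
    out_dir: str = "somnivid_out"
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("scenario_path", "params_path", "classifier_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name.replace('_path', '')} file not found: {p}")
        if self.video_path is not None:
            if not Path(self.video_path).exists():
                raise FileNotFoundError(f"video input not found: {self.video_path}")
            if self.classifier_path is None:
                raise FileNotFoundError(
                    "video input requires a trained classifier; no classifier "
                    "path was given")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate (or load), stage, score, and write the result bundle.

    Deterministic under the config seed; every output directory carries a
    JSON manifest with the parameter digest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = (read_staging_params(config.params_path)
              if config.params_path else StagingParams())

    if config.video_path is not None:
        from .io import read_frames
        classifier = PatchClassifier.load(config.classifier_path)
        detections = detect_frames(read_frames(config.video_path), classifier,
                                   VisionParams(), fps=params.fps)
        activity = activity_from_detections(detections, params)
        hyp_s = stage_sleep_wake(activity, params)
        hyp_epoch = epoch_hypnogram(hyp_s, params.epoch_s)
        result = PipelineResult(hyp_s, hyp_epoch, None, None, activity,
                                digest=config_digest(params))
    else:
        if config.scenario_path:
            scenario, model = read_scenario(config.scenario_path)
        else:
            scenario = SimScenario(duration_s=1800.0, seed=config.seed)
            model = StateModel(mean_wake_bout_s=180.0, mean_sleep_bout_s=240.0,
                               twitch_rate_per_min=0.5)
        truth = simulate_state_sequence(model, scenario.duration_s, config.seed,
                                        scenario)
        classifier = (PatchClassifier.load(config.classifier_path)
                      if config.classifier_path
                      else default_classifier_for(truth, scenario, config.seed))
        result = run_video_pipeline(truth, scenario, classifier, params)
        write_ground_truth(truth, out / "ground_truth.csv", out / "twitches.json")
        result.digest = config_digest(params, scenario, model)

    result.hypnogram_epoch.to_csv(out / "hypnogram.csv")
    result.hypnogram_s.to_csv(out / "hypnogram_per_second.csv")
    result.activity.to_frame().to_csv(out / "activity.csv", index=False)
    if result.agreement is not None:
        import json
        (out / "agreement.json").write_text(
            json.dumps(result.agreement.to_dict(), indent=2))
    hourly, daily = sleep_time_summary(result.hypnogram_epoch, 0.0)
    hourly.to_csv(out / "sleep_hourly.csv")
    write_manifest(out / "manifest.json", seed=config.seed, digest=result.digest,
                   params={"staging": params.__dict__})
    return result
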