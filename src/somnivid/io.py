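"""Readers and writers for the pipeline's on-disk formats.

Frames: a directory of PNGs, a single multi-frame TIFF, or any video
container imageio can open. Hypnograms and activity traces: CSV. Ground
truth: CSV (``second,state``) plus a JSON twitch list. Scenario and staging
parameters: YAML. Result bundles carry a JSON manifest with the config
digest so outputs are traceable to the exact parameter set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .hypnogram import Hypnogram
from .simulate import Distractor, GroundTruth, SimScenario, StateModel
from .staging import StagingParams

VIDEO_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv"}


# -- frames -----------------------------------------------------------------

def write_frames(stack: np.ndarray, path) -> Path:
    """Write a frame stack as a PNG directory or a multi-frame ``.tif``."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, stack)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack):
            iio.imwrite(path / f"frame_{i:06d}.png", frame)
    return path


def read_frames(path):
    """Yield ``(frame_index, frame)`` from a directory, TIFF, or video file."""
    path = Path(path)
    if path.is_dir():
        for i, f in enumerate(sorted(path.glob("frame_*.png"))):
            yield i, iio.imread(f)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        for i, frame in enumerate(stack):
            yield i, frame
    elif path.suffix.lower() in VIDEO_SUFFIXES:
        for i, frame in enumerate(iio.imiter(path)):
            if frame.ndim == 3:
                frame = frame.mean(axis=-1).astype(np.uint8)
            yield i, frame
    else:
        raise ValueError(f"unrecognized frame source: {path}")


# -- ground truth -----------------------------------------------------------

def write_ground_truth(truth: GroundTruth, csv_path, twitch_json_path=None) -> None:
    pd.DataFrame({
        "second": np.arange(truth.state_per_second.size),
        "state": truth.state_per_second,
    }).to_csv(csv_path, index=False)
    if twitch_json_path is not None:
        Path(twitch_json_path).write_text(json.dumps(
            {"twitch_intervals": [[a, b] for a, b in truth.twitch_intervals]},
            indent=2))


def read_state_csv(path) -> np.ndarray:
    return pd.read_csv(path)["state"].to_numpy(dtype="U8")


# -- configs ----------------------------------------------------------------

def _as_dict(obj) -> dict:
    return dataclasses.asdict(obj)


def write_scenario(scenario: SimScenario, model: StateModel, path) -> None:
    data = {"scenario": _as_dict(scenario), "state_model": _as_dict(model)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_scenario(path) -> tuple[SimScenario, StateModel]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    sc = dict(data.get("scenario", {}))
    if "arena_size_px" in sc:
        sc["arena_size_px"] = tuple(sc["arena_size_px"])
    if sc.get("distractors"):
        sc["distractors"] = [
            Distractor(d["shape"], tuple(d["position"]), d["size_px"], d["gray"])
            for d in sc["distractors"]]
    sm = dict(data.get("state_model", {}))
    if "twitch_duration_s" in sm:
        sm["twitch_duration_s"] = tuple(sm["twitch_duration_s"])
    return SimScenario(**sc), StateModel(**sm)


def read_staging_params(path) -> StagingParams:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return StagingParams(**data)


def write_staging_params(params: StagingParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_dict(params), fh, sort_keys=False)


def config_digest(*objs) -> str:
    """Stable sha256 over the canonical JSON of config dataclasses/dicts."""
    payload = []
    for obj in objs:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            obj = dataclasses.asdict(obj)
        payload.append(obj)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, *, seed: int, digest: str, params: dict,
                   inputs: dict | None = None) -> None:
    from . import __version__
    Path(path).write_text(json.dumps({
        "software": "somnivid",
        "version": __version__,
        "seed": seed,
        "config_digest": digest,
        "parameters": params,
        "inputs": inputs or {},
    }, indent=2, sort_keys=True, default=str))
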