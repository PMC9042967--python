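"""Delimited-text + JSON-sidecar serialization for every pipeline artifact.

Streams and metric/score series are tab-separated tables with a header row;
each carries a ``<name>.json`` sidecar with the participant metadata, the
run seed, a config hash and the package version, so reruns are auditable
and byte-comparable (timestamps are deliberately not recorded).  Trained
models are a single JSON file holding the weights next to the normalization
statistics, the feature manifest, the schedule and the RMSE history;
loading refuses files whose manifest does not match the current pipeline's.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import FeatureOrderError, MalformedStreamError
from .metrics import METRIC_NAMES, MetricSeries, METRIC_MANIFEST
from .model import ExpertiseResults
from .scoring import ParticipantScore, ScoreSeries
from .simulate import RawStream

__all__ = [
    "config_hash",
    "write_sidecar",
    "read_sidecar",
    "write_raw_stream",
    "read_raw_stream",
    "write_metric_series",
    "read_metric_series",
    "write_score_series",
    "write_participant_scores",
    "write_intervals",
    "save_model",
    "load_model",
    "write_manifest",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Stable short hash of any JSON-able configuration object."""
    payload = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_sidecar(path: Path, seed: int, config, extra: dict | None = None) -> Path:
    side = Path(path).with_suffix(Path(path).suffix + ".json")
    payload = {
        "seed": int(seed),
        "config_hash": config_hash(config),
        "version": __version__,
    }
    if extra:
        payload.update(_jsonable(extra))
    side.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return side


def read_sidecar(path: Path) -> dict:
    side = Path(path).with_suffix(Path(path).suffix + ".json")
    if not side.exists():
        raise FeatureOrderError(f"missing sidecar for {path}")
    return json.loads(side.read_text())


def write_raw_stream(stream: RawStream, path: Path, seed: int = 0,
                     config=None) -> Path:
    path = Path(path)
    stream.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    write_sidecar(path, seed, config, extra={
        "participant_id": stream.participant_id,
        "trial_index": stream.trial_index,
        "group_label": stream.group_label,
        "skill": stream.skill,
    })
    return path


def read_raw_stream(path: Path) -> RawStream:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = read_sidecar(path)
    return RawStream.from_frame(
        df,
        participant_id=meta.get("participant_id", "p00"),
        trial_index=meta.get("trial_index", 0),
        group_label=meta.get("group_label"),
        skill=meta.get("skill"),
    )


def write_metric_series(series: MetricSeries, path: Path, seed: int = 0,
                        config=None) -> Path:
    path = Path(path)
    series.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    write_sidecar(path, seed, config, extra={
        "participant_id": series.participant_id,
        "trial_index": series.trial_index,
        "group_label": series.group_label,
        "skill": series.skill,
        "manifest": list(series.names),
    })
    return path


def read_metric_series(path: Path) -> MetricSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = read_sidecar(path)
    names = tuple(meta["manifest"])
    if names != METRIC_NAMES:
        raise FeatureOrderError(
            f"metric file {path} has manifest {names}, expected {METRIC_NAMES}"
        )
    if tuple(df.columns[1:]) != names:
        raise MalformedStreamError(f"column order of {path} disagrees with sidecar")
    return MetricSeries(
        time=df["time"].to_numpy(float),
        values=df[list(names)].to_numpy(float),
        manifest=METRIC_MANIFEST,
        participant_id=meta.get("participant_id", "p00"),
        trial_index=meta.get("trial_index", 0),
        group_label=meta.get("group_label"),
        skill=meta.get("skill"),
    )


def write_score_series(series: ScoreSeries, path: Path, seed: int = 0,
                       config=None) -> Path:
    path = Path(path)
    series.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    write_sidecar(path, seed, config, extra={
        "participant_id": series.participant_id,
        "trial_index": series.trial_index,
        "group_label": series.group_label,
        "task_average": series.task_average,
    })
    return path


def write_participant_scores(scores: list[ParticipantScore], path: Path) -> Path:
    path = Path(path)
    payload = [_jsonable(s) for s in scores]
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_intervals(intervals: list[tuple[str, float, float]], path: Path) -> Path:
    """Three-column interval table: participant, start_s, end_s."""
    path = Path(path)
    df = pd.DataFrame(intervals, columns=["participant", "start_s", "end_s"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def save_model(results: ExpertiseResults, path: Path, config=None) -> Path:
    path = Path(path)
    path.write_text(json.dumps(results.to_dict()))
    write_sidecar(path, results.seed, config, extra={
        "manifest": list(results.manifest_names),
        "test_rmse": results.test_rmse,
    })
    return path


def load_model(path: Path) -> ExpertiseResults:
    path = Path(path)
    meta = read_sidecar(path)  # refuse weights without their sidecar
    results = ExpertiseResults.from_dict(json.loads(path.read_text()))
    if tuple(meta["manifest"]) != tuple(results.manifest_names):
        raise FeatureOrderError(f"sidecar manifest of {path} disagrees with weights")
    return results


def write_manifest(path: Path) -> Path:
    """Write the 16-metric manifest (names, units, categories, reductions)."""
    path = Path(path)
    payload = [
        {
            "name": m.name,
            "unit": m.unit,
            "category": m.category,
            "reduction": m.reduction,
            "reconstructed": m.reconstructed,
        }
        for m in METRIC_MANIFEST
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path
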