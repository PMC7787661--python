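"""Configuration loading, result persistence, and run records.

Every experiment writes a JSON RunRecord (config snapshot, seeds, outputs)
so that any published number can be regenerated from its record alone.
Tabular outputs go to CSV; configs are plain YAML/JSON key-value files with
unknown keys rejected and units documented in error messages.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomech import ArmParams, Trajectory
from .control import CostConfig
from .experiments import FittsConfig, FittsResult
from .neural import NeuralTrialSet
from .optimizer import OptimizerConfig

__all__ = ["RunRecord", "load_config", "save_config", "save_run_record",
           "trajectory_to_csv", "fitts_to_csv", "neural_set_to_csv",
           "neural_set_from_csv", "CONFIG_SECTIONS"]

CONFIG_SECTIONS = {
    "arm": ArmParams,
    "cost": CostConfig,
    "optimizer": OptimizerConfig,
    "fitts": FittsConfig,
}


def _build_section(cls, mapping: dict, section: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'; "
            f"valid keys: {sorted(valid)} (lengths/widths in m, times in s, "
            f"masses in kg, torques in N m)")
    coerced = {}
    for f in fields(cls):
        if f.name not in mapping:
            continue
        v = mapping[f.name]
        coerced[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"section '{section}': {exc}") from exc


def load_config(path) -> dict:
    """Load a YAML/JSON config file into validated config objects.

    An empty file yields all-default configs.  Unknown sections or keys are
    rejected with field-level messages.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping of sections")
    unknown = set(data) - set(CONFIG_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s) {sorted(unknown)}; "
                         f"valid: {sorted(CONFIG_SECTIONS)}")
    return {name: _build_section(cls, data.get(name, {}), name)
            for name, cls in CONFIG_SECTIONS.items()}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(configs: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(configs), sort_keys=True))


@dataclass
class RunRecord:
    """Reproducibility ledger for one experiment invocation."""

    tool: str = "reachopt"
    version: str = __version__
    command: str = ""
    config: dict = field(default_factory=dict)
    seeds: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    wall_time_s: float | None = None  # informational only


def save_run_record(record: RunRecord, path) -> None:
    Path(path).write_text(json.dumps(_to_plain(record), indent=2, sort_keys=True))


class Timer:
    def __enter__(self):
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self._t0


# ---------------------------------------------------------------------------
# tabular outputs


def trajectory_to_csv(traj: Trajectory, path) -> None:
    cols = {"time": traj.t, "q1": traj.q[:, 0], "q2": traj.q[:, 1],
            "qd1": traj.qd[:, 0], "qd2": traj.qd[:, 1]}
    for m in range(traj.activations.shape[1]):
        cols[f"a_{m + 1}"] = traj.activations[:, m]
    cols.update({"hand_x": traj.hand[:, 0], "hand_y": traj.hand[:, 1],
                 "speed": traj.speed})
    pd.DataFrame(cols).to_csv(path, index=False)


def fitts_to_csv(result: FittsResult, path) -> None:
    result.to_frame().to_csv(path, index=False)


def neural_set_to_csv(ts: NeuralTrialSet, path, ground_truth: dict | None = None) -> None:
    """CSV with columns trial_id, condition, md_s, ch_0001..; optional
    ground-truth JSON sidecar next to it."""
    path = Path(path)
    n_ch = ts.n_channels
    cols = {"trial_id": np.arange(ts.n_trials), "condition": ts.condition,
            "md_s": ts.md}
    for c in range(n_ch):
        cols[f"ch_{c + 1:04d}"] = ts.rates[:, c]
    pd.DataFrame(cols).to_csv(path, index=False)
    if ground_truth is not None:
        sidecar = path.with_suffix(".ground_truth.json")
        sidecar.write_text(json.dumps(_to_plain(ground_truth), indent=2))


def neural_set_from_csv(path) -> NeuralTrialSet:
    df = pd.read_csv(path)
    ch_cols = sorted(c for c in df.columns if c.startswith("ch_"))
    gt_path = Path(path).with_suffix(".ground_truth.json")
    gt = json.loads(gt_path.read_text()) if gt_path.exists() else None
    return NeuralTrialSet(rates=df[ch_cols].to_numpy(float),
                          md=df["md_s"].to_numpy(float),
                          condition=df["condition"].to_numpy(),
                          ground_truth=gt)
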