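"""Serialization, run manifests and deterministic fixture generation.

File formats (see docs/FORMATS.md): behavioral data as CSV, BOLD-like
time series as two-column TSV with a JSON sidecar carrying the full
neural config, fit/GLM results and manifests as JSON, configs as YAML.
Floats are written with 12 significant digits so regenerated artifacts
are byte-identical across platforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .neural_sim import HRFSpec, NeuralConfig, NeuralTimeSeries
from .rl_core import BehavioralData, RLParams, TaskConfig

__all__ = [
    "FLOAT_FORMAT",
    "save_behavior",
    "load_behavior",
    "save_timeseries",
    "load_timeseries",
    "config_to_yaml",
    "config_from_yaml",
    "task_from_dict",
    "params_from_dict",
    "neural_config_from_dict",
    "config_hash",
    "write_manifest",
    "make_fixtures",
]

FLOAT_FORMAT = "%.12g"
TOOL_VERSION = "0.1.0"


# --------------------------------------------------------------------- tables


def save_behavior(datasets: list[BehavioralData], path) -> Path:
    """Write one or more subjects' behavioral data as a single CSV."""
    path = Path(path)
    df = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def load_behavior(path) -> list[BehavioralData]:
    """Read the behavioral CSV back into per-subject records.

    Value trajectories for the unchosen option are not stored in the
    CSV; the loaded object carries the chosen-option value per trial,
    which is what fitting and GLM estimation need.
    """
    df = pd.read_csv(path)
    out = []
    for subject, g in df.groupby("subject", sort=False):
        g = g.sort_values("trial")
        n = len(g)
        choices = g["choice"].to_numpy(dtype=np.int64)
        values = np.full((n, 2), np.nan)
        values[np.arange(n), choices] = g["value_chosen"].to_numpy(dtype=float)
        out.append(
            BehavioralData(
                subject=str(subject),
                choices=choices,
                outcomes=g["outcome"].to_numpy(dtype=float),
                values=values,
                pe=g["pe"].to_numpy(dtype=float),
                choice_probs=np.full(n, np.nan),
                mode="instrumental",
            )
        )
    return out


def save_timeseries(ts: NeuralTimeSeries, path) -> Path:
    """Two-column TSV (time_s, signal) plus a ``.json`` config sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": ts.times, "signal": ts.signal}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"config": asdict(ts.config), "noise_sd_used": ts.noise_sd_used},
            indent=2,
            default=float,
        )
    )
    return path


def load_timeseries(path) -> NeuralTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    return NeuralTimeSeries(
        times=df["time_s"].to_numpy(),
        signal=df["signal"].to_numpy(),
        config=neural_config_from_dict(meta["config"]),
        noise_sd_used=meta.get("noise_sd_used"),
    )


# -------------------------------------------------------------------- configs


def task_from_dict(d: dict) -> TaskConfig:
    d = dict(d)
    for key in ("reward_probs", "outcome_values"):
        if key in d:
            d[key] = tuple(d[key])
    return TaskConfig(**d)


def params_from_dict(d: dict) -> RLParams:
    return RLParams(**{k: v for k, v in d.items() if k != "subject"})


def neural_config_from_dict(d: dict) -> NeuralConfig:
    d = dict(d)
    if isinstance(d.get("hrf"), dict):
        d["hrf"] = HRFSpec(**d["hrf"])
    return NeuralConfig(**d)


def config_to_yaml(obj, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(obj), sort_keys=True))
    return path


def config_from_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(obj) -> str:
    """Stable sha256 over a canonical JSON rendering of a config dict."""
    if not isinstance(obj, dict):
        obj = asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_manifest(
    out_dir,
    command: str,
    master_seed,
    config: dict,
    inputs: list,
    outputs: list,
) -> Path:
    """RunManifest: everything needed to re-execute the run exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool_version": TOOL_VERSION,
        "command": command,
        "master_seed": master_seed,
        "config_hash": config_hash(config),
        "config": config,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float))
    return path


# ------------------------------------------------------------------- fixtures


def make_fixtures(seed: int, out_dir) -> dict:
    """Deterministic two-subject, 100-trial fixture bundle.

    Writes a behavioral CSV, one BOLD TSV per subject (noiseless, so a
    correctly specified GLM recovers phi exactly), and a manifest with
    the generative parameters.  Regenerating with the same seed
    reproduces the data files byte-for-byte (the manifest carries a
    timestamp).
    """
    from .neural_sim import simulate_bold
    from .rl_core import simulate_agent

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    task = TaskConfig(n_trials=100)
    subjects = {"s1": RLParams(alpha=0.1, beta=2.0), "s2": RLParams(alpha=0.5, beta=2.0)}
    phi = 1.7
    cfg = NeuralConfig(phi=phi, tr=1.0, trial_duration=4.0, event_duration=0.01, noise_sd=0.0)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(subjects))
    datasets, outputs = [], []
    for (name, params), child in zip(subjects.items(), children):
        data = simulate_agent(task, params, np.random.default_rng(child))
        data.subject = name
        datasets.append(data)
        ts = simulate_bold(data.pe, cfg, None)
        outputs.append(save_timeseries(ts, out_dir / f"bold_{name}.tsv"))
    behavior_path = save_behavior(datasets, out_dir / "behavior.csv")
    outputs.insert(0, behavior_path)
    config = {
        "task": asdict(task),
        "subjects": {k: asdict(v) for k, v in subjects.items()},
        "neural": asdict(cfg),
        "phi": phi,
    }
    manifest = write_manifest(out_dir, "make-fixtures", seed, config, [], outputs)
    return {"behavior": behavior_path, "manifest": manifest, "phi": phi, "config": config}
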