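"""File formats: TAC/input-function CSVs, fit-result JSONs, cohort layout.

CSV dialects (comma-separated, header row, UTF-8, '.' decimal separator):

* input function — ``time_s,value``
* tissue TAC     — ``frame_start_s,frame_duration_s,value``

A simulated cohort is one directory per subject (``tissue.csv``,
``arterial.csv``, ``portal.csv``, ``truth.json``) plus ``manifest.csv``.
Every artifact embeds the seed and a hash of the generating configuration
so a run can be reconstructed from its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .model import FrameSchedule, InputFunction, TissueCurve
from .optim import FitResult
from .simulate import SyntheticSubject

__all__ = [
    "read_input_function",
    "write_input_function",
    "read_tac",
    "write_tac",
    "write_cohort",
    "read_subject",
    "result_to_dict",
    "write_result",
    "read_result",
    "load_config",
    "config_hash",
]


def write_input_function(path: Path | str, curve: InputFunction) -> None:
    pd.DataFrame({"time_s": curve.times, "value": curve.values}).to_csv(path, index=False)


def read_input_function(path: Path | str) -> InputFunction:
    df = pd.read_csv(path)
    return InputFunction(df["time_s"].to_numpy(), df["value"].to_numpy())


def write_tac(path: Path | str, tac: TissueCurve) -> None:
    pd.DataFrame(
        {
            "frame_start_s": tac.schedule.starts,
            "frame_duration_s": tac.schedule.durations,
            "value": tac.values,
        }
    ).to_csv(path, index=False)


def read_tac(path: Path | str, label: str = "") -> TissueCurve:
    df = pd.read_csv(path)
    schedule = FrameSchedule(
        df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy()
    )
    return TissueCurve(schedule, df["value"].to_numpy(), label=label)


def config_hash(config: Any) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_cohort(
    outdir: Path | str, subjects: Sequence[SyntheticSubject], meta: dict | None = None
) -> Path:
    """Write one directory per subject plus a cohort manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        sdir = outdir / s.subject_id
        sdir.mkdir(exist_ok=True)
        write_tac(sdir / "tissue.csv", s.tissue)
        write_input_function(sdir / "arterial.csv", s.arterial)
        write_input_function(sdir / "portal.csv", s.portal)
        truth = {"group": s.group, "params": asdict(s.true_params)}
        if meta:
            truth["meta"] = meta
        (sdir / "truth.json").write_text(json.dumps(truth, indent=2))
        rows.append({"subject_id": s.subject_id, "group": s.group, "path": s.subject_id})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    if meta:
        (outdir / "cohort.json").write_text(json.dumps(meta, indent=2, default=str))
    return outdir


def read_subject(subject_dir: Path | str):
    """Load one cohort subject directory -> (tissue, arterial, portal, truth)."""
    subject_dir = Path(subject_dir)
    truth = json.loads((subject_dir / "truth.json").read_text())
    tissue = read_tac(subject_dir / "tissue.csv", label=truth.get("group", ""))
    arterial = read_input_function(subject_dir / "arterial.csv")
    portal = read_input_function(subject_dir / "portal.csv")
    return tissue, arterial, portal, truth


def result_to_dict(result: FitResult, extra: dict | None = None) -> dict:
    d = {
        "method": result.method,
        "params": dict(zip(["k1", "k2", "k3", "k4", "hpi"], map(float, result.x))),
        "fitness": float(result.fun),
        "trace": [float(v) for v in result.trace],
        "residuals": None
        if result.residuals is None
        else [float(v) for v in result.residuals],
        "n_frames": result.n_obs,
        "n_params": result.n_params,
        "n_evals": result.n_evals,
    }
    if extra:
        d.update(extra)
    return d


def write_result(path: Path | str, result: FitResult, extra: dict | None = None) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result, extra), indent=2))


def read_result(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path: Path | str) -> dict:
    """Load a YAML (or JSON — YAML superset) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg
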