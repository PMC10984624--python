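"""Serialisation of run results: JSONL trajectory, CSV summaries, config snapshot."""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .esteem import RunResult, TrialRecord
from .experiments import config_digest

__all__ = ["write_run", "read_run"]

_TRAJECTORY = "trajectory.jsonl"
_TRAIT_STEPS = "trait_steps.csv"
_CONFIG = "config.json"

_TRAIT_COLUMNS = ["step", "trial", "map_trait", "omega", "gamma0",
                  "p_low", "p_medium", "p_high", "v_negative", "v_neutral", "v_positive"]


def write_run(result: RunResult, path) -> Path:
    """Write a run to ``path`` (a directory): one JSON line per lower-level
    timestep, a trait-step CSV and a config snapshot with its digest.
    Floats are written with ``repr`` so the round trip is lossless."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / _TRAJECTORY, "w") as fh:
        for rec in result.records:
            fh.write(json.dumps(rec.to_dict()) + "\n")

    with open(path / _TRAIT_STEPS, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRAIT_COLUMNS)
        for ts in result.trait_steps:
            tp, vp = ts["trait_posterior"], ts["valence_posterior"]
            writer.writerow([ts["step"], ts["trial"], ts["map_trait"],
                             repr(ts["omega"]), repr(ts["gamma0"]),
                             *[repr(float(x)) for x in tp], *[repr(float(x)) for x in vp]])

    snapshot = {"config": result.config, "seed": result.seed,
                "config_digest": config_digest(result.config)}
    with open(path / _CONFIG, "w") as fh:
        json.dump(snapshot, fh, indent=2)
    return path


def _parse_error(path: Path, line_no: int, field: str, exc: Exception):
    return ValueError(f"{path}, line {line_no}: bad field {field!r} ({exc})")


def read_run(path) -> RunResult:
    """Read a run written by :func:`write_run`; inverse up to the live agent."""
    path = Path(path)

    records = []
    traj = path / _TRAJECTORY
    with open(traj) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise _parse_error(traj, i, "<json>", exc) from exc
            try:
                records.append(TrialRecord.from_dict(d))
            except TypeError as exc:
                raise _parse_error(traj, i, "<record fields>", exc) from exc

    trait_steps = []
    steps_path = path / _TRAIT_STEPS
    with open(steps_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            try:
                trait_steps.append({
                    "step": int(row["step"]),
                    "trial": int(row["trial"]),
                    "map_trait": row["map_trait"],
                    "omega": float(row["omega"]),
                    "gamma0": float(row["gamma0"]),
                    "trait_posterior": [float(row[k]) for k in ("p_low", "p_medium", "p_high")],
                    "valence_posterior": [float(row[k]) for k in ("v_negative", "v_neutral", "v_positive")],
                })
            except (KeyError, ValueError) as exc:
                raise _parse_error(steps_path, i, "<trait step>", exc) from exc

    with open(path / _CONFIG) as fh:
        snapshot = json.load(fh)
    return RunResult(records=records, trait_steps=trait_steps,
                     config=snapshot["config"], seed=snapshot["seed"], agent=None)
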