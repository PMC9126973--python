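"""Session bundle: the on-disk and in-memory data model for one recording.

A session directory holds:

* ``manifest.json`` — session id, cohort, seed, stimulus-set parameters;
* ``trials.csv`` — one row per trial (stimuli, choice, outcome, timing);
* ``spikes.csv`` — neuron_id, time_s;
* ``neurons.csv`` — neuron_id, depth_um, p2t_ms;
* ``licks.csv`` — time_s, side;
* ``pupil.csv`` — time_s, pupil_z (optional stream).

Times are seconds on the session clock; trial indices are 1-based.  All
windows elsewhere in the package are half-open [start, end).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Session", "SessionValidationError", "read_session", "write_session"]

TRIAL_COLUMNS = [
    "trial_index", "trial_type", "pre_feature", "post_feature", "saliency",
    "change_magnitude", "change_time", "choice", "correct_side", "outcome",
    "reaction_time", "photostim", "reward_time",
]


class SessionValidationError(ValueError):
    """Raised when a session bundle violates the schema, with row detail."""


@dataclass
class Session:
    """In-memory session: behavior, spikes, metadata, and optional streams."""

    manifest: dict
    trials: pd.DataFrame
    spikes: pd.DataFrame
    neurons: pd.DataFrame
    licks: pd.DataFrame
    pupil: pd.DataFrame | None = None
    ground_truth: dict | None = None

    @property
    def session_id(self) -> str:
        return str(self.manifest.get("session_id", "unknown"))

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def span(self) -> tuple[float, float]:
        """Recording span in seconds (0 to a little past the last event)."""
        t_end = float(self.manifest.get("duration_s", 0.0))
        if not t_end:
            candidates = [self.trials["change_time"].max() + 5.0]
            if len(self.spikes):
                candidates.append(self.spikes["time_s"].max())
            t_end = float(max(candidates))
        return 0.0, t_end

    def validate(self) -> None:
        errors = []
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            errors.append(f"trials.csv missing columns: {missing}")
        known = set(self.neurons["neuron_id"])
        bad = self.spikes.loc[~self.spikes["neuron_id"].isin(known)]
        if len(bad):
            rows = bad.index[:5].tolist()
            errors.append(
                f"spikes.csv references unknown neuron_ids at rows {rows} "
                f"(e.g. {bad['neuron_id'].iloc[0]!r})"
            )
        rt = self.trials["reaction_time"].dropna()
        if len(rt) and ((rt <= 0.1) | (rt > 1.5)).any():
            n = int(((rt <= 0.1) | (rt > 1.5)).sum())
            errors.append(f"{n} reaction times outside the (0.1, 1.5] s window")
        if (np.diff(self.trials["change_time"].to_numpy()) <= 0).any():
            errors.append("trials.csv change_time not strictly increasing")
        if errors:
            raise SessionValidationError("; ".join(errors))


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session bundle; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = dict(session.manifest)
    manifest["config_hash"] = config_hash(manifest)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    session.trials.to_csv(path / "trials.csv", index=False)
    session.spikes.to_csv(path / "spikes.csv", index=False)
    session.neurons.to_csv(path / "neurons.csv", index=False)
    session.licks.to_csv(path / "licks.csv", index=False)
    if session.pupil is not None:
        session.pupil.to_csv(path / "pupil.csv", index=False)
    if session.ground_truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(session.ground_truth, indent=2, default=_jsonable)
        )
    return path


def read_session(path: str | Path, validate: bool = True) -> Session:
    """Read a session bundle from disk; optional streams may be absent."""
    path = Path(path)
    if not (path / "manifest.json").exists():
        raise SessionValidationError(f"no manifest.json in {path}")
    manifest = json.loads((path / "manifest.json").read_text())
    trials = pd.read_csv(path / "trials.csv")
    spikes = pd.read_csv(path / "spikes.csv")
    neurons = pd.read_csv(path / "neurons.csv")
    licks = pd.read_csv(path / "licks.csv")
    pupil_path = path / "pupil.csv"
    pupil = pd.read_csv(pupil_path) if pupil_path.exists() else None
    gt_path = path / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else None
    session = Session(
        manifest=manifest, trials=trials, spikes=spikes, neurons=neurons,
        licks=licks, pupil=pupil, ground_truth=ground_truth,
    )
    if validate:
        session.validate()
    return session


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")
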