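"""Reading and writing the plain-text study fixture dialect and results.

One trial is three files: a spike-train table (unit_id, firing_time_s), a
torque table (time_s, torque_Nm, target_Nm) and a JSON sidecar with trial
metadata and per-unit pulse-to-noise ratios.  A YAML manifest names the
trials.  The dialect is deliberately plain text so that simulated
fixtures, tests and re-analyses stay hermetic and diffable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    OUTCOME_COLUMNS,
    Condition,
    MotorUnitTrain,
    Phase,
    RampTrial,
    TestUnitOutcome,
)

log = logging.getLogger(__name__)

_CONDITION_SLUG = {
    Condition.CONTROL: "control",
    Condition.GRIP_40_15: "40p15s",
    Condition.GRIP_40_30: "40p30s",
    Condition.GRIP_80_15: "80p15s",
}


@dataclass
class StudyInputs:
    """Loaded study: trials with their (PNR-gated) spike trains.

    ``unmatched_units`` lists (participant, condition, unit_id) present in
    only one phase; they keep their per-unit metrics but are excluded from
    before/after contrasts.
    """

    trials: list[tuple[RampTrial, list[MotorUnitTrain]]]
    n_excluded_pnr: int = 0
    unmatched_units: list[tuple[str, str, str]] = field(default_factory=list)


def _trial_stem(participant_id: str, condition: Condition, phase: Phase) -> str:
    return f"{participant_id}_{_CONDITION_SLUG[Condition(condition)]}_{Phase(phase).value}"


def write_trial(
    dest: Path, trial: RampTrial, trains: list[MotorUnitTrain]
) -> dict:
    """Write one trial's three files; returns its manifest entry."""
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    stem = _trial_stem(trial.participant_id, trial.condition, trial.phase)

    spike_rows = []
    for tr in trains:
        for t in tr.firing_times:
            spike_rows.append((tr.unit_id, t))
    spikes = pd.DataFrame(spike_rows, columns=["unit_id", "firing_time_s"])
    spikes.to_csv(dest / f"{stem}_spikes.csv", index=False, float_format="%.6f")

    torque = pd.DataFrame(
        {
            "time_s": trial.time,
            "torque_Nm": trial.torque_raw,
            "target_Nm": trial.target_path,
        }
    )
    torque.to_csv(dest / f"{stem}_torque.csv", index=False, float_format="%.8f")

    meta = {
        "participant_id": trial.participant_id,
        "condition": trial.condition.value,
        "phase": trial.phase.value,
        "fs_hz": trial.fs,
        "peak_torque_Nm": trial.peak_torque,
        "units": {tr.unit_id: round(tr.pnr_db, 3) for tr in trains},
    }
    with open(dest / f"{stem}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)

    return {
        "spikes": f"{stem}_spikes.csv",
        "torque": f"{stem}_torque.csv",
        "meta": f"{stem}_meta.json",
    }


def write_study(dest: Path, trials) -> Path:
    """Write a collection of (RampTrial, trains) plus a manifest.yaml."""
    dest = Path(dest)
    entries = [write_trial(dest, trial, trains) for trial, trains in trials]
    manifest = {"trials": entries}
    path = dest / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def _read_trial(root: Path, entry: dict) -> tuple[RampTrial, list[MotorUnitTrain]]:
    for key in ("spikes", "torque", "meta"):
        if not (root / entry[key]).exists():
            raise FileNotFoundError(f"manifest names missing file: {entry[key]}")
    with open(root / entry["meta"]) as fh:
        meta = json.load(fh)
    torque = pd.read_csv(root / entry["torque"])
    fs = float(meta["fs_hz"])
    trial = RampTrial(
        participant_id=meta["participant_id"],
        condition=Condition(meta["condition"]),
        phase=Phase(meta["phase"]),
        torque_raw=torque["torque_Nm"].to_numpy(),
        fs=fs,
        peak_torque=float(meta["peak_torque_Nm"]),
        target_path=torque["target_Nm"].to_numpy(),
    )
    spikes = pd.read_csv(root / entry["spikes"])
    trains = []
    for unit_id, grp in spikes.groupby("unit_id", sort=True):
        times = grp["firing_time_s"].to_numpy()
        if np.any(times < -1e-9) or np.any(times > trial.duration + 1e-6):
            raise ValueError(
                f"unit {unit_id}: firing time outside the trial window "
                f"[0, {trial.duration:.2f}] s"
            )
        trains.append(
            MotorUnitTrain(
                unit_id=str(unit_id),
                participant_id=trial.participant_id,
                condition=trial.condition,
                phase=trial.phase,
                firing_times=times,
                pnr_db=float(meta["units"][str(unit_id)]),
            )
        )
    return trial, trains


def read_study_inputs(root: Path, manifest: Path | None = None) -> StudyInputs:
    """Load all trials named by a manifest, applying the PNR >= 30 dB gate.

    Units present in only one phase of a (participant, condition) pair are
    retained but flagged unmatched.  Missing files, out-of-window firing
    times and non-monotone trains are fatal.
    """
    root = Path(root)
    manifest = Path(manifest) if manifest else root / "manifest.yaml"
    with open(manifest) as fh:
        spec = yaml.safe_load(fh)

    trials: list[tuple[RampTrial, list[MotorUnitTrain]]] = []
    n_excluded = 0
    for entry in spec["trials"]:
        trial, trains = _read_trial(root, entry)
        retained = [t for t in trains if t.retained]
        n_excluded += len(trains) - len(retained)
        trials.append((trial, retained))
    if n_excluded:
        log.info("PNR gate excluded %d unit trains (< 30 dB)", n_excluded)

    seen: dict[tuple[str, str], dict[str, set]] = {}
    for trial, trains in trials:
        k = (trial.participant_id, trial.condition.value)
        seen.setdefault(k, {}).setdefault(trial.phase.value, set()).update(
            t.unit_id for t in trains
        )
    unmatched = []
    for (pid, cond), phases in seen.items():
        before = phases.get(Phase.BEFORE.value, set())
        after = phases.get(Phase.AFTER.value, set())
        for uid in sorted(before.symmetric_difference(after)):
            unmatched.append((pid, cond, uid))
    return StudyInputs(
        trials=trials, n_excluded_pnr=n_excluded, unmatched_units=unmatched
    )


def write_outcomes(rows: list[TestUnitOutcome], dest: Path) -> Path:
    """Write the per-test-unit results table (deterministic row order)."""
    if not rows:
        raise ValueError("no outcome rows to write")
    ordered = sorted(rows, key=lambda r: r.sort_key())
    df = pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "participant_id": r.participant_id,
                "condition": r.condition.value,
                "phase": r.phase.value,
                "delta_f": r.delta_f,
                "brace_height": r.brace_height,
                "attenuation_slope": r.attenuation_slope,
                "peak_discharge_rate": r.peak_discharge_rate,
                "recruitment_threshold": r.recruitment_threshold,
                "derecruitment_threshold": r.derecruitment_threshold,
                "n_control_units": r.n_control_units,
            }
            for r in ordered
        ],
        columns=list(OUTCOME_COLUMNS),
    )
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(dest, index=False, float_format="%.6f")
    return dest


def read_outcomes(path: Path) -> pd.DataFrame:
    """Read a results table back as a DataFrame (canonical column order)."""
    df = pd.read_csv(path)
    missing = set(OUTCOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    return df[list(OUTCOME_COLUMNS)]
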