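"""End-to-end orchestration: torque QC -> smoothing -> pairing -> outcomes.

``analyze_trial`` turns one ramp and its spike trains into per-test-unit
outcome rows; ``analyze_study`` maps it over a loaded or simulated study
with full exclusion accounting (every loaded trial/unit is either
analysed or counted in exactly one exclusion bucket).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import metrics
from .datamodel import (
    ExclusionCounts,
    MotorUnitTrain,
    RampTrial,
    TestUnitOutcome,
)
from .metrics import PAIR_CRITERIA
from .smoothing import MIN_FIRINGS, SVRConfig, smooth_unit
from .torque import FilteredTorque, filter_torque, ramp_qc

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the per-unit pipeline in one place.

    Pairing criteria and the QC limit default to the printed analysis
    constants (r >= 0.7, recruitment gap > 1 s, control modulation
    > 0.5 pps, QC deviation <= 5% of peak torque); the smoothing
    hyperparameters are package conventions.
    """

    svr: SVRConfig = field(default_factory=SVRConfig)
    qc_enabled: bool = True
    seed: int = 0


@dataclass
class TrialAnalysis:
    """Per-trial result bundle."""

    trial: RampTrial
    outcomes: list[TestUnitOutcome]
    smoothed: dict
    pairs: list
    torque: FilteredTorque | None
    counts: ExclusionCounts


def analyze_trial(
    trial: RampTrial,
    trains: list[MotorUnitTrain],
    config: PipelineConfig | None = None,
) -> TrialAnalysis:
    """Analyse one ramp: QC, smoothing, geometry, pairing and deltaF.

    Trials failing torque QC yield no outcomes (the whole contraction is
    discarded, mirroring the acquisition rule).  Units are dropped
    per-metric, never silently: the returned counts account for every
    unit.
    """
    config = config or PipelineConfig()
    counts = ExclusionCounts(
        trials_loaded=1,
        units_loaded=len(trains),
        pair_rejections={c: 0 for c in PAIR_CRITERIA},
    )

    filtered = filter_torque(trial)
    target_pct = 100.0 * trial.target_path / trial.peak_torque
    trial.qc = ramp_qc(filtered, target_pct)
    if config.qc_enabled and not trial.qc.passed:
        counts.trials_failed_qc = 1
        counts.units_in_failed_trials = len(trains)
        log.info(
            "trial %s failed QC (max deviation %.2f%% of peak)",
            trial.key(),
            trial.qc.max_abrupt_deviation,
        )
        return TrialAnalysis(trial, [], {}, [], filtered, counts)

    retained = [t for t in trains if t.retained]
    counts.units_failed_pnr = len(trains) - len(retained)

    smoothed = {}
    for tr in retained:
        if tr.n_firings < MIN_FIRINGS:
            counts.units_too_few_firings += 1
            continue
        smoothed[tr.unit_id] = smooth_unit(tr, config.svr)

    pairs, rejections = metrics.pair_units(list(smoothed.values()))
    for k, v in rejections.items():
        counts.pair_rejections[k] += v
    df_by_test: dict[str, list[float]] = {}
    for p in pairs:
        df_by_test.setdefault(p.test_id, []).append(
            metrics.delta_f(p, smoothed[p.control_id], smoothed[p.test_id])
        )

    outcomes = []
    for uid, sr in smoothed.items():
        rec, derec, peak = metrics.thresholds(sr, filtered)
        try:
            geo = metrics.unit_geometry(sr, filtered)
            brace, slope = geo.brace_height, geo.attenuation_slope
        except ValueError:
            counts.units_degenerate_geometry += 1
            brace, slope = None, None
        pair_dfs = df_by_test.get(uid, [])
        if not pair_dfs:
            counts.test_units_without_pairs += 1
        outcomes.append(
            TestUnitOutcome(
                unit_id=uid,
                participant_id=trial.participant_id,
                condition=trial.condition,
                phase=trial.phase,
                delta_f=metrics.delta_f_per_test_unit(pair_dfs) if pair_dfs else None,
                brace_height=brace,
                attenuation_slope=slope,
                peak_discharge_rate=peak,
                recruitment_threshold=max(0.0, min(100.0, rec)),
                derecruitment_threshold=max(0.0, min(100.0, derec)),
                n_control_units=len(pair_dfs),
            )
        )
    return TrialAnalysis(trial, outcomes, smoothed, pairs, filtered, counts)


def _merge_counts(total: ExclusionCounts, one: ExclusionCounts) -> None:
    total.trials_loaded += one.trials_loaded
    total.trials_failed_qc += one.trials_failed_qc
    total.units_loaded += one.units_loaded
    total.units_in_failed_trials += one.units_in_failed_trials
    total.units_failed_pnr += one.units_failed_pnr
    total.units_too_few_firings += one.units_too_few_firings
    total.units_degenerate_geometry += one.units_degenerate_geometry
    total.test_units_without_pairs += one.test_units_without_pairs
    for k, v in one.pair_rejections.items():
        total.pair_rejections[k] = total.pair_rejections.get(k, 0) + v


@dataclass
class StudyAnalysis:
    """All per-unit outcomes of a study plus pooled exclusion accounting."""

    outcomes: list[TestUnitOutcome]
    counts: ExclusionCounts
    per_trial: list[TrialAnalysis]

    def table(self) -> pd.DataFrame:
        rows = sorted(self.outcomes, key=lambda r: r.sort_key())
        return pd.DataFrame(
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
                for r in rows
            ]
        )


def analyze_study(
    trials: list[tuple[RampTrial, list[MotorUnitTrain]]],
    config: PipelineConfig | None = None,
) -> StudyAnalysis:
    """Run the per-trial analysis over a whole study."""
    config = config or PipelineConfig()
    total = ExclusionCounts(pair_rejections={c: 0 for c in PAIR_CRITERIA})
    outcomes: list[TestUnitOutcome] = []
    per_trial = []
    for trial, trains in trials:
        ta = analyze_trial(trial, trains, config)
        _merge_counts(total, ta.counts)
        outcomes.extend(ta.outcomes)
        per_trial.append(ta)
    return StudyAnalysis(outcomes=outcomes, counts=total, per_trial=per_trial)


def matched_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict an outcome table to units observed in both phases.

    Units identified in only one of the before/after ramps cannot enter a
    within-unit contrast; they are dropped here (but remain in the full
    table for descriptive statistics).
    """
    key = ["participant_id", "condition", "unit_id"]
    n_phases = table.groupby(key)["phase"].transform("nunique")
    return table[n_phases == 2].reset_index(drop=True)
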