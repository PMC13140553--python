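"""Ground-truth validation scenarios for the whole pipeline.

Each function here runs the package end to end on a simulated study with
known ground truth and returns summary numbers: deltaF oracle errors,
hysteresis-grid recovery, injected-contrast recovery and null confidence-
interval coverage.  They are used by the test suite and by the
reproduction script; sizes are chosen so every scenario runs in minutes
on one CPU while keeping Monte-Carlo error well inside the tolerance it
is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import Condition, Phase
from .pipeline import PipelineConfig, analyze_study, matched_outcomes
from .simulate import ConditionEffect, PoolConfig, simulate_study, simulate_trial
from .smoothing import smooth_unit
from .stats import ModelSpec, fit_contrasts
from . import metrics


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


def noiseless_pool_config(**kw) -> PoolConfig:
    """The exact-oracle regime: linear rate model, no noise anywhere."""
    base = dict(
        units_per_trial=10,
        isi_cv=0.0,
        drive_noise_pct=0.0,
        torque_noise_pct=0.0,
        pic_amplitude=0.0,
        gain_jitter=0.0,
        condition_effects={},
    )
    base.update(kw)
    return PoolConfig(**base)


def delta_f_pair_errors(cfg: PoolConfig, seed: int) -> np.ndarray:
    """Pipeline deltaF minus ground-truth deltaF for every valid pair of
    one simulated trial."""
    rng = np.random.default_rng(_sub_seed(seed, 0))
    _, trains, truth = simulate_trial(
        cfg, "P01", Condition.CONTROL, Phase.BEFORE, rng
    )
    by_id = {u.unit_id: u for u in truth.units}
    smoothed = {tr.unit_id: smooth_unit(tr) for tr in trains}
    pairs, _ = metrics.pair_units(list(smoothed.values()))
    errors = []
    for p in pairs:
        measured = metrics.delta_f(p, smoothed[p.control_id], smoothed[p.test_id])
        errors.append(
            measured - truth.true_delta_f(by_id[p.control_id], by_id[p.test_id])
        )
    return np.asarray(errors)


def noiseless_delta_f_errors(seed: int = 0, n_trials: int = 4) -> np.ndarray:
    """Pair-level deltaF errors in the noiseless regime, pooled over trials."""
    errs = []
    for k in range(n_trials):
        errs.append(
            delta_f_pair_errors(noiseless_pool_config(), _sub_seed(seed, k + 1))
        )
    return np.concatenate(errs)


def hysteresis_grid_recovery(
    seed: int = 0,
    deltas=(1.0, 2.0, 3.0, 4.0),
    n_units: int = 30,
    n_seeds: int = 20,
    isi_cv: float = 0.15,
) -> pd.DataFrame:
    """Median pipeline deltaF error per hysteresis level.

    For each hysteresis level, simulates trials of ``n_units`` at the
    given ISI variability over ``n_seeds`` replicates and reports the
    median pair-level error relative to gain_control x hysteresis_test
    (realized).
    """
    rows = []
    for d in deltas:
        errs = []
        for k in range(n_seeds):
            cfg = PoolConfig(
                units_per_trial=n_units,
                isi_cv=isi_cv,
                pic_amplitude=0.0,
                gain_jitter=0.0,
                hysteresis_range=(d, d),
                condition_effects={},
            )
            errs.append(delta_f_pair_errors(cfg, _sub_seed(seed, 100 * int(d * 10) + k)))
        errs = np.concatenate(errs)
        rows.append(
            {
                "delta": d,
                "median_error": float(np.median(errs)),
                "n_pairs": int(errs.size),
            }
        )
    return pd.DataFrame(rows)


#: Conditions receiving the injected effect in the recovery scenario.
INJECTED = (Condition.GRIP_40_30, Condition.GRIP_80_15)
NULLS = (Condition.CONTROL, Condition.GRIP_40_15)


def recovery_scenario_config(seed: int, effect_pps: float = 0.30) -> PoolConfig:
    """Study config with a known deltaF effect injected in two conditions.

    The linear rate model is used (the hysteresis -> deltaF mapping is
    exactly gain x hysteresis) and recruitment thresholds start at 5 %MVT
    so every unit can carry the shifted hysteresis within the ramp --
    i.e. the nominal effect is actually injected, not clipped.
    """
    cfg = PoolConfig(
        n_participants=8,
        units_per_trial=12,
        threshold_range=(5.0, 18.0),
        hysteresis_range=(1.0, 3.0),
        pic_amplitude=0.0,
        seed=seed,
    )
    shift = effect_pps / cfg.gain
    cfg.condition_effects = {c: ConditionEffect(delta_shift=shift) for c in INJECTED}
    return cfg


@dataclass
class ContrastRecovery:
    """Outcome of the injected-contrast recovery scenario."""

    effect_pps: float
    n_seeds: int
    #: per-condition mean of per-seed recovered contrasts
    recovered: dict = field(default_factory=dict)
    #: per-condition fraction of per-seed 95% CIs containing zero
    null_coverage: dict = field(default_factory=dict)
    per_seed: pd.DataFrame | None = None


def contrast_recovery(
    seed: int = 0, n_seeds: int = 30, effect_pps: float = 0.30
) -> ContrastRecovery:
    """Recover an injected deltaF effect through the full pipeline.

    Runs ``n_seeds`` independent replicate studies, fits the deltaF mixed
    model on each, and aggregates: the mean recovered after-before
    contrast in the injected conditions (should equal ``effect_pps``) and
    the rate at which 95% CIs cover zero in the untreated conditions
    (should be ~95%).
    """
    rows = []
    for k in range(n_seeds):
        cfg = recovery_scenario_config(_sub_seed(seed, 7000 + k), effect_pps)
        study = simulate_study(cfg)
        analysis = analyze_study(
            [(td.trial, td.trains) for td in study.trials], PipelineConfig()
        )
        m = matched_outcomes(analysis.table())
        contrasts = fit_contrasts(m, ModelSpec.for_response("delta_f"))
        for c, r in contrasts.items():
            rows.append(
                {
                    "seed": k,
                    "condition": c,
                    "estimate": r.after_minus_before,
                    "covers_zero": r.ci_95[0] <= 0.0 <= r.ci_95[1],
                }
            )
    per_seed = pd.DataFrame(rows)
    out = ContrastRecovery(effect_pps=effect_pps, n_seeds=n_seeds, per_seed=per_seed)
    g = per_seed.groupby("condition")
    for c in INJECTED:
        out.recovered[c.value] = float(g["estimate"].mean()[c.value])
    for c in NULLS:
        out.null_coverage[c.value] = float(g["covers_zero"].mean()[c.value])
    return out


def null_coverage(
    seed: int = 0, n_seeds: int = 50, n_participants: int = 6, units: int = 6
) -> pd.DataFrame:
    """Type-I behaviour: null studies, fraction of 95% CIs covering zero.

    No condition effects at all; every after-before contrast's true value
    is 0, so ~95% of the per-replicate CIs should contain it.
    """
    rows = []
    for k in range(n_seeds):
        cfg = PoolConfig(
            n_participants=n_participants,
            units_per_trial=units,
            pic_amplitude=0.0,
            condition_effects={},
            seed=_sub_seed(seed, 9000 + k),
        )
        study = simulate_study(cfg)
        analysis = analyze_study(
            [(td.trial, td.trains) for td in study.trials], PipelineConfig()
        )
        m = matched_outcomes(analysis.table())
        contrasts = fit_contrasts(m, ModelSpec.for_response("delta_f"))
        for c, r in contrasts.items():
            rows.append(
                {
                    "seed": k,
                    "condition": c,
                    "estimate": r.after_minus_before,
                    "covers_zero": r.ci_95[0] <= 0.0 <= r.ci_95[1],
                }
            )
    return pd.DataFrame(rows)


def brace_height_vs_acceleration(
    amplitudes=(0.0, 1.0, 2.0, 3.0, 4.0), seed: int = 0
) -> pd.DataFrame:
    """Mean brace height as a function of the PIC acceleration amplitude.

    Noiseless pools at a fixed saturation scale; brace height should
    increase monotonically with the acceleration amplitude.
    """
    from .torque import filter_torque

    rows = []
    for amp in amplitudes:
        cfg = noiseless_pool_config(units_per_trial=8, pic_amplitude=amp)
        rng = np.random.default_rng(_sub_seed(seed, 300))
        trial, trains, _ = simulate_trial(
            cfg, "P01", Condition.CONTROL, Phase.BEFORE, rng
        )
        tq = filter_torque(trial)
        heights = []
        for tr in trains:
            try:
                geo = metrics.unit_geometry(smooth_unit(tr), tq)
                heights.append(geo.brace_height)
            except ValueError:
                continue
        rows.append({"amplitude": amp, "mean_brace_height": float(np.mean(heights))})
    return pd.DataFrame(rows)
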