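"""Synthetic motoneuron pool with known recruitment-derecruitment hysteresis.

Generates spike trains and torque traces for triangular ramp contractions
(0 -> 20 %MVT over 10 s -> 0 over 10 s) from a phenomenological rate
model with controllable ground truth, so every pipeline stage can be
validated against known parameters:

* unit i is recruited when the common drive E(t) (%MVT) crosses its
  threshold theta_i on the ascent and keeps firing until E falls below
  theta_i - delta_i on the descent (delta_i is the hysteresis, the
  simulator's analogue of PIC-supported self-sustained firing);
* while active, the true rate is
  r_i(t) = r_min + g_i * (E - theta_i) + A * (1 - exp(-max(E - theta_i, 0)/s)),
  a linear drive term plus a saturating acceleration term of amplitude A
  (pps) and saturation scale s (%MVT) — PIC-like amplification without a
  conductance model;
* spikes are an inhomogeneous renewal process: gamma inter-spike intervals
  at a configurable coefficient of variation, time-rescaled through the
  integrated rate.

For a (control, test) pair the model's deltaF ground truth is the control
rate read at drive theta_test minus at drive theta_test - delta_test; with
A = 0 this reduces exactly to g_control * delta_test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    CONDITIONS,
    Condition,
    MotorUnitTrain,
    Phase,
    RampTrial,
)

#: Ramp geometry: peak %MVT and ascent/descent durations (s).
RAMP_PEAK_PCT = 20.0
RAMP_UP_S = 10.0
RAMP_DOWN_S = 10.0
RAMP_RATE_PCT_S = RAMP_PEAK_PCT / RAMP_UP_S  # 2 %MVT per second

#: Internal drive/rate grid step (s) for spike generation.
_SIM_DT = 0.002


def target_triangle_pct(time: np.ndarray) -> np.ndarray:
    """Requested triangular torque path in %MVT on a given time grid."""
    up = RAMP_RATE_PCT_S * time
    down = RAMP_PEAK_PCT - RAMP_RATE_PCT_S * (time - RAMP_UP_S)
    return np.clip(np.where(time <= RAMP_UP_S, up, down), 0.0, RAMP_PEAK_PCT)


@dataclass
class ConditionEffect:
    """Shift applied to "after"-phase trials of one condition.

    ``delta_shift`` adds to every unit's hysteresis (%MVT of drive), which
    raises deltaF by gain * delta_shift; ``rate_shift`` adds a constant to
    the discharge rate (pps), which moves the peak rate.
    """

    delta_shift: float = 0.0
    rate_shift: float = 0.0


def _default_effects() -> dict[Condition, ConditionEffect]:
    # High-impulse handgrip conditions facilitate hysteresis; with the
    # default gain 0.5 pps/%MVT these produce after-before deltaF shifts
    # of +0.33 and +0.24 pps respectively.
    return {
        Condition.GRIP_40_30: ConditionEffect(delta_shift=0.66),
        Condition.GRIP_80_15: ConditionEffect(delta_shift=0.48, rate_shift=0.20),
    }


@dataclass
class PoolConfig:
    """Study-level configuration of the synthetic motoneuron pool.

    Defaults emulate the tibialis anterior protocol: 21 participants,
    ~15 matched units per trial, 20 %MVT triangular ramps, recruitment
    thresholds spread over 1-18 %MVT, gain 0.5 pps/%MVT, minimum rate
    6 pps, ISI coefficient of variation 0.15, and hysteresis effects
    injected in the two high-impulse conditions only.
    """

    n_participants: int = 21
    units_per_trial: int = 15
    threshold_range: tuple[float, float] = (1.0, 18.0)
    gain: float = 0.5  # pps per %MVT
    gain_jitter: float = 0.2  # relative, uniform +-
    r_min: float = 6.0  # pps at recruitment
    pic_amplitude: float = 3.0  # pps, acceleration term amplitude
    pic_saturation: float = 5.0  # %MVT, acceleration saturation scale
    hysteresis_range: tuple[float, float] = (1.0, 4.0)  # %MVT
    isi_cv: float = 0.15
    condition_effects: dict = field(default_factory=_default_effects)
    conditions: tuple = CONDITIONS
    fs: float = 256.0  # torque sampling rate, Hz
    torque_noise_pct: float = 0.15  # measurement noise SD, % of peak
    drive_noise_pct: float = 0.4  # tracking error SD, % of peak
    peak_torque_nm: float = 54.0  # dorsiflexion peak torque, N*m
    pnr_range: tuple[float, float] = (32.0, 48.0)
    seed: int = 0

    def validate(self) -> None:
        if self.threshold_range[1] >= RAMP_PEAK_PCT:
            raise ValueError("recruitment thresholds must lie below the ramp peak")
        if self.hysteresis_range[0] < 0:
            raise ValueError("hysteresis must be non-negative")
        if self.isi_cv < 0:
            raise ValueError("isi_cv must be non-negative")


@dataclass
class UnitParams:
    """Ground-truth parameters of one synthetic unit.

    ``delta`` is the nominal hysteresis (the derecruitment rule fires
    until drive < theta - delta); ``delta_realized`` is the hysteresis the
    simulated train actually exhibited, i.e. theta minus the drive at the
    last emitted spike.  The last spike necessarily precedes the exact
    crossing, so realized hysteresis is what a recovery oracle should be
    scored against.
    """

    unit_id: str
    theta: float  # recruitment threshold, %MVT of drive
    gain: float  # pps per %MVT
    delta: float  # hysteresis, %MVT of drive
    pnr_db: float
    delta_realized: float | None = None

    @property
    def delta_eff(self) -> float:
        return self.delta if self.delta_realized is None else self.delta_realized


@dataclass
class PoolGroundTruth:
    """Simulator truth for one trial, for parameter-recovery tests."""

    units: list[UnitParams]
    rate_shift: float
    config: PoolConfig
    #: dense (time, rate) true profiles per unit id
    rate_profiles: dict = field(default_factory=dict)

    def true_rate_at_drive(self, unit: UnitParams, drive: float) -> float:
        """The rate model evaluated at a given drive level (%MVT)."""
        x = drive - unit.theta
        pic = self.config.pic_amplitude * (
            1.0 - np.exp(-max(x, 0.0) / self.config.pic_saturation)
        )
        return self.config.r_min + unit.gain * x + pic + self.rate_shift

    def true_delta_f(self, control: UnitParams, test: UnitParams) -> float:
        """Model deltaF for a pair: control rate drop over the test unit's
        (realized) hysteresis interval.  Equals gain_control * delta_test
        when the acceleration amplitude is zero."""
        return self.true_rate_at_drive(control, test.theta) - self.true_rate_at_drive(
            control, test.theta - test.delta_eff
        )

    def true_delta_f_linear(self, control: UnitParams, test: UnitParams) -> float:
        return control.gain * test.delta_eff

    def pair_table(self) -> pd.DataFrame:
        rows = []
        for c in self.units:
            for t in self.units:
                if c.theta < t.theta:
                    rows.append(
                        {
                            "control_id": c.unit_id,
                            "test_id": t.unit_id,
                            "true_delta_f": self.true_delta_f(c, t),
                            "true_delta_f_linear": self.true_delta_f_linear(c, t),
                        }
                    )
        return pd.DataFrame(rows)


def draw_unit_params(cfg: PoolConfig, rng: np.random.Generator) -> list[UnitParams]:
    """Draw one trial's unit parameters (shared by both phases of a condition)."""
    lo, hi = cfg.threshold_range
    thetas = np.sort(rng.uniform(lo, hi, cfg.units_per_trial))
    gains = cfg.gain * (1.0 + cfg.gain_jitter * rng.uniform(-1, 1, cfg.units_per_trial))
    dlo, dhi = cfg.hysteresis_range
    deltas = rng.uniform(dlo, dhi, cfg.units_per_trial)
    pnrs = rng.uniform(*cfg.pnr_range, cfg.units_per_trial)
    return [
        UnitParams(
            unit_id=f"u{i + 1:02d}",
            theta=float(thetas[i]),
            gain=float(gains[i]),
            delta=float(min(deltas[i], 0.9 * thetas[i])),
            pnr_db=float(pnrs[i]),
        )
        for i in range(cfg.units_per_trial)
    ]


def _tracking_noise(
    n: int, fs: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Slow (~1 Hz) tracking wander: low-passed white noise rescaled to sd."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    # single-pole smoothing with ~1 Hz corner
    alpha = np.exp(-2.0 * np.pi * 1.0 / fs)
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = alpha * acc + (1 - alpha) * white[i]
        out[i] = acc
    s = out.std()
    return out * (sd / s) if s > 0 else out


def _spike_times_deterministic(tgrid: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """Noise-free spikes whose reciprocal ISIs sit exactly on the rate curve.

    Each interval satisfies t_k - t_{k-1} = 1/r(t_k) (fixed-point solved),
    so the instantaneous-rate samples the pipeline computes (assigned at
    the closing spike) reproduce the true profile without the half-ISI lag
    of a time-rescaled process.  The first spike sits exactly at the
    recruitment crossing; the train ends at the last rate-consistent spike
    before the derecruitment crossing (the realized hysteresis is recorded
    in the ground truth from that spike).
    """
    t0, tend = float(tgrid[0]), float(tgrid[-1])

    def r(t: float) -> float:
        return float(np.interp(t, tgrid, rate))

    times = [t0]
    t_prev = t0
    while True:
        dt = 1.0 / r(t_prev)
        for _ in range(4):
            dt = 1.0 / r(min(t_prev + dt, tend))
        t_next = t_prev + dt
        if t_next >= tend:
            break
        times.append(t_next)
        t_prev = t_next
    return np.asarray(times)


def _spike_times(
    tgrid: np.ndarray, rate: np.ndarray, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous gamma renewal spikes by time rescaling.

    The integrated rate maps real time to operational time in which ISIs
    are i.i.d. gamma with mean 1 and coefficient of variation ``cv``.
    cv = 0 switches to the deterministic rate-consistent construction.
    """
    if cv == 0:
        return _spike_times_deterministic(tgrid, rate)
    lam = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(tgrid))]
    )
    total = lam[-1]
    if total < 1.0:
        return np.array([tgrid[0]]) if total > 0 else np.empty(0)
    shape = 1.0 / cv**2
    increments = rng.gamma(shape, cv**2, int(total) + 1)
    ops = np.cumsum(increments)
    ops = ops[ops <= total]
    times = np.interp(ops, lam, tgrid)
    return np.concatenate([[tgrid[0]], times])


def simulate_trial(
    cfg: PoolConfig,
    participant_id: str,
    condition: Condition,
    phase: Phase,
    rng: np.random.Generator,
    unit_params: list[UnitParams] | None = None,
) -> tuple[RampTrial, list[MotorUnitTrain], PoolGroundTruth]:
    """Simulate one triangular ramp with its motor-unit spike trains.

    ``unit_params`` lets the caller reuse one draw across the before and
    after phases of a condition (tracked units).  Condition effects are
    applied to "after" trials only.
    """
    cfg.validate()
    condition = Condition(condition)
    phase = Phase(phase)
    if unit_params is None:
        unit_params = draw_unit_params(cfg, rng)

    for u in unit_params:
        if u.delta >= u.theta:
            raise ValueError(
                f"unit {u.unit_id}: hysteresis {u.delta} >= threshold {u.theta}; "
                "the unit would never derecruit within the ramp"
            )

    effect = ConditionEffect()
    if phase is Phase.AFTER and condition in cfg.condition_effects:
        effect = cfg.condition_effects[condition]

    duration = RAMP_UP_S + RAMP_DOWN_S
    tdense = np.arange(0.0, duration + _SIM_DT / 2, _SIM_DT)
    target = target_triangle_pct(tdense)
    drive = target + _tracking_noise(len(tdense), 1 / _SIM_DT, cfg.drive_noise_pct, rng)
    drive = np.clip(drive, 0.0, None)

    # The condition shift is capped below the unit's threshold so shifted
    # units still derecruit; ground truth records the delta actually used.
    # Units are copied so each phase owns its realized-hysteresis record.
    truth = PoolGroundTruth(
        units=[
            replace(
                u,
                delta=min(u.delta + effect.delta_shift, 0.9 * u.theta),
                delta_realized=None,
            )
            for u in unit_params
        ],
        rate_shift=effect.rate_shift,
        config=cfg,
    )

    trains: list[MotorUnitTrain] = []
    i_apex = int(np.argmax(drive))
    for u in truth.units:
        on_candidates = np.nonzero(drive[: i_apex + 1] >= u.theta)[0]
        if on_candidates.size == 0:
            continue
        i_on = int(on_candidates[0])
        off_candidates = np.nonzero(drive[i_apex:] >= u.theta - u.delta)[0]
        i_off = int(off_candidates[-1]) + i_apex
        seg_t = tdense[i_on : i_off + 1]
        x = drive[i_on : i_off + 1] - u.theta
        rate = (
            cfg.r_min
            + u.gain * x
            + cfg.pic_amplitude
            * (1.0 - np.exp(-np.clip(x, 0.0, None) / cfg.pic_saturation))
            + effect.rate_shift
        )
        rate = np.clip(rate, 0.5, None)
        truth.rate_profiles[u.unit_id] = (seg_t, rate)
        spikes = _spike_times(seg_t, rate, cfg.isi_cv, rng)
        if spikes.size < 2:
            continue
        u.delta_realized = float(u.theta - np.interp(spikes[-1], tdense, drive))
        trains.append(
            MotorUnitTrain(
                unit_id=u.unit_id,
                participant_id=participant_id,
                condition=condition,
                phase=phase,
                firing_times=spikes,
                pnr_db=u.pnr_db,
            )
        )

    tq_time = np.arange(0.0, duration + 0.5 / cfg.fs, 1.0 / cfg.fs)
    drive_tq = np.interp(tq_time, tdense, drive)
    torque_nm = drive_tq / 100.0 * cfg.peak_torque_nm
    torque_nm = torque_nm + rng.normal(
        0.0, cfg.torque_noise_pct / 100.0 * cfg.peak_torque_nm, len(tq_time)
    )
    target_nm = target_triangle_pct(tq_time) / 100.0 * cfg.peak_torque_nm
    trial = RampTrial(
        participant_id=participant_id,
        condition=condition,
        phase=phase,
        torque_raw=torque_nm,
        fs=cfg.fs,
        peak_torque=cfg.peak_torque_nm,
        target_path=target_nm,
    )
    return trial, trains, truth


@dataclass
class TrialData:
    """One simulated ramp bundle."""

    trial: RampTrial
    trains: list[MotorUnitTrain]
    truth: PoolGroundTruth


@dataclass
class StudyData:
    """A full simulated study: participants x conditions x 2 phases."""

    trials: list[TrialData]
    config: PoolConfig

    def ground_truth_table(self) -> pd.DataFrame:
        rows = []
        for td in self.trials:
            for u in td.truth.units:
                rows.append(
                    {
                        "participant_id": td.trial.participant_id,
                        "condition": td.trial.condition.value,
                        "phase": td.trial.phase.value,
                        "unit_id": u.unit_id,
                        "theta": u.theta,
                        "gain": u.gain,
                        "delta": u.delta,
                        "rate_shift": td.truth.rate_shift,
                        "pnr_db": u.pnr_db,
                    }
                )
        return pd.DataFrame(rows)


def simulate_study(cfg: PoolConfig) -> StudyData:
    """Simulate the full design: every participant in every condition,
    before and after, with tracked units and per-condition effects.

    Reproducible: all randomness descends from ``cfg.seed`` through
    per-trial seed-sequence children, so the same config yields the same
    study regardless of evaluation order.
    """
    cfg.validate()
    trials: list[TrialData] = []
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        for c, condition in enumerate(cfg.conditions):
            ss_params = np.random.SeedSequence([cfg.seed, p, c, 0])
            ss_before = np.random.SeedSequence([cfg.seed, p, c, 1])
            ss_after = np.random.SeedSequence([cfg.seed, p, c, 2])
            params = draw_unit_params(cfg, np.random.default_rng(ss_params))
            for phase, ss in ((Phase.BEFORE, ss_before), (Phase.AFTER, ss_after)):
                trial, trains, truth = simulate_trial(
                    cfg,
                    pid,
                    condition,
                    phase,
                    np.random.default_rng(ss),
                    unit_params=params,
                )
                trials.append(TrialData(trial=trial, trains=trains, truth=truth))
    return StudyData(trials=trials, config=cfg)
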