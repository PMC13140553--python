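"""Core data model for the motor-unit ramp-contraction pipeline.

The analysis operates on pairs of triangular dorsiflexion ramps (one
"before" and one "after" an intervening handgrip condition), each carrying
a torque trace and a set of decomposed motor-unit spike trains.  Types here
are plain dataclasses; heavy numerics live in the processing modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: Decomposition-quality gate: units below this pulse-to-noise ratio (dB)
#: are excluded from all analyses.
PNR_RETENTION_DB = 30.0


class Condition(str, Enum):
    """Handgrip condition interposed between the two ramps."""

    CONTROL = "Control"
    GRIP_40_15 = "40%15s"
    GRIP_40_30 = "40%30s"
    GRIP_80_15 = "80%15s"


class Phase(str, Enum):
    """Ramp position relative to the handgrip condition."""

    BEFORE = "before"
    AFTER = "after"


CONDITIONS = tuple(Condition)
PHASES = (Phase.BEFORE, Phase.AFTER)


@dataclass
class MotorUnitTrain:
    """One motor unit's firing times within a single ramp contraction.

    ``unit_id`` is stable across the before/after phases of a condition
    (units are tracked across the pair of ramps upstream), which is what
    lets the stats stage treat the unit as a repeated measure.
    Firing times are seconds from ramp onset and strictly increasing.
    """

    unit_id: str
    participant_id: str
    condition: Condition
    phase: Phase
    firing_times: np.ndarray
    pnr_db: float

    def __post_init__(self) -> None:
        self.firing_times = np.asarray(self.firing_times, dtype=float)
        self.condition = Condition(self.condition)
        self.phase = Phase(self.phase)
        if self.firing_times.ndim != 1:
            raise ValueError("firing_times must be a 1-D array")
        if self.firing_times.size and np.any(np.diff(self.firing_times) <= 0):
            raise ValueError(
                f"unit {self.unit_id}: firing times must be strictly increasing"
            )

    @property
    def n_firings(self) -> int:
        return int(self.firing_times.size)

    @property
    def retained(self) -> bool:
        """Whether the unit passes the pulse-to-noise-ratio gate."""
        return self.pnr_db >= PNR_RETENTION_DB


@dataclass
class QCResult:
    """Quality control of how well a ramp tracked the requested triangle.

    ``max_abrupt_deviation`` is the largest instantaneous gap between the
    performed and requested torque, in % of peak torque; a trial fails when
    it exceeds 5% (abrupt/steep torque deviation).  ``tracking_error_area``
    is the unsigned area between the performed and requested paths,
    in (% of peak torque)*s, kept as a consistency metric.
    """

    passed: bool
    max_abrupt_deviation: float
    tracking_error_area: float


@dataclass
class RampTrial:
    """One triangular ramp: torque trace, target path and trial metadata.

    The target path rises linearly from 0 to 20% of ``peak_torque`` over
    10 s and returns to 0 over the next 10 s (2%/s both ways).
    """

    participant_id: str
    condition: Condition
    phase: Phase
    torque_raw: np.ndarray
    fs: float
    peak_torque: float
    target_path: np.ndarray
    qc: QCResult | None = None

    def __post_init__(self) -> None:
        self.torque_raw = np.asarray(self.torque_raw, dtype=float)
        self.target_path = np.asarray(self.target_path, dtype=float)
        self.condition = Condition(self.condition)
        self.phase = Phase(self.phase)
        if self.torque_raw.shape != self.target_path.shape:
            raise ValueError("torque_raw and target_path must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.peak_torque <= 0:
            raise ValueError("peak torque must be positive")

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return (len(self.torque_raw) - 1) / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.torque_raw)) / self.fs

    def key(self) -> tuple[str, str, str]:
        return (self.participant_id, self.condition.value, self.phase.value)


#: Column order of the per-test-unit results table.
OUTCOME_COLUMNS = (
    "unit_id",
    "participant_id",
    "condition",
    "phase",
    "delta_f",
    "brace_height",
    "attenuation_slope",
    "peak_discharge_rate",
    "recruitment_threshold",
    "derecruitment_threshold",
    "n_control_units",
)


@dataclass
class TestUnitOutcome:
    """One row of the analysis dataset: all per-unit outcomes + metadata.

    ``delta_f`` is None when the unit formed no valid pair
    (``n_control_units == 0``); geometry metrics are None when the unit's
    ascending phase was degenerate.  Thresholds are % of peak torque.
    """

    __test__ = False  # not a pytest class, despite the Test* name

    unit_id: str
    participant_id: str
    condition: Condition
    phase: Phase
    delta_f: float | None
    brace_height: float | None
    attenuation_slope: float | None
    peak_discharge_rate: float
    recruitment_threshold: float
    derecruitment_threshold: float
    n_control_units: int = 0

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.phase = Phase(self.phase)
        if self.delta_f is not None and self.n_control_units < 1:
            raise ValueError("delta_f requires at least one control unit")
        for name in ("recruitment_threshold", "derecruitment_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100] % of peak torque")

    def sort_key(self) -> tuple:
        return (
            self.participant_id,
            self.condition.value,
            self.phase.value,
            self.unit_id,
        )


@dataclass
class ExclusionCounts:
    """Per-stage accounting of what entered and what was excluded.

    The pipeline conserves counts at every stage:
    loaded = analysed + excluded.
    """

    trials_loaded: int = 0
    trials_failed_qc: int = 0
    units_loaded: int = 0
    units_in_failed_trials: int = 0
    units_failed_pnr: int = 0
    units_too_few_firings: int = 0
    units_degenerate_geometry: int = 0
    test_units_without_pairs: int = 0
    pair_rejections: dict = field(default_factory=dict)
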