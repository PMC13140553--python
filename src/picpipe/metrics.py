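"""Paired-motor-unit deltaF and firing-pattern geometry.

deltaF estimates the persistent-inward-current contribution to
self-sustained firing: a lower-threshold (control) unit's smoothed rate is
read at a higher-threshold (test) unit's recruitment and derecruitment;
the drop between the two readings, in pps, is the hysteresis attributable
to PIC-supported firing of the test unit.  Brace height and attenuation
slope characterise the nonlinearity of the ascending rate profile
(neuromodulatory and inhibitory drive proxies respectively).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .smoothing import GRID_DT, AscendingSegment, SmoothedRate, ascending_phase
from .torque import FilteredTorque

#: Pairing criteria: minimum smoothed rate-rate correlation, minimum
#: recruitment-time separation (s), and minimum control-unit rate
#: modulation between test recruitment and control peak (pps).
R_RATE_MIN = 0.7
RECRUIT_GAP_MIN_S = 1.0
CONTROL_MOD_MIN_PPS = 0.5

PAIR_CRITERIA = ("r_rate", "recruit_gap", "control_mod", "derec_order")


@dataclass
class MUPair:
    """A candidate control/test unit pair with its criterion values."""

    control_id: str
    test_id: str
    r_rate: float
    recruit_gap: float
    control_mod: float
    derec_order_ok: bool

    @property
    def valid(self) -> bool:
        return (
            self.r_rate >= R_RATE_MIN
            and self.recruit_gap > RECRUIT_GAP_MIN_S
            and self.control_mod > CONTROL_MOD_MIN_PPS
            and self.derec_order_ok
        )

    def failed_criteria(self) -> list[str]:
        out = []
        if self.r_rate < R_RATE_MIN:
            out.append("r_rate")
        if self.recruit_gap <= RECRUIT_GAP_MIN_S:
            out.append("recruit_gap")
        if self.control_mod <= CONTROL_MOD_MIN_PPS:
            out.append("control_mod")
        if not self.derec_order_ok:
            out.append("derec_order")
        return out


@dataclass
class GeometryResult:
    """Brace height and companions for one unit's ascending phase.

    ``brace_height`` is the maximal signed orthogonal deviation of the
    unit-square-normalised ascending curve from its chord, as a percentage
    of the right-triangle vertex distance (% rTri).  ``d_max`` is the same
    deviation in unit-square units; ``insertion_time`` is where it occurs.
    """

    brace_height: float
    d_max: float
    insertion_time: float
    attenuation_slope: float | None = None


def evaluate_pair(control: SmoothedRate, test: SmoothedRate) -> MUPair | None:
    """Score one ordered (control, test) pair against the pairing criteria.

    Returns None when the ordering precondition (control recruited first)
    fails; otherwise an MUPair carrying all four criterion values:

    (i)   rate-rate Pearson correlation >= 0.7 on the common support,
    (ii)  test - control recruitment separation > 1 s,
    (iii) control rate modulation between test recruitment and the control
          peak > 0.5 pps,
    (iv)  control derecruited after the test unit.
    """
    if control.t_rec >= test.t_rec:
        return None
    lo, hi = max(control.t_rec, test.t_rec), min(control.t_derec, test.t_derec)
    if hi - lo < 2 * GRID_DT:
        return None
    common = np.arange(lo, hi + GRID_DT / 2, GRID_DT)
    rc = control.interp(common)
    rt = test.interp(common)
    if np.std(rc) == 0 or np.std(rt) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(rc, rt)[0, 1])
    return MUPair(
        control_id=control.unit_id,
        test_id=test.unit_id,
        r_rate=r,
        recruit_gap=test.t_rec - control.t_rec,
        control_mod=control.peak_rate - control.at(test.t_rec),
        derec_order_ok=control.t_derec > test.t_derec,
    )


def pair_units(
    units: list[SmoothedRate],
) -> tuple[list[MUPair], dict[str, int]]:
    """Form all valid (control, test) pairs within one trial.

    Every ordered pair with the control recruited before the test unit is
    evaluated; only pairs passing all four criteria are returned, together
    with per-criterion rejection counts.
    """
    rejections = {c: 0 for c in PAIR_CRITERIA}
    valid: list[MUPair] = []
    for control in units:
        for test in units:
            if control is test:
                continue
            pair = evaluate_pair(control, test)
            if pair is None:
                continue
            failed = pair.failed_criteria()
            if failed:
                for c in failed:
                    rejections[c] += 1
            else:
                valid.append(pair)
    return valid, rejections


def delta_f(pair: MUPair, control: SmoothedRate, test: SmoothedRate) -> float:
    """deltaF (pps) for one valid pair.

    Control smoothed rate at test recruitment minus control smoothed rate
    at test derecruitment, both read at the nearest control grid point.
    """
    if not pair.valid:
        raise ValueError("deltaF is only defined for valid pairs")
    if test.t_derec > control.t_derec:
        raise ValueError(
            "test derecruitment outside control support (criterion iv violated)"
        )
    return control.at(test.t_rec) - control.at(test.t_derec)


def delta_f_per_test_unit(pair_values: list[float]) -> float:
    """Single deltaF per test unit: unweighted mean over its control units."""
    if not pair_values:
        raise ValueError("test unit has no valid pairs")
    return float(np.mean(pair_values))


def brace_height(asc: AscendingSegment) -> GeometryResult:
    """Brace height of an ascending rate segment, in % rTri.

    The segment is normalised to the unit square (time and rate each
    affinely mapped to [0, 1]); the chord is the hypotenuse (0,0)-(1,1).
    d_max is the maximal signed orthogonal distance from the curve to the
    chord (positive above); brace height normalises d_max by the distance
    from the right-angle vertex (0, 1) to the chord, i.e.
    brace = 100 * d_max * sqrt(2) = 100 * max(y - x).

    A concave (PIC-accelerated then saturating) profile bulges above the
    chord; a curve through the vertex itself scores 100.  Negative values
    (curve below the chord) are reported as-is, not clipped.
    """
    if asc.degenerate:
        raise ValueError(f"unit {asc.unit_id}: degenerate ascending phase")
    x = (asc.time - asc.time[0]) / (asc.time[-1] - asc.time[0])
    y = (asc.rate - asc.rate[0]) / (asc.rate[-1] - asc.rate[0])
    dev = y - x
    # largest-magnitude signed deviation: a curve bulging below the chord
    # (endpoint deviations are exactly zero) reports a negative height
    i = int(np.argmax(np.abs(dev)))
    d_max = float(dev[i] / np.sqrt(2.0))
    return GeometryResult(
        brace_height=100.0 * float(dev[i]),
        d_max=d_max,
        insertion_time=float(asc.time[i]),
    )


def attenuation_slope(
    asc: AscendingSegment, insertion_time: float, torque: FilteredTorque
) -> float:
    """OLS slope of rate (pps) vs torque (%MVT) after the brace insertion.

    Fitted over the grid samples from the brace-height insertion to the
    ascending-phase peak; torque is linearly interpolated onto the rate
    grid.  A saturated (PIC-dominated) unit shows a flatter slope than one
    still tracking drive linearly.
    """
    mask = asc.time >= insertion_time - 1e-12
    if int(mask.sum()) < 3:
        raise ValueError("fewer than 3 samples between insertion and peak")
    tq = torque.at(asc.time[mask])
    if np.ptp(tq) == 0:
        raise ValueError("torque constant over the attenuation window")
    slope = np.polyfit(tq, asc.rate[mask], 1)[0]
    return float(slope)


def thresholds(
    sr: SmoothedRate, torque: FilteredTorque
) -> tuple[float, float, float]:
    """Recruitment/derecruitment thresholds (% of peak torque) + peak rate.

    Thresholds are the filtered torque read at the unit's first and last
    firing; peak discharge rate is the smoothed-curve maximum.
    """
    if sr.t_rec < torque.time[0] - 1e-9 or sr.t_derec > torque.time[-1] + 1e-9:
        raise ValueError(
            f"unit {sr.unit_id}: firing landmarks outside the torque record"
        )
    rt = float(torque.at(sr.t_rec))
    dt_ = float(torque.at(sr.t_derec))
    return rt, dt_, sr.peak_rate


def unit_geometry(sr: SmoothedRate, torque: FilteredTorque) -> GeometryResult:
    """Brace height + attenuation slope for one unit, or raise if degenerate."""
    asc = ascending_phase(sr)
    geo = brace_height(asc)
    try:
        geo.attenuation_slope = attenuation_slope(asc, geo.insertion_time, torque)
    except ValueError:
        geo.attenuation_slope = None
    return geo
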