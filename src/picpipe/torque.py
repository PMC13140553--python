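"""Torque-trace conditioning, ramp quality control, and handgrip impulse.

Torque is low-pass filtered (5th-order Butterworth, 10 Hz cut-off) and
expressed as % of the participant's peak torque before any threshold or
slope is read off it.  The filter is applied forward-backward so that
recruitment/derecruitment timing is not biased by filter delay; the
effective magnitude response is the squared single-pass response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .datamodel import QCResult, RampTrial

#: Filter order and cut-off frequency (Hz) for the torque low-pass.
TORQUE_FILTER_ORDER = 5
TORQUE_FILTER_CUTOFF_HZ = 10.0

#: A trial fails QC when |performed - target| exceeds this % of peak torque.
QC_DEVIATION_LIMIT_PCT = 5.0


@dataclass
class FilteredTorque:
    """Zero-phase low-pass filtered torque in % of peak torque."""

    time: np.ndarray
    torque_pct: np.ndarray
    fs: float

    def at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Torque (% of peak) at time ``t``, linearly interpolated."""
        return np.interp(t, self.time, self.torque_pct)


def filter_torque(trial: RampTrial) -> FilteredTorque:
    """Low-pass filter a raw torque trace and normalise to % of peak.

    Applies the 5th-order Butterworth at 10 Hz forward and backward
    (zero phase) with reflective edge padding, then divides by the
    trial's peak torque.

    Raises
    ------
    ValueError
        If the sampling rate puts the 10 Hz cut-off at or above Nyquist.
    """
    if trial.fs <= 2 * TORQUE_FILTER_CUTOFF_HZ:
        raise ValueError(
            f"sampling rate {trial.fs} Hz too low for a "
            f"{TORQUE_FILTER_CUTOFF_HZ} Hz cut-off (Nyquist violation)"
        )
    sos = signal.butter(
        TORQUE_FILTER_ORDER, TORQUE_FILTER_CUTOFF_HZ, output="sos", fs=trial.fs
    )
    padlen = min(len(trial.torque_raw) - 1, int(3 * trial.fs / TORQUE_FILTER_CUTOFF_HZ))
    filtered = signal.sosfiltfilt(
        sos, trial.torque_raw, padtype="even", padlen=padlen
    )
    pct = 100.0 * filtered / trial.peak_torque
    return FilteredTorque(time=trial.time, torque_pct=pct, fs=trial.fs)


def ramp_qc(filtered: FilteredTorque, target_pct: np.ndarray) -> QCResult:
    """Check a performed ramp against its requested triangular path.

    ``max_abrupt_deviation`` is the largest |performed - target| in % of
    peak torque anywhere in the ramp; the trial passes iff it stays at or
    below 5%.  ``tracking_error_area`` integrates |performed - target|
    over time (trapezoid), a secondary consistency metric.
    """
    target_pct = np.asarray(target_pct, dtype=float)
    if target_pct.shape != filtered.torque_pct.shape:
        raise ValueError("target path must be on the same grid as the torque")
    dev = np.abs(filtered.torque_pct - target_pct)
    max_dev = float(np.max(dev))
    area = float(np.trapezoid(dev, filtered.time))
    return QCResult(
        passed=max_dev <= QC_DEVIATION_LIMIT_PCT,
        max_abrupt_deviation=max_dev,
        tracking_error_area=area,
    )


def impulse(force: np.ndarray, fs: float) -> float:
    """Impulse (N*s): trapezoidal time-integral of a force trace."""
    force = np.asarray(force, dtype=float)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if force.size < 2:
        raise ValueError("need at least 2 samples to integrate")
    return float(np.trapezoid(force, dx=1.0 / fs))


def handgrip_profile(
    peak_force: float, fraction: float, duration: float, fs: float = 100.0
) -> np.ndarray:
    """Idealised rectangular handgrip force profile.

    Constant force at ``fraction`` of ``peak_force`` held for ``duration``
    seconds, sampled at ``fs``; endpoints included so the trapezoidal
    impulse of the rectangle is exactly fraction * peak_force * duration.
    """
    n = int(round(duration * fs)) + 1
    return np.full(n, fraction * peak_force)
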