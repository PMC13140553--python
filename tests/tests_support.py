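"""Shared fixture helpers for constructing synthetic smoothed-rate curves."""

import numpy as np

from picpipe.smoothing import GRID_DT, SmoothedRate


def tent_curve(t0, t1, lo, hi, unit_id="u", descending=False):
    """A symmetric rise-and-fall smoothed-rate curve on [t0, t1].

    With ``descending`` the curve falls monotonically instead (useful to
    break rate-rate correlation against a tent-shaped partner).
    """
    n = int(round((t1 - t0) / GRID_DT)) + 1
    t = t0 + GRID_DT * np.arange(n)
    if descending:
        r = hi - (hi - lo) * (t - t0) / (t1 - t0)
    else:
        mid = (t0 + t1) / 2
        frac = np.where(t <= mid, (t - t0) / (mid - t0), (t1 - t) / (t1 - mid))
        r = lo + (hi - lo) * frac
    i = int(np.argmax(r))
    return SmoothedRate(
        grid_time=t, rate=r, t_rec=float(t0), t_derec=float(t1),
        t_peak=float(t[i]), peak_rate=float(r[i]), unit_id=unit_id,
    )
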