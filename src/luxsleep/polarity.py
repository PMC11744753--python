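"""Circular "polarity" of sleep stages and of daytime illuminance.

Each 30-s epoch of a given stage inside the sleep period is a unit vector
on the 24-h circle, at the angle of its clock time (24 h = one full turn,
so 1 h = 15 degrees). The resultant of all such vectors gives, through its
angle, a centroid clock time for the stage, and through its length a
strength: high when the stage is abundant and temporally clustered, low
when it is sparse or dispersed. The same construction with vector lengths
equal to hourly median illuminance (instead of unit length) describes the
daytime light profile.

Strength is reported in raw units (epochs; lx.bins); the divisors used to
fit the vectors onto a polar plot are presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clock import DAY_S
from .sleep import Hypnogram, sleep_offset_index, sleep_onset_index

STRENGTH_TOL = 1e-9  # below this the centroid direction is meaningless


def clock_angle(t_s):
    """Angle (rad) of a clock time on the 24-h circle: 2*pi * t / 24 h."""
    return 2.0 * np.pi * (np.asarray(t_s, dtype=float) % DAY_S) / DAY_S


def angle_to_clock(angle: float) -> float:
    """Inverse of :func:`clock_angle`, folded into [0, 24 h)."""
    return (angle % (2.0 * np.pi)) / (2.0 * np.pi) * DAY_S


@dataclass
class PolarityVector:
    subject: str  # stage label or "illuminance"
    centroid_clock_s: float | None  # None when strength below tolerance
    strength: float
    n_contributors: int
    total_weight: float  # == n_contributors for unit-weight stage vectors


def resultant(times_s, weights=None, subject: str = "") -> PolarityVector:
    """Sum (weighted) unit vectors at clock-time angles; return the resultant."""
    times_s = np.asarray(times_s, dtype=float)
    if weights is None:
        weights = np.ones_like(times_s)
    else:
        weights = np.asarray(weights, dtype=float)
    ang = clock_angle(times_s)
    x = float(np.sum(weights * np.cos(ang)))
    y = float(np.sum(weights * np.sin(ang)))
    strength = float(np.hypot(x, y))
    centroid = angle_to_clock(np.arctan2(y, x)) if strength >= STRENGTH_TOL \
        else None
    return PolarityVector(subject, centroid, strength, int(times_s.size),
                          float(np.sum(weights)))


def stage_polarity(h: Hypnogram, stage: str,
                   onset_index: int | None = None,
                   offset_index: int | None = None) -> PolarityVector:
    """Polarity vector of a stage's epochs within the sleep period.

    Epoch vectors are anchored at epoch start times. Zero matching epochs
    yield strength 0 and an undefined centroid (flagged, not raised).
    """
    i0 = sleep_onset_index(h) if onset_index is None else onset_index
    i1 = sleep_offset_index(h) if offset_index is None else offset_index
    idx = i0 + np.nonzero(h.stages[i0:i1] == stage)[0]
    return resultant(h.epoch_start_linear(idx), subject=stage)


def illuminance_polarity(bin_start_s, weights_lx,
                         bin_s: int = 3600) -> PolarityVector:
    """Lux-weighted polarity of a binned daytime illuminance profile.

    Vectors sit at bin midpoints with length equal to the bin's (median)
    illuminance; the default hourly resolution matches how the daytime
    profile is usually displayed, but any bin width works.
    """
    mids = np.asarray(bin_start_s, dtype=float) + bin_s / 2.0
    return resultant(mids, np.asarray(weights_lx, dtype=float),
                     subject="illuminance")


def rel_onset_hours(centroid_clock_s: float | None,
                    onset_clock_s: float) -> float:
    """Centroid time re-expressed as hours after sleep onset, in [0, 24)."""
    if centroid_clock_s is None:
        return float("nan")
    return ((centroid_clock_s - onset_clock_s) % DAY_S) / 3600.0


@dataclass
class PolarityReport:
    rem: PolarityVector
    sws: PolarityVector
    rem_time_rel_onset_h: float
    sws_time_rel_onset_h: float


def polarity_report(h: Hypnogram) -> PolarityReport:
    """REM and SWS polarity of one hypnogram, plus onset-relative times."""
    i0 = sleep_onset_index(h)
    i1 = sleep_offset_index(h)
    onset_clock = float(h.epoch_clock(i0))
    rem = stage_polarity(h, "R", i0, i1)
    sws = stage_polarity(h, "N3", i0, i1)
    return PolarityReport(
        rem, sws,
        rel_onset_hours(rem.centroid_clock_s, onset_clock),
        rel_onset_hours(sws.centroid_clock_s, onset_clock),
    )


def plot_scaling(v: PolarityVector, divisor: float) -> float:
    """Display length of a vector on a polar plot; never used in statistics."""
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return v.strength / divisor


def plot_polarity(vectors, path, divisors=None) -> None:
    """Render polarity vectors on a 24-h polar plot (midnight at top)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    divisors = divisors or {}
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_xticks(np.linspace(0, 2 * np.pi, 8, endpoint=False))
    ax.set_xticklabels([f"{h:02d}:00" for h in range(0, 24, 3)])
    for v in vectors:
        if v.centroid_clock_s is None:
            continue
        theta = 2 * np.pi * v.centroid_clock_s / DAY_S
        r = plot_scaling(v, divisors.get(v.subject, 1.0))
        ax.annotate("", xy=(theta, r), xytext=(theta, 0),
                    arrowprops={"arrowstyle": "-|>", "lw": 2})
        ax.text(theta, r, v.subject)
    ax.set_rlabel_position(90)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
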