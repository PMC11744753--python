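"""Dim-light melatonin onset (DLMO) from evening saliva series.

Salivary melatonin is flat at a low daytime baseline and then rises
roughly linearly in the evening. The two-piece "hockey-stick" model

    c(t) = b                   for t <= tau
    c(t) = b + s * (t - tau)   for t >  tau

is fitted by least squares, with the breakpoint tau searched on a 1-min
grid across the sampling interval (for each candidate tau, b and s have a
closed-form solution; ties in RSS go to the earlier tau). DLMO is the time
at which the *fitted* curve crosses the 10 pg/mL threshold,
tau + (10 - b) / s; the raw linear-interpolation crossing of the data is
also reported for transparency.

Degenerate situations are flagged rather than guessed at: a baseline
already above threshold, a fitted curve that never reaches threshold
within one hour past the last sample, or a series with no rise at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clock import DAY_S

DLMO_THRESHOLD_PG_ML = 10.0
TAU_GRID_S = 60
#: evening clock times are mapped onto a linear axis starting here, so a
#: cohort spanning midnight still averages correctly
EVENING_AXIS_START_S = 18 * 3600


class NoMelatoninRiseError(ValueError):
    """The series shows no positive evening rise to fit."""


@dataclass
class MelatoninSeries:
    """Evening saliva samples: clock times (s) and concentrations (pg/mL)."""

    times_s: np.ndarray
    conc: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.times_s = evening_linear(np.asarray(self.times_s, dtype=float))
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times_s.shape != self.conc.shape:
            raise ValueError("times and concentrations must align")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")


def evening_linear(times_s):
    """Fold clock times onto a linear evening axis (18:00 -> 18:00 + 24 h)."""
    t = np.asarray(times_s, dtype=float) % DAY_S
    return np.where(t < EVENING_AXIS_START_S, t + DAY_S, t)


@dataclass
class DLMOResult:
    breakpoint_s: float  # tau, evening-linear seconds
    baseline_pg_ml: float
    rise_slope_pg_ml_h: float
    rss: float
    threshold_pg_ml: float
    dlmo_s: float | None  # evening-linear seconds; None when undefined
    dlmo_interp_s: float | None  # raw linear-interpolation crossing
    flags: tuple[str, ...] = ()


def linear_crossing(series: MelatoninSeries,
                    threshold: float = DLMO_THRESHOLD_PG_ML) -> float | None:
    """First upward linear-interpolation crossing of the raw data."""
    t, c = series.times_s, series.conc
    if c[0] >= threshold:
        return float(t[0])
    above = np.nonzero(c >= threshold)[0]
    if above.size == 0:
        return None
    j = int(above[0])
    frac = (threshold - c[j - 1]) / (c[j] - c[j - 1])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def fit_hockey_stick(
    series: MelatoninSeries,
    threshold: float = DLMO_THRESHOLD_PG_ML,
    grid_s: int = TAU_GRID_S,
) -> DLMOResult:
    """Grid-search least-squares fit of the two-piece model; global minimum.

    Requires at least four samples that are not all equal. Raises
    :class:`NoMelatoninRiseError` when the best fit has non-positive slope.
    """
    t_s, y = series.times_s, series.conc
    if t_s.size < 4:
        raise ValueError("need at least 4 samples to fit")
    if np.allclose(y, y[0]):
        raise NoMelatoninRiseError("constant series: no melatonin rise")
    t = (t_s - t_s[0]) / 3600.0  # hours from first sample
    n = t.size
    taus = np.arange(t_s[0], t_s[-1], grid_s)
    tau_h = (taus - t_s[0]) / 3600.0
    # closed-form 2-parameter least squares, vectorised over the tau grid
    f = np.maximum(t[None, :] - tau_h[:, None], 0.0)  # (G, n)
    sf = f.sum(axis=1)
    sff = (f * f).sum(axis=1)
    sy = float(y.sum())
    sfy = (f * y).sum(axis=1)
    det = n * sff - sf * sf
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sfy - sf * sy) / det
        intercept = (sy - slope * sf) / n
    # taus leaving < 2 distinct rise points make the model unidentifiable
    ok = det > 1e-12
    slope = np.where(ok, slope, 0.0)
    intercept = np.where(ok, intercept, sy / n)
    resid = y[None, :] - (intercept[:, None] + slope[:, None] * f)
    rss = (resid * resid).sum(axis=1)
    best = int(np.argmin(rss))  # argmin returns the first (earliest) minimum
    b, s, tau = float(intercept[best]), float(slope[best]), float(taus[best])
    flags: list[str] = []
    if s <= 0:
        raise NoMelatoninRiseError("best fit has non-positive slope")
    if b < 0:
        warnings.warn("fitted baseline below 0 pg/mL; clamped",
                      stacklevel=2)
        flags.append("baseline_clamped")
        b = 0.0
        fb = f[best]
        s = float((fb * y).sum() / (fb * fb).sum())
        rss_b = float(((y - s * fb) ** 2).sum())
    else:
        rss_b = float(rss[best])
    # DLMO on the fitted curve
    dlmo: float | None
    if b >= threshold:
        flags.append("baseline_above_threshold")
        dlmo = float(t_s[0])
    else:
        dlmo = tau + (threshold - b) / s * 3600.0
        if dlmo > t_s[-1] + 3600.0:
            flags.append("threshold_not_reached")
            dlmo = None
    return DLMOResult(tau, b, s, rss_b, threshold, dlmo,
                      linear_crossing(series, threshold), tuple(flags))


def dlmo_from_fit(result: DLMOResult) -> float | None:
    """DLMO time implied by a fitted model (already stored on the result)."""
    return result.dlmo_s


def cohort_dlmo(dlmo_times_s) -> tuple[float, float]:
    """Mean and SD (s) of DLMO times on the linear evening axis."""
    t = evening_linear(np.asarray(list(dlmo_times_s), dtype=float))
    if t.size == 0:
        raise ValueError("no defined DLMO times")
    sd = float(np.std(t, ddof=1)) if t.size > 1 else 0.0
    return float(np.mean(t)), sd
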