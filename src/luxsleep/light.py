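"""Cleaning and descriptive summaries of 1-Hz eye-level illuminance logs.

The wearable sensors report reliable illuminance in the 1-40,000 lx range at
1 Hz. Cleaning maps each raw reading onto a status:

* negative readings are physically impossible and flagged ``artifact``;
* readings below 1 lx are below the reliable floor; they are still "very
  low light", so they are clipped to 1 lx (``clipped_low``) rather than
  discarded (a raw 0 is treated as a below-detection reading, not an
  artifact);
* readings above 40,000 lx are clipped to 40,000 lx (``clipped_high``);
* seconds with no reading at all are ``missing``.

Statistics (medians, means, percentiles, time-below-threshold fractions)
use valid + clipped samples only; artifacts and gaps never contribute.
Because the headline summaries are medians, the clipping at either end of
the range has negligible influence on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock import format_clock, parse_clock

# status codes (int8 in the arrays)
VALID = 0
CLIPPED_LOW = 1
CLIPPED_HIGH = 2
ARTIFACT = 3
MISSING = 4
STATUS_NAMES = ("valid", "clipped_low", "clipped_high", "artifact", "missing")

SENSOR_MIN_LX = 1.0
SENSOR_MAX_LX = 40000.0
DEFAULT_THRESHOLDS_LX = (20.0, 80.0, 200.0, 500.0)
MAX_EXPOSURE_BIN_S = 1200  # 20-minute bins for time of maximal exposure


@dataclass(frozen=True)
class TimeWindow:
    """Half-open clock interval [start_s, end_s); windows never wrap."""

    start_s: int
    end_s: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"empty or inverted window: {self.label or self}")
        if not (0 <= self.start_s and self.end_s <= 86400):
            raise ValueError("window must lie within one calendar day")
        if not self.label:
            object.__setattr__(
                self, "label",
                f"{format_clock(self.start_s)}-{format_clock(self.end_s)}")

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


def window(start: str, end: str) -> TimeWindow:
    return TimeWindow(parse_clock(start), parse_clock(end))


ALL_DAY = window("07:00", "19:00")
MORNING = window("07:00", "11:00")
MIDDAY = window("11:00", "15:00")
AFTERNOON = window("15:00", "19:00")
FRAMES_4H = (MORNING, MIDDAY, AFTERNOON)
FRAMES_2H = tuple(
    window(f"{h:02d}:00", f"{h + 2:02d}:00") for h in range(7, 19, 2)
)
#: the seven time frames entering the association analysis
ASSOCIATION_FRAMES = FRAMES_2H + (ALL_DAY,)
#: the ten windows reported in the descriptive cohort table
SUMMARY_WINDOWS = (ALL_DAY,) + FRAMES_4H + FRAMES_2H


@dataclass
class LightRecording:
    """One participant-day of cleaned 1-Hz illuminance on a full-second grid.

    ``raw`` retains the as-recorded values (NaN where no sample existed) so
    that re-cleaning a cleaned recording is exactly idempotent; ``value``
    holds the cleaned values and is NaN for artifact/missing samples.
    """

    participant_id: str
    date: str
    time_s: np.ndarray  # int seconds since midnight, strictly increasing
    raw: np.ndarray
    value: np.ndarray
    status: np.ndarray  # int8 codes
    window: TimeWindow = field(default_factory=lambda: ALL_DAY)

    @property
    def n(self) -> int:
        return len(self.time_s)


def _classify(raw: np.ndarray):
    value = raw.astype(float).copy()
    status = np.full(raw.shape, VALID, dtype=np.int8)
    absent = np.isnan(raw)
    status[absent] = MISSING
    neg = ~absent & (raw < 0)
    status[neg] = ARTIFACT
    value[absent | neg] = np.nan
    low = ~absent & (raw >= 0) & (raw < SENSOR_MIN_LX)
    status[low] = CLIPPED_LOW
    value[low] = SENSOR_MIN_LX
    high = ~absent & (raw > SENSOR_MAX_LX)
    status[high] = CLIPPED_HIGH
    value[high] = SENSOR_MAX_LX
    return value, status


def clean_samples(
    times,
    values,
    participant_id: str = "",
    date: str = "",
    analysis_window: TimeWindow = ALL_DAY,
) -> LightRecording:
    """Clean raw (time, lux) rows into a status-flagged 1-Hz recording.

    ``times`` are integer seconds since midnight, strictly increasing;
    duplicates or unsorted input are structural errors. The result is laid
    out on the full one-sample-per-second grid of ``analysis_window``;
    seconds without a reading become ``missing``. Readings outside the
    window are ignored.
    """
    times = np.asarray(times, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have equal length")
    if times.size:
        diffs = np.diff(times)
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            t = times[bad[0] + 1]
            kind = "duplicated" if diffs[bad[0]] == 0 else "unsorted"
            raise ValueError(
                f"{kind} timestamp at {format_clock(t, with_seconds=True)}")
    grid = np.arange(analysis_window.start_s, analysis_window.end_s,
                     dtype=np.int64)
    raw = np.full(grid.shape, np.nan)
    inside = (times >= analysis_window.start_s) & (times < analysis_window.end_s)
    raw[times[inside] - analysis_window.start_s] = values[inside]
    value, status = _classify(raw)
    return LightRecording(participant_id, date, grid, raw, value, status,
                          analysis_window)


def clean_recording(rec: LightRecording) -> LightRecording:
    """Re-apply the cleaning rules to a recording (idempotent)."""
    value, status = _classify(rec.raw)
    return LightRecording(rec.participant_id, rec.date, rec.time_s,
                          rec.raw.copy(), value, status, rec.window)


def _window_slice(rec: LightRecording, win: TimeWindow) -> slice:
    lo = int(np.searchsorted(rec.time_s, win.start_s, side="left"))
    hi = int(np.searchsorted(rec.time_s, win.end_s, side="left"))
    return slice(lo, hi)


def usable_values(rec: LightRecording, win: TimeWindow | None = None) -> np.ndarray:
    """Valid + clipped sample values inside ``win`` (default: whole window)."""
    sl = _window_slice(rec, win or rec.window)
    status = rec.status[sl]
    return rec.value[sl][status <= CLIPPED_HIGH]


def valid_percent(rec: LightRecording, win: TimeWindow | None = None) -> float:
    """Percent of the window's nominal 1-Hz samples that are usable.

    The denominator is the expected sample count (window length in
    seconds), so gaps in the log count against the recording.
    """
    win = win or rec.window
    n_valid = usable_values(rec, win).size
    return 100.0 * n_valid / win.duration_s


@dataclass
class LightSummary:
    window: TimeWindow
    median_lx: float
    mean_lx: float
    p10_lx: float
    p90_lx: float
    frac_below: dict[float, float]
    valid_percent: float
    n_valid: int
    missing: bool = False  # True when the window held no usable sample


def frac_below(
    rec: LightRecording,
    win: TimeWindow | None = None,
    thresholds=DEFAULT_THRESHOLDS_LX,
) -> dict[float, float]:
    """Percent of usable samples strictly below each threshold.

    Strict "<" means a sample exactly at a threshold counts as not below;
    the map is non-decreasing in the threshold by construction.
    """
    vals = usable_values(rec, win)
    if vals.size == 0:
        return {float(t): float("nan") for t in thresholds}
    return {float(t): 100.0 * float(np.count_nonzero(vals < t)) / vals.size
            for t in thresholds}


def window_stats(
    rec: LightRecording,
    win: TimeWindow | None = None,
    thresholds=DEFAULT_THRESHOLDS_LX,
) -> LightSummary:
    """Median / mean / 10th / 90th percentile summary over usable samples.

    Percentiles use linear interpolation between order statistics (the
    median is the usual midpoint of the two central values for even
    counts).
    """
    win = win or rec.window
    vals = usable_values(rec, win)
    vp = valid_percent(rec, win)
    if vals.size == 0:
        nan = float("nan")
        return LightSummary(win, nan, nan, nan, nan,
                            frac_below(rec, win, thresholds), vp, 0, True)
    p10, med, p90 = np.percentile(vals, [10, 50, 90])
    return LightSummary(win, float(med), float(vals.mean()), float(p10),
                        float(p90), frac_below(rec, win, thresholds), vp,
                        int(vals.size), False)


def minutes_above(rec: LightRecording, threshold_lx: float,
                  win: TimeWindow | None = None) -> float:
    """Minutes of usable samples at or above ``threshold_lx`` (1 s = 1/60 min)."""
    vals = usable_values(rec, win)
    return float(np.count_nonzero(vals >= threshold_lx)) / 60.0


def max_exposure_time(rec: LightRecording, bin_s: int = MAX_EXPOSURE_BIN_S) -> float:
    """Clock time (s) of the centre of the 20-min bin with the largest mean.

    The analysis window is partitioned into consecutive ``bin_s`` bins; the
    bin statistic is the mean of its usable samples; ties go to the
    earliest bin; empty bins are skipped. Raises if no bin holds a usable
    sample.
    """
    win = rec.window
    edges = np.arange(win.start_s, win.end_s + 1, bin_s)
    best_mean, best_mid = -np.inf, None
    for lo, hi in zip(edges[:-1], edges[1:]):
        vals = usable_values(rec, TimeWindow(int(lo), int(hi)))
        if vals.size == 0:
            continue
        m = float(vals.mean())
        if m > best_mean:  # strict ">" keeps the earliest bin on ties
            best_mean, best_mid = m, (lo + hi) / 2.0
    if best_mid is None:
        raise ValueError("no usable samples in any bin")
    return float(best_mid)


def frame_medians(rec: LightRecording,
                  frames=ASSOCIATION_FRAMES) -> dict[str, float]:
    """Median usable illuminance per association time frame (NaN if empty)."""
    out = {}
    for fr in frames:
        vals = usable_values(rec, fr)
        out[fr.label] = float(np.median(vals)) if vals.size else float("nan")
    return out


def cohort_table(
    recordings,
    windows=SUMMARY_WINDOWS,
    thresholds=DEFAULT_THRESHOLDS_LX,
) -> pd.DataFrame:
    """Two-stage (individual-first) descriptive table across participant-days.

    Per window: the group median and range of the individual medians, the
    group mean +/- SD of the individual means, and the mean +/- SD of the
    individual below-threshold percentages and valid percentages. Windows
    where an individual had no usable sample are dropped pairwise for that
    individual (cells from zero individuals are NaN).
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings")
    rows = []
    for win in windows:
        med, mean, vps = [], [], []
        fb: dict[float, list[float]] = {float(t): [] for t in thresholds}
        for rec in recordings:
            s = window_stats(rec, win, thresholds)
            vps.append(s.valid_percent)
            if s.missing:
                continue
            med.append(s.median_lx)
            mean.append(s.mean_lx)
            for t, v in s.frac_below.items():
                fb[t].append(v)
        row = {
            "window": win.label,
            "n": len(med),
            "median_lx": float(np.median(med)) if med else np.nan,
            "median_min_lx": float(np.min(med)) if med else np.nan,
            "median_max_lx": float(np.max(med)) if med else np.nan,
            "mean_lx": float(np.mean(mean)) if mean else np.nan,
            "mean_sd_lx": float(np.std(mean, ddof=1)) if len(mean) > 1 else 0.0
            if mean else np.nan,
            "valid_percent_mean": float(np.mean(vps)),
            "valid_percent_sd": float(np.std(vps, ddof=1)) if len(vps) > 1 else 0.0,
        }
        for t in thresholds:
            vals = fb[float(t)]
            row[f"pct_below_{int(t)}lx_mean"] = (
                float(np.mean(vals)) if vals else np.nan)
            row[f"pct_below_{int(t)}lx_sd"] = (
                float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                if vals else np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("window")
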