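"""Hypnogram parsing and sleep-architecture metrics.

A hypnogram is an ordered sequence of 30-s epochs scored W / N1 / N2 / N3 /
R. Sleep onset follows the "first 2 min of N2" convention: the first N2
epoch that opens a four-epoch run containing no wake (other sleep stages
may appear inside the run). The sleep period (SPT) runs from onset to the
end of the last non-wake epoch; total sleep time (TST) is SPT minus wake
within it; stage durations and percentages are reported relative to SPT.

All epoch arithmetic happens on a linear time axis anchored at the
recording start, so recordings crossing midnight need no special casing;
clock times are folded back onto [0, 24 h) only for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clock import DAY_S, parse_clock

STAGES = ("W", "N1", "N2", "N3", "R")
SLEEP_STAGES = ("N1", "N2", "N3", "R")
ONSET_RUN_EPOCHS = 4  # 2 min at 30 s per epoch
DEFAULT_LIGHTS_OFF_S = parse_clock("23:00")


class SleepOnsetError(ValueError):
    """No epoch satisfies the sleep-onset rule."""


@dataclass
class Hypnogram:
    start_s: int  # clock time of the first epoch, seconds since midnight
    stages: np.ndarray  # dtype '<U2', values in STAGES
    epoch_s: int = 30

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="<U2")
        if self.stages.size == 0:
            raise ValueError("empty hypnogram")
        bad = set(self.stages.tolist()) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.stages)

    def epoch_start_linear(self, index) -> np.ndarray | float:
        """Start time of epoch(s), linear seconds from midnight of day 0."""
        return self.start_s + np.asarray(index) * self.epoch_s

    def epoch_clock(self, index) -> np.ndarray | float:
        return self.epoch_start_linear(index) % DAY_S


def sleep_onset_index(h: Hypnogram) -> int:
    """Index of the first N2 epoch opening a 4-epoch wake-free run."""
    is_w = h.stages == "W"
    is_n2 = h.stages == "N2"
    for i in np.nonzero(is_n2)[0]:
        if i + ONSET_RUN_EPOCHS <= h.n and not is_w[i:i + ONSET_RUN_EPOCHS].any():
            return int(i)
    raise SleepOnsetError("no sleep onset")


def sleep_offset_index(h: Hypnogram) -> int:
    """End-exclusive index of the last non-wake epoch ("end of sleep")."""
    non_w = np.nonzero(h.stages != "W")[0]
    if non_w.size == 0:
        raise SleepOnsetError("recording contains no sleep")
    return int(non_w[-1]) + 1


@dataclass
class SleepMetrics:
    onset_index: int
    offset_index: int  # end-exclusive
    onset_clock_s: float
    offset_clock_s: float
    midpoint_clock_s: float
    sleep_latency_min: float
    spt_min: float
    tst_min: float
    efficiency_percent: float
    rems_latency_min: float  # NaN when no REM after onset
    stage_minutes: dict[str, float]  # over [onset, offset)
    stage_percent_spt: dict[str, float]
    wake_within_min: float
    flags: tuple[str, ...] = ()


def rems_latency(h: Hypnogram, onset_index: int | None = None) -> float:
    """Minutes from sleep onset to the first REM epoch (NaN if none)."""
    i0 = sleep_onset_index(h) if onset_index is None else onset_index
    rem = np.nonzero(h.stages[i0:] == "R")[0]
    if rem.size == 0:
        return float("nan")
    return float(rem[0]) * h.epoch_s / 60.0


def stage_stats(h: Hypnogram, onset_index: int | None = None,
                offset_index: int | None = None):
    """(minutes, percent-of-SPT) per stage, counted within [onset, offset)."""
    i0 = sleep_onset_index(h) if onset_index is None else onset_index
    i1 = sleep_offset_index(h) if offset_index is None else offset_index
    spt_min = (i1 - i0) * h.epoch_s / 60.0
    minutes = {}
    for st in STAGES:
        minutes[st] = float(np.count_nonzero(h.stages[i0:i1] == st)) \
            * h.epoch_s / 60.0
    percent = {st: 100.0 * m / spt_min for st, m in minutes.items()}
    return minutes, percent


def compute_metrics(h: Hypnogram,
                    lights_off_s: int = DEFAULT_LIGHTS_OFF_S) -> SleepMetrics:
    i0 = sleep_onset_index(h)
    i1 = sleep_offset_index(h)
    epoch_min = h.epoch_s / 60.0
    onset_lin = h.epoch_start_linear(i0)
    offset_lin = h.epoch_start_linear(i1)
    spt_min = (i1 - i0) * epoch_min
    wake_within = float(np.count_nonzero(h.stages[i0:i1] == "W")) * epoch_min
    tst_min = spt_min - wake_within
    minutes, percent = stage_stats(h, i0, i1)
    rl = rems_latency(h, i0)
    flags = () if np.isfinite(rl) else ("no_rem_after_onset",)
    # latency measured from lights-off; the recording may begin at lights-off
    latency_min = (((h.start_s - lights_off_s) % DAY_S)
                   + i0 * h.epoch_s) / 60.0
    return SleepMetrics(
        onset_index=i0,
        offset_index=i1,
        onset_clock_s=float(onset_lin % DAY_S),
        offset_clock_s=float(offset_lin % DAY_S),
        midpoint_clock_s=float((onset_lin + spt_min * 30.0) % DAY_S),
        sleep_latency_min=latency_min,
        spt_min=spt_min,
        tst_min=tst_min,
        efficiency_percent=100.0 * tst_min / spt_min,
        rems_latency_min=rl,
        stage_minutes=minutes,
        stage_percent_spt=percent,
        wake_within_min=wake_within,
        flags=flags,
    )
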