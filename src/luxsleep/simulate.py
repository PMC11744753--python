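"""Synthetic light logs, hypnograms and melatonin series.

The generator reproduces the statistical structure the pipeline assumes,
at the scale of the emulated study (eleven participants wearing 1-Hz
eye-level light sensors over urban winter days; nine with an in-lab
polysomnography night starting 23:00 and half-hourly evening saliva
sampling), so that every stage of the analysis can be exercised without
any real recordings.

* Light days are a log-normal indoor baseline shaped by a diurnal
  envelope peaking mid-morning (with a small secondary noon peak),
  interrupted by Poisson-timed piecewise-constant outdoor bursts of
  3,000-40,000 lx lasting one to ten minutes. Negative artifact readings
  and per-sample gaps are injected at fixed rates chosen to land near the
  ~87% valid-data fraction typical of such wearables. Bursts being brief
  and extreme is what makes day medians robust while day means are not.
* Hypnograms alternate NREM/REM cycles with slow-wave sleep weighted to
  the early cycles and REM episodes lengthening across the night; REM
  latency is drawn around its target and planted exactly (to epoch
  resolution), and brief wake epochs are sprinkled through the sleep
  period.
* Melatonin series follow the flat-baseline / linear-rise shape with the
  threshold crossing planted at the requested onset time.

Cohorts can plant a rank correlation between one light frame's median and
REM latency through a Gaussian copula: the latent correlation is chosen as
r = 2 sin(pi * rho_S / 6), the monotone map whose population Spearman
coefficient equals the requested value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .clock import parse_clock
from .dlmo import MelatoninSeries
from .light import ALL_DAY, TimeWindow, window
from .sleep import Hypnogram

#: hourly multipliers of ``indoor_median_lx`` for 07:00..18:00
DEFAULT_ENVELOPE = (0.4, 1.0, 1.5, 1.25, 0.9, 1.1, 0.8, 0.625,
                    0.35, 0.25, 0.2, 0.15)


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


@dataclass(frozen=True)
class LightGenParams:
    indoor_median_lx: float = 40.0
    indoor_log_sd: float = 1.0
    day_log_sd: float = 0.2  # day-to-day scatter of the whole profile
    diurnal_envelope: tuple = DEFAULT_ENVELOPE
    indoor_max_lx: float = 450.0  # indoor baseline ceiling
    outdoor_burst_rate_per_h: float = 0.5
    burst_lx_range: tuple = (3000.0, 40000.0)
    burst_duration_s: tuple = (60.0, 600.0)
    artifact_rate: float = 0.08
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        for r in (self.outdoor_burst_rate_per_h / 24.0, self.artifact_rate,
                  self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.artifact_rate + self.missing_rate > 1.0:
            raise ValueError("artifact_rate + missing_rate must be <= 1")
        lo, hi = self.burst_lx_range
        if not (1.0 <= lo <= hi <= 40000.0):
            raise ValueError("burst range must lie within [1, 40000] lx")


def gen_light_day(
    p: LightGenParams,
    seed=0,
    analysis_window: TimeWindow = ALL_DAY,
    planted_frame: tuple[TimeWindow, float] | None = None,
):
    """One raw participant-day: (times_s, values) with gaps dropped.

    ``planted_frame`` replaces the day-level scale factor inside the given
    window by an explicit multiplier, so a cohort generator can make that
    frame's median a deterministic monotone image of a latent draw.
    """
    rng = _rng(seed)
    win = analysis_window
    n = win.duration_s
    hours = np.arange(win.start_s, win.end_s, 3600) // 3600 - 7
    env = np.asarray(p.diurnal_envelope, dtype=float)[hours % len(
        p.diurnal_envelope)]
    log_med = np.log(p.indoor_median_lx * env).repeat(3600)[:n]
    log_scale = np.full(n, np.log(rng.lognormal(0.0, p.day_log_sd)))
    if planted_frame is not None:
        fwin, factor = planted_frame
        lo = max(fwin.start_s, win.start_s) - win.start_s
        hi = min(fwin.end_s, win.end_s) - win.start_s
        log_scale[lo:hi] = np.log(factor)
    values = np.exp(rng.standard_normal(n) * p.indoor_log_sd
                    + log_med + log_scale)
    np.minimum(values, p.indoor_max_lx, out=values)
    # outdoor bursts: piecewise-constant high-lux episodes. A planted
    # frame stays burst-free so its median is a deterministic monotone
    # image of the planted multiplier (rank-exact planting).
    n_bursts = rng.poisson(p.outdoor_burst_rate_per_h * n / 3600.0)
    if n_bursts:
        baseline = values.copy() if planted_frame is not None else None
        starts = rng.integers(0, n, n_bursts)
        durs = rng.uniform(*p.burst_duration_s, n_bursts).astype(int)
        lux = np.exp(rng.uniform(*np.log(p.burst_lx_range), n_bursts))
        for s0, d, lx in zip(starts, durs, lux):
            values[s0:s0 + d] = lx
        if baseline is not None:
            values[lo:hi] = baseline[lo:hi]
    # artifacts and gaps (disjoint per-sample draws)
    u = rng.random(n)
    artifact = u < p.artifact_rate
    missing = (u >= p.artifact_rate) & (u < p.artifact_rate + p.missing_rate)
    values[artifact] = -rng.uniform(0.5, 5.0, int(artifact.sum()))
    times = np.arange(win.start_s, win.end_s, dtype=np.int64)
    keep = ~missing
    return times[keep], values[keep]


@dataclass(frozen=True)
class SleepGenParams:
    n_cycles: int = 5
    cycle_min: float = 90.0
    rem_latency_min: float = 71.0
    rem_latency_sd: float = 11.8
    sleep_latency_min: float = 26.4
    sleep_latency_sd: float = 15.0
    sws_front_loading: float = 0.6
    rem_back_loading: float = 0.6
    wake_prob: float = 0.066
    rem_fraction: float = 0.231  # of sleep period time
    sws_fraction: float = 0.242
    n1_fraction: float = 0.043
    start_s: int = field(default_factory=lambda: parse_clock("23:00"))
    epoch_s: int = 30

    def __post_init__(self) -> None:
        for c in (self.sws_front_loading, self.rem_back_loading,
                  self.wake_prob):
            if not 0.0 <= c <= 1.0:
                raise ValueError("coefficients must lie in [0, 1]")


def gen_hypnogram(p: SleepGenParams, seed=0) -> Hypnogram:
    """One night: initial wake, then cyclic NREM/REM with SWS front-loaded
    and REM back-loaded; REM latency planted to epoch resolution."""
    rng = _rng(seed)
    epm = 60.0 / p.epoch_s  # epochs per minute
    lat_ep = int(round(np.clip(
        rng.normal(p.sleep_latency_min, p.sleep_latency_sd), 2.0, 80.0) * epm))
    rl_ep = int(round(np.clip(
        rng.normal(p.rem_latency_min, p.rem_latency_sd), 15.0, 140.0) * epm))
    cyc_ep = int(round(p.cycle_min * epm))
    nc = p.n_cycles
    # REM episode lengths grow across the night
    w_rem = 1.0 + p.rem_back_loading * np.arange(nc)
    w_rem /= w_rem.sum()
    # total REM solves T = f * SPT with SPT = rl + T*w0 + (nc-1)*cycle
    t_rem = p.rem_fraction * (rl_ep + (nc - 1) * cyc_ep) \
        / (1.0 - p.rem_fraction * w_rem[0])
    rem_ep = np.maximum(1, np.round(t_rem * w_rem).astype(int))
    nrem_ep = np.concatenate([[rl_ep], cyc_ep - rem_ep[1:]])
    spt_ep = int(nrem_ep.sum() + rem_ep.sum())
    # SWS minutes per cycle, weighted to the early cycles
    w_sws = 1.0 + p.sws_front_loading * np.arange(nc)[::-1]
    w_sws /= w_sws.sum()
    sws_ep = np.round(p.sws_fraction * spt_ep * w_sws).astype(int)
    n1_each = max(0, int(round(p.n1_fraction * spt_ep / nc)))
    stages: list[str] = ["W"] * max(0, lat_ep - 2) + ["N1", "N1"]
    first_rem_abs = len(stages) + rl_ep  # epoch index of the first R
    for i in range(nc):
        part = int(nrem_ep[i])
        n1 = 0 if i == 0 else min(n1_each, max(0, part - 5))
        s = int(min(sws_ep[i], max(0, part - n1 - 5)))  # keep >=4 leading N2
        a = max(4 if i == 0 else 2, (part - n1 - s) // 2)
        b = part - n1 - s - a
        if b < 0:
            a, b = part - n1 - s, 0
        stages += ["N1"] * n1 + ["N2"] * a + ["N3"] * s + ["N2"] * b
        stages += ["R"] * int(rem_ep[i])
    arr = np.array(stages, dtype="<U2")
    onset = max(0, lat_ep - 2) + 2  # first N2 epoch
    # sprinkle wake inside the sleep period, sparing the onset run, the
    # latency-defining first REM epoch, and the final (offset) epoch
    if p.wake_prob > 0:
        cand = np.arange(onset + 4, len(arr) - 1)
        cand = cand[cand != first_rem_abs]
        hit = cand[rng.random(cand.size) < p.wake_prob]
        arr[hit] = "W"
    return Hypnogram(p.start_s, arr, p.epoch_s)


def gen_melatonin(
    dlmo_target_s: float,
    noise_sd: float = 0.5,
    seed=0,
    baseline_pg_ml: float = 2.0,
    slope_pg_ml_h: float = 16.0,
    threshold_pg_ml: float = 10.0,
    participant_id: str = "",
) -> MelatoninSeries:
    """Half-hourly 20:00-23:00 series whose noiseless threshold crossing
    sits exactly at ``dlmo_target_s``."""
    rng = _rng(seed)
    times = np.arange(parse_clock("20:00"), parse_clock("23:00") + 1, 1800)
    tau = dlmo_target_s - (threshold_pg_ml - baseline_pg_ml) \
        / slope_pg_ml_h * 3600.0
    rise_h = np.maximum(times - tau, 0.0) / 3600.0
    conc = baseline_pg_ml + slope_pg_ml_h * rise_h
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, conc.size)
    return MelatoninSeries(times, np.maximum(conc, 0.0), participant_id)


@dataclass(frozen=True)
class CohortGenParams:
    n_subjects: int = 9
    planted_rho: float = 0.0
    frame: TimeWindow = field(default_factory=lambda: window("11:00", "13:00"))
    light: LightGenParams = field(default_factory=LightGenParams)
    sleep: SleepGenParams = field(default_factory=SleepGenParams)
    dlmo_mean_s: int = field(default_factory=lambda: parse_clock("20:56"))
    dlmo_sd_s: float = 1800.0
    melatonin_noise_sd: float = 0.5
    frame_log_sd: float = 0.6  # spread of the planted frame's light scale

    def __post_init__(self) -> None:
        if not abs(self.planted_rho) <= 1.0:
            raise ValueError("|planted_rho| must be <= 1")


@dataclass
class Subject:
    participant_id: str
    light_times_s: np.ndarray
    light_values: np.ndarray
    hypnogram: Hypnogram
    melatonin: MelatoninSeries


def gen_cohort(p: CohortGenParams, seed=0) -> list[Subject]:
    """Paired light day + hypnogram + melatonin series per subject.

    The planted Spearman correlation links the chosen frame's median
    illuminance to REM latency via a Gaussian copula with latent
    correlation 2 sin(pi * planted_rho / 6); all other frame/outcome
    pairs carry no planted dependence.
    """
    rng = _rng(seed)
    r = 2.0 * np.sin(np.pi * p.planted_rho / 6.0)
    z1 = rng.standard_normal(p.n_subjects)
    eps = rng.standard_normal(p.n_subjects)
    z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * eps
    subjects = []
    for i in range(p.n_subjects):
        factor = float(np.exp(p.frame_log_sd * z1[i]))
        lt, lv = gen_light_day(p.light, rng,
                               planted_frame=(p.frame, factor))
        latency = float(np.clip(p.sleep.rem_latency_min
                                + p.sleep.rem_latency_sd * z2[i], 20.0, 140.0))
        sleep_p = replace(p.sleep, rem_latency_min=latency,
                          rem_latency_sd=0.0)
        h = gen_hypnogram(sleep_p, rng)
        dlmo = float(np.clip(rng.normal(p.dlmo_mean_s, p.dlmo_sd_s),
                             parse_clock("20:05"), parse_clock("22:40")))
        mel = gen_melatonin(dlmo, p.melatonin_noise_sd, rng,
                            participant_id=f"S{i + 1:02d}")
        subjects.append(Subject(f"S{i + 1:02d}", lt, lv, h, mel))
    return subjects
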