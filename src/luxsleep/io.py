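"""CSV readers/writers for the pipeline's input and output dialects.

All files are comma-separated UTF-8 with a mandatory header row and ``.``
decimal separator. Timestamps are naive local clock times (the emulated
protocol is a single-site winter study with no DST transition).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .clock import format_clock, parse_clock
from .dlmo import MelatoninSeries
from .sleep import Hypnogram

LIGHT_HEADER = ["participant_id", "timestamp", "illuminance_lx"]


def _seconds_of_timestamp(ts: str) -> int:
    # ISO-8601 "YYYY-MM-DDTHH:MM:SS" or a bare clock time
    clock = ts.split("T")[1] if "T" in ts else ts.split(" ")[-1]
    return parse_clock(clock)


def _date_of_timestamp(ts: str) -> str:
    return ts.split("T")[0].split(" ")[0] if ("T" in ts or " " in ts) else ""


def write_light_csv(path, participant_id: str, times_s, values,
                    date: str = "2008-11-17") -> None:
    ts = [f"{date}T{format_clock(t, with_seconds=True)}" for t in times_s]
    pd.DataFrame({
        "participant_id": participant_id,
        "timestamp": ts,
        "illuminance_lx": np.asarray(values, dtype=float),
    }).to_csv(path, index=False)


def read_light_csv(path):
    """Yield (participant_id, date, times_s, values) per participant-day."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(LIGHT_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"light CSV missing columns: {sorted(missing)}")
    df["_s"] = df["timestamp"].map(_seconds_of_timestamp)
    df["_d"] = df["timestamp"].map(_date_of_timestamp)
    out = []
    for (pid, date), g in df.groupby(["participant_id", "_d"], sort=True):
        out.append((pid, date, g["_s"].to_numpy(np.int64),
                    g["illuminance_lx"].to_numpy(float)))
    return out


def write_hypnogram(path, h: Hypnogram, fmt: str = "compact") -> None:
    if fmt == "compact":
        lines = [f"start={format_clock(h.start_s)} epoch={h.epoch_s}"]
        lines += list(h.stages)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    elif fmt == "csv":
        ts = [format_clock(h.epoch_clock(i), with_seconds=True)
              for i in range(h.n)]
        pd.DataFrame({"timestamp": ts, "stage": h.stages}).to_csv(
            path, index=False)
    else:
        raise ValueError("fmt must be 'compact' or 'csv'")


def read_hypnogram(path) -> Hypnogram:
    """Read either the compact text format or the timestamp,stage CSV."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if first.startswith("start="):
        head = dict(part.split("=") for part in first.split())
        with open(path, encoding="utf-8") as fh:
            stages = [ln.strip() for ln in fh.readlines()[1:] if ln.strip()]
        return Hypnogram(parse_clock(head["start"]), np.array(stages),
                         int(head.get("epoch", 30)))
    df = pd.read_csv(path)
    start = _seconds_of_timestamp(str(df["timestamp"].iloc[0]))
    epoch = 30
    if len(df) > 1:
        second = _seconds_of_timestamp(str(df["timestamp"].iloc[1]))
        epoch = int((second - start) % 86400)
    return Hypnogram(start, df["stage"].to_numpy(dtype="<U2"), epoch)


def write_melatonin_csv(path, series_list) -> None:
    rows = []
    for s in series_list:
        for t, c in zip(s.times_s, s.conc):
            rows.append({"participant_id": s.participant_id,
                         "clock_time": format_clock(t),
                         "concentration_pg_ml": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_melatonin_csv(path) -> list[MelatoninSeries]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    out = []
    for pid, g in df.groupby("participant_id", sort=True):
        times = g["clock_time"].map(parse_clock).to_numpy(float)
        out.append(MelatoninSeries(times,
                                   g["concentration_pg_ml"].to_numpy(float),
                                   pid))
    return out


def sleep_metrics_frame(metrics_by_id: dict) -> pd.DataFrame:
    """One row per recording, mirroring the usual PSG descriptive table."""
    rows = []
    for pid, m in metrics_by_id.items():
        rows.append({
            "participant_id": pid,
            "sleep_onset": format_clock(m.onset_clock_s),
            "sleep_offset": format_clock(m.offset_clock_s),
            "midpoint": format_clock(m.midpoint_clock_s),
            "sleep_latency_min": m.sleep_latency_min,
            "spt_min": m.spt_min,
            "tst_min": m.tst_min,
            "efficiency_percent": m.efficiency_percent,
            "rems_latency_min": m.rems_latency_min,
            "n1_min": m.stage_minutes["N1"],
            "n2_min": m.stage_minutes["N2"],
            "sws_min": m.stage_minutes["N3"],
            "rems_min": m.stage_minutes["R"],
            "n1_pct_spt": m.stage_percent_spt["N1"],
            "n2_pct_spt": m.stage_percent_spt["N2"],
            "sws_pct_spt": m.stage_percent_spt["N3"],
            "rems_pct_spt": m.stage_percent_spt["R"],
            "wake_within_min": m.wake_within_min,
        })
    return pd.DataFrame(rows).set_index("participant_id")


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return path
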