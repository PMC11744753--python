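"""End-to-end orchestration: clean -> summarize -> sleep -> polarity ->
DLMO -> associations, with reproducible CSV outputs and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__, association, dlmo as dlmo_mod, io as io_mod, light
from .clock import format_clock, parse_clock
from .config import RunConfig
from .polarity import polarity_report
from .sleep import SleepOnsetError, compute_metrics

log = logging.getLogger("luxsleep")

LOW_VALID_WARN_PERCENT = 50.0


def subject_outcomes(h, lights_off_s: int) -> dict:
    """The eight sleep outcomes entering the association grid."""
    m = compute_metrics(h, lights_off_s)
    rep = polarity_report(h)
    return {
        "n2_min": m.stage_minutes["N2"],
        "sws_min": m.stage_minutes["N3"],
        "sws_polarity_time_h": rep.sws_time_rel_onset_h,
        "sws_polarity_strength": rep.sws.strength,
        "rems_min": m.stage_minutes["R"],
        "rems_latency_min": m.rems_latency_min,
        "rem_polarity_time_h": rep.rem_time_rel_onset_h,
        "rem_polarity_strength": rep.rem.strength,
    }


def run_all(subjects, config: RunConfig | None = None,
            out_dir: str | None = None) -> dict:
    """Run the full analysis over paired per-subject inputs.

    ``subjects`` is an iterable with attributes ``participant_id``,
    ``light_times_s``, ``light_values``, ``hypnogram`` and ``melatonin``
    (e.g. :class:`luxsleep.simulate.Subject`). Subjects whose hypnogram
    has no sleep onset or whose melatonin shows no rise are flagged and
    skipped for the affected outputs rather than aborting the run.
    Writes CSVs plus ``manifest.json`` when ``out_dir`` is given.
    """
    config = config or RunConfig()
    window = light.TimeWindow(parse_clock(config.analysis_window_start),
                              parse_clock(config.analysis_window_end))
    lights_off_s = parse_clock(config.lights_off)
    recordings, medians, metrics, outcomes, dlmo_rows = [], {}, {}, {}, []
    for sub in subjects:
        pid = sub.participant_id
        rec = light.clean_samples(sub.light_times_s, sub.light_values,
                                  pid, analysis_window=window)
        vp = light.valid_percent(rec)
        if vp < LOW_VALID_WARN_PERCENT:
            log.warning("participant %s: only %.1f%% valid light data",
                        pid, vp)
        recordings.append(rec)
        medians[pid] = light.frame_medians(rec)
        try:
            metrics[pid] = compute_metrics(sub.hypnogram, lights_off_s)
            outcomes[pid] = subject_outcomes(sub.hypnogram, lights_off_s)
        except SleepOnsetError as exc:
            log.warning("participant %s: %s; excluded from sleep outputs",
                        pid, exc)
        row = {"participant_id": pid, "dlmo": "", "breakpoint": "",
               "baseline_pg_ml": np.nan, "slope_pg_ml_h": np.nan,
               "rss": np.nan, "flags": ""}
        try:
            fit = dlmo_mod.fit_hockey_stick(
                sub.melatonin, threshold=config.dlmo_threshold_pg_ml)
            row.update(
                dlmo=format_clock(fit.dlmo_s) if fit.dlmo_s is not None else "",
                breakpoint=format_clock(fit.breakpoint_s),
                baseline_pg_ml=fit.baseline_pg_ml,
                slope_pg_ml_h=fit.rise_slope_pg_ml_h, rss=fit.rss,
                flags=";".join(fit.flags))
        except (dlmo_mod.NoMelatoninRiseError, ValueError) as exc:
            row["flags"] = str(exc)
            log.warning("participant %s: DLMO fit failed: %s", pid, exc)
        dlmo_rows.append(row)

    summary = light.cohort_table(recordings,
                                 thresholds=config.thresholds_lx)
    sleep_df = io_mod.sleep_metrics_frame(metrics)
    medians_df = pd.DataFrame(medians).T.rename_axis("participant_id")
    outcomes_df = pd.DataFrame(outcomes).T.rename_axis("participant_id")
    table = association.build_table(
        medians_df, outcomes_df, sided=config.sided,
        exact_max_n=config.exact_max_n, holm_scope=config.holm_scope,
        alpha=config.alpha)
    dlmo_df = pd.DataFrame(dlmo_rows).set_index("participant_id")

    result = {"light_summary": summary, "sleep_metrics": sleep_df,
              "light_frame_medians": medians_df, "outcomes": outcomes_df,
              "associations": table, "dlmo": dlmo_df}
    if out_dir is not None:
        io_mod.ensure_dir(out_dir)
        for name in ("light_summary", "sleep_metrics", "light_frame_medians",
                     "associations", "dlmo"):
            df = result[name]
            df.to_csv(os.path.join(out_dir, f"{name}.csv"),
                      index=name != "associations")
        cfg = config.to_dict()
        manifest = {
            "package": "luxsleep",
            "version": __version__,
            "seed": config.seed,
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
            "n_subjects": len(recordings),
        }
        with open(os.path.join(out_dir, "manifest.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
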