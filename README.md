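# luxsleep

Analysis pipeline for studying how habitual daytime light exposure,
measured continuously at eye level by wearable 1-Hz lux sensors, relates
to the architecture of the following night's sleep. It is written for
chronobiology and sleep researchers who have three input streams per
participant — a daytime illuminance log (07:00–19:00), an overnight
hypnogram (30-s epochs, W/N1/N2/N3/R), and an evening salivary melatonin
series — and want the full chain from raw logs to a corrected association
table, plus a calibrated synthetic-data generator to exercise it.

## What it computes

* **Light dosimetry** — status-flagged cleaning of 1-Hz lux logs
  (artifacts, clipping to the 1–40,000 lx reliable range, gaps), then
  per-window medians, means, 10th/90th percentiles, percent of time below
  20/80/200/500 lx, valid-data percentage and the time of maximal
  exposure on 20-min bins, aggregated individual-first across a cohort.
* **Sleep metrics** — sleep onset ("first 2 min of N2 without wake"),
  sleep period time (SPT), total sleep time, efficiency, latencies, and
  stage minutes / percent-of-SPT.
* **Polarity** — a circular statistic: every 30-s epoch of a stage is a
  unit vector at its clock-time angle on the 24-h circle (1 h = 15°); the
  resultant's angle is the stage's centroid time and its length the
  polarity strength. A lux-weighted analogue describes the daytime light
  profile.
* **DLMO** — dim-light melatonin onset from a two-piece "hockey-stick"
  least-squares fit (flat baseline, linear rise, breakpoint on a 1-min
  grid), crossing the 10 pg/mL threshold on the fitted curve.
* **Association inference** — Spearman's rho between frame-wise median
  illuminance (six 2-h frames plus the full day) and eight sleep
  outcomes, with *exact* permutation p-values (full n! enumeration for
  n ≤ 10, tie-free) and Bonferroni-Holm correction over the seven frames
  per outcome.
* **Synthetic data** — generators for light days, hypnograms, melatonin
  series and paired cohorts, including a Gaussian-copula construction
  that plants a chosen rank correlation between midday light and REM
  latency.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

Generate a nine-subject cohort with a strong planted link between midday
(11:00–13:00) median illuminance and REM latency, then run the whole
pipeline:

```python
from luxsleep import RunConfig, simulate
from luxsleep.pipeline import run_all

subjects = simulate.gen_cohort(
    simulate.CohortGenParams(planted_rho=0.8), seed=1)
res = run_all(subjects, RunConfig(), out_dir="results")

tab = res["associations"]
print(tab[(tab.frame == "11:00-13:00")
          & (tab.outcome == "rems_latency_min")].to_string(index=False))
```

```
      frame          outcome  n  rho    p_raw method flags    p_adj  significant
11:00-13:00 rems_latency_min  9  0.9 0.001014  exact       0.007099         True
```

The planted cell is recovered with a sample Spearman coefficient of 0.9
(n = 9 is small, so the estimate scatters around the planted 0.8). Its
raw p-value, 0.001014, is an exact count over all 362,880 rank
permutations — 368 of them reach rho ≥ 0.9 — and Holm's step-down
correction over the seven time frames multiplies it by 7 to 0.0071,
comfortably significant at the 0.05 level. The same run writes
`light_summary.csv` (dosimetry per window), `sleep_metrics.csv`,
`light_frame_medians.csv`, `dlmo.csv`, `associations.csv` (all 56 cells)
and a `manifest.json` recording config, seed and package version;
rerunning with the same seed reproduces every file byte for byte.

The same flow is available from the shell:

```sh
luxsleep simulate --what cohort --seed 1 --planted-rho 0.8 --out data/
luxsleep run-all --light data/ --hypnograms data/ \
         --melatonin data/melatonin.csv --out results/
```

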