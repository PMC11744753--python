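"""Run configuration with the study's protocol constants as defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class RunConfig:
    analysis_window_start: str = "07:00"
    analysis_window_end: str = "19:00"
    thresholds_lx: tuple = (20.0, 80.0, 200.0, 500.0)
    epoch_s: int = 30
    lights_off: str = "23:00"
    dlmo_threshold_pg_ml: float = 10.0
    sided: str = "one"
    exact_max_n: int = 10
    holm_scope: str = "column"  # seven frames per outcome column
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra = extra
        if "thresholds_lx" in kwargs:
            cfg.thresholds_lx = tuple(float(t) for t in cfg.thresholds_lx)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds_lx"] = list(self.thresholds_lx)
        return d
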