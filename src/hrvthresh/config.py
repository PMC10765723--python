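"""Run configuration with the method's published default constants."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All numeric knobs of the pipeline, defaulting to the standard values.

    Preprocessing: interval range 200-2000 ms, median kernel 7 beats,
    deviation fraction 0.10.  DDFA: 20 log-spaced integer scales on 5-64
    beats, segment factor 5, hop 1.  Threshold rule: 25 baseline bins,
    10-bin smoothing kernel, 10-bin stability run, second level -0.5.
    alpha1 method: 120-s window every 5 s, smoothness priors lambda = 500,
    regression band [0.5, 0.75], gap bridging n = 4.  HRmax percentages
    0.70 / 0.85.  Statistics: 10^4 resamples.
    """

    # preprocessing
    lo: float = 200.0
    hi: float = 2000.0
    kernel: int = 7
    frac: float = 0.10
    manual_exclude: list = field(default_factory=list)
    # DDFA
    scale_min: int = 5
    scale_max: int = 64
    n_scales: int = 20
    segment_factor: int = 5
    hop: int = 1
    centered: bool = True
    # DDFA thresholds
    baseline_bins: int = 25
    smooth_kernel: int = 10
    run: int = 10
    level2: float = -0.5
    # alpha1 method
    a1_window: float = 120.0
    a1_step: float = 5.0
    lam: float = 500.0
    order: int = 1
    band: tuple = (0.5, 0.75)
    gap_n: int = 4
    # HRmax method
    p1: float = 0.70
    p2: float = 0.85
    # statistics
    n_perm: int = 10_000
    n_boot: int = 10_000
    n_mc: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.merged(**data)

    @classmethod
    def merged(cls, **overrides) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "band" in overrides:
            overrides["band"] = tuple(overrides["band"])
        return cls(**overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(d["band"])
        return d
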