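"""Bundled reference data."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_study_thresholds"]


def load_study_thresholds() -> pd.DataFrame:
    """Per-subject threshold estimates (BPM) from a 15-subject incremental
    cyclo-ergometer study.

    Columns: ``subject`` plus ``{method}{k}`` for methods LT (lactate,
    the benchmark), VT (ventilatory), HRmaxT, DFAa1T and DDFAT, k in
    {1, 2}.  This is the regression surface for the agreement statistics;
    the underlying recordings are not distributable, so only the published
    per-subject thresholds are shipped.
    """
    with resources.files("hrvthresh.data").joinpath("study_thresholds.csv").open() as f:
        return pd.read_csv(f)
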