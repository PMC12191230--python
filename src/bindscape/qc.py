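"""Cross-cutting QC and assay statistics: IQR outlier masks, Y2H scoring."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["iqr_filter", "y2h_normalize"]

Y2H_CATEGORIES = ("normal", "perturbed", "absent")


def iqr_filter(values: Sequence[float], k: float = 1.5) -> np.ndarray:
    """Boolean keep-mask: values within [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation. With fewer than 4 values everything
    is kept (with a warning): quartiles are not meaningful.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        warnings.warn("fewer than 4 values; IQR filter keeps everything")
        return np.ones(len(v), dtype=bool)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - k * iqr) & (v <= q3 + k * iqr)


def y2h_normalize(
    records: pd.DataFrame,
    wt_bait: str = "WT",
    normal_min: float = 0.75,
    absent_max: float = 0.25,
) -> pd.DataFrame:
    """Score bait-prey interactions against the wild-type bait.

    Each record's growth ratio f_t2/f_t1 is divided by the mean ratio of the
    wild-type bait with the same prey; the score is categorized as normal
    (>= normal_min), perturbed, or absent (< absent_max). Records with
    f_t1 = 0 are flagged invalid (NaN score, empty category).
    """
    df = records.copy()
    required = {"bait", "prey", "f_t1", "f_t2"}
    if not required.issubset(df.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    valid = df["f_t1"] > 0
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} record(s) with f_t1 = 0 flagged invalid")
    df["ratio"] = np.where(valid, df["f_t2"] / df["f_t1"].where(valid), np.nan)
    wt = df[(df["bait"] == wt_bait) & valid]
    if wt.empty:
        raise ValueError(f"no valid records for reference bait {wt_bait!r}")
    ref = wt.groupby("prey")["ratio"].mean()
    missing = set(df["prey"]) - set(ref.index)
    if missing:
        raise ValueError(f"no WT reference for prey(s): {sorted(missing)}")
    df["score"] = df["ratio"] / df["prey"].map(ref)
    df["valid"] = valid

    def categorize(s: float) -> str:
        if not np.isfinite(s):
            return ""
        if s >= normal_min:
            return "normal"
        if s < absent_max:
            return "absent"
        return "perturbed"

    df["category"] = df["score"].map(categorize)
    return df
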