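"""Growth-rate estimation from race-tube position series.

The rate of one assay is the ordinary least-squares slope of front position
(mm) on time (hr), using marks from the first clearly-visible one onward so
that differences in inoculum size do not bias the slope.  Tubes that never
grew get a rate of zero; tubes with fewer than two usable marks are flagged
invalid and excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import RaceTubeSeries, ValidationError

__all__ = ["GrowthRateRecord", "estimate_growth_rate", "estimate_table", "qc_summary"]

log = logging.getLogger(__name__)


@dataclass
class GrowthRateRecord:
    assay_id: str
    rate: float          # mm/hr, >= 0
    intercept: float     # mm (NaN for zero-growth tubes)
    r_squared: float     # in [0, 1]; NaN when undefined
    n_marks_used: int
    zero_growth: bool
    valid: bool = True


def estimate_growth_rate(series: RaceTubeSeries) -> GrowthRateRecord:
    """OLS slope of position on time from ``first_visible_index`` onward."""
    pos = series.positions
    times = series.mark_times
    if np.all(pos == 0.0):
        return GrowthRateRecord(series.assay_id, 0.0, np.nan, np.nan, 0, True)
    start = series.first_visible_index
    if start < 0:
        # grew a little but never crossed the visibility threshold
        log.warning("assay %s: no visible front; flagged invalid", series.assay_id)
        return GrowthRateRecord(series.assay_id, 0.0, np.nan, np.nan, 0, False, valid=False)
    t, y = times[start:], pos[start:]
    if t.size < 2:
        log.warning("assay %s: <2 usable marks; flagged invalid", series.assay_id)
        return GrowthRateRecord(series.assay_id, 0.0, np.nan, np.nan, int(t.size), False, valid=False)
    res = stats.linregress(t, y)
    return GrowthRateRecord(
        assay_id=series.assay_id,
        rate=max(0.0, float(res.slope)),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_marks_used=int(t.size),
        zero_growth=False,
    )


def estimate_table(series_list: list[RaceTubeSeries], design: pd.DataFrame) -> pd.DataFrame:
    """Join per-assay estimates onto a design table.

    ``design`` needs an ``assay_id`` column; design cells without a matching
    series are flagged missing rather than fabricated.
    """
    if "assay_id" not in design.columns:
        raise ValidationError("design table must carry an assay_id column")
    records = {s.assay_id: estimate_growth_rate(s) for s in series_list}
    out = design.copy()
    cols = {"rate_mm_per_hr": [], "r_squared": [], "zero_growth": [], "missing_flag": [], "valid": []}
    for aid in out["assay_id"]:
        rec = records.get(aid)
        if rec is None or not rec.valid:
            cols["rate_mm_per_hr"].append(np.nan)
            cols["r_squared"].append(np.nan)
            cols["zero_growth"].append(False)
            cols["missing_flag"].append(1)
            cols["valid"].append(rec is not None)
        else:
            cols["rate_mm_per_hr"].append(rec.rate)
            cols["r_squared"].append(rec.r_squared)
            cols["zero_growth"].append(rec.zero_growth)
            cols["missing_flag"].append(0)
            cols["valid"].append(True)
    for k, v in cols.items():
        out[k] = v
    return out


def qc_summary(table: pd.DataFrame) -> dict:
    """Fit-quality summary: R-squared quantiles plus zero-growth/missing counts.

    Quantiles (2.5%, 50%, 97.5%) use linear interpolation between order
    statistics and cover only records with a defined R-squared.
    """
    if len(table) == 0:
        raise ValidationError("empty growth-rate table")
    r2 = table["r_squared"].dropna().to_numpy() if "r_squared" in table.columns else np.array([])
    quantiles = (
        tuple(np.quantile(r2, [0.025, 0.5, 0.975]).tolist()) if r2.size else None
    )
    n_zero = int(table["zero_growth"].sum()) if "zero_growth" in table.columns else int(
        ((table["rate_mm_per_hr"] == 0) & (table.get("missing_flag", 0) == 0)).sum()
    )
    n_missing = int(table["missing_flag"].sum()) if "missing_flag" in table.columns else int(
        table["rate_mm_per_hr"].isna().sum()
    )
    return {"r2_quantiles": quantiles, "n_zero_growth": n_zero, "n_missing": n_missing}
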