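"""Time-to-onset (induction time) analysis.

Induction time is the whole-day difference between the start of therapy
with the target drug and the event onset date, ``event_dt −
therapy_start_dt`` with no +1, so a same-day onset is 0 days and lands in
the first "0–30" bin. Records are per (report, PT): a report listing
three reactions contributes three records with equal days, because the
per-SOC summaries count events, not reports.

Candidates are excluded — never fatal — when either date is missing,
when both dates were month-imputed (the interval would be an artifact of
the day-15 convention), or when the difference is negative; exclusions
are tallied by reason.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from faers_signals.cohort_builder import SocMap

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (0, 30, 60, 90, 180, 360)

#: quantile conventions: numpy's default linear interpolation ("type 7"),
#: or the weighted-average convention of common commercial packages ("type 6")
QUANTILE_METHODS = {"linear": "linear", "spss": "weibull"}


def compute_onset(
    cohort: pd.DataFrame, soc_map: SocMap | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-(report, PT) induction-time records plus exclusion tallies.

    Returns a frame (primaryid, pt, soc, days) and a dict counting why
    candidate reports were excluded: ``missing_event_date``,
    ``missing_start_date``, ``both_dates_imputed``, ``negative_interval``.
    """
    excluded = {"missing_event_date": 0, "missing_start_date": 0,
                "both_dates_imputed": 0, "negative_interval": 0}
    rows = []
    for rep in cohort.itertuples():
        if pd.isna(rep.event_dt):
            excluded["missing_event_date"] += 1
            continue
        if pd.isna(rep.therapy_start_dt):
            excluded["missing_start_date"] += 1
            continue
        if bool(rep.event_dt_imputed) and bool(rep.therapy_start_imputed):
            excluded["both_dates_imputed"] += 1
            continue
        days = (rep.event_dt - rep.therapy_start_dt).days
        if days < 0:
            excluded["negative_interval"] += 1
            continue
        for pt in sorted(rep.pts):
            rows.append({
                "primaryid": rep.primaryid,
                "pt": pt,
                "soc": soc_map.lookup(pt) if soc_map else SocMap.FALLBACK,
                "days": int(days),
            })
    records = pd.DataFrame(rows, columns=["primaryid", "pt", "soc", "days"])
    return records, excluded


def bin_onset(
    records: pd.DataFrame, edges: Iterable[int] = DEFAULT_BIN_EDGES
) -> pd.Series:
    """Histogram of onset days over inclusive integer-day bins.

    Edges (0, 30, 60, ...) yield bins "0-30", "31-60", ... plus a final
    ">last". Counts sum to the number of records.
    """
    edges = list(edges)
    if records.empty:
        logger.warning("no onset records to bin")
        return pd.Series(dtype=int)
    labels = [f"{edges[0]}-{edges[1]}"] + [
        f"{lo + 1}-{hi}" for lo, hi in zip(edges[1:], edges[2:])
    ]
    labels.append(f">{edges[-1]}")
    bins = [edges[0] - 1] + edges[1:] + [np.inf]
    cat = pd.cut(records["days"], bins=bins, labels=labels, right=True)
    return cat.value_counts().reindex(labels).fillna(0).astype(int)


def summarize_by_soc(
    records: pd.DataFrame, method: str = "linear"
) -> pd.DataFrame:
    """Per-SOC n, median, Q1, Q3 of induction days.

    ``method`` selects the quantile convention ("linear" default, "spss"
    for the weighted-average rule). SOCs with fewer than 3 records are
    flagged ``low_n``.
    """
    if method not in QUANTILE_METHODS:
        raise ValueError(f"unknown quantile method {method!r}")
    interp = QUANTILE_METHODS[method]
    rows = []
    for soc, grp in records.groupby("soc", sort=True):
        days = grp["days"].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(days, [0.25, 0.5, 0.75], method=interp)
        rows.append({"soc": soc, "n": len(days), "median_days": med,
                     "q1_days": q1, "q3_days": q3, "low_n": len(days) < 3})
    return pd.DataFrame(rows, columns=["soc", "n", "median_days", "q1_days",
                                       "q3_days", "low_n"])


def cumulative_timeline(records: pd.DataFrame) -> pd.DataFrame:
    """Per-SOC empirical CDF of onset days (ties collapsed to one step).

    Returns (soc, days, cum_frac) with cum_frac reaching 1.0 at each
    SOC's last event; SOCs with no records are simply absent.
    """
    rows = []
    for soc, grp in records.groupby("soc", sort=True):
        days = np.sort(grp["days"].to_numpy())
        n = len(days)
        uniq, counts = np.unique(days, return_counts=True)
        cum = np.cumsum(counts) / n
        for d, f in zip(uniq, cum):
            rows.append({"soc": soc, "days": int(d), "cum_frac": float(f)})
    return pd.DataFrame(rows, columns=["soc", "days", "cum_frac"])
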