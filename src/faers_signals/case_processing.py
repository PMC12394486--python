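"""Case-level deduplication of spontaneous reports.

FAERS distributes one row per report *version*: a case (CASEID) that is
updated or re-submitted appears several times under different PRIMARYIDs,
possibly across quarters. The FDA rule collapses each case to its most
recent version: sort by CASEID, FDA receipt date (FDA_DT), PRIMARYID, and
keep the row with the largest FDA_DT; on an FDA_DT tie, the largest
PRIMARYID wins. Cases on the cumulative deleted-report lists (distributed
since 2019Q1) are then removed entirely.

Deduplication is applied to the concatenation of all loaded quarters, not
per quarter, so a case updated across quarters still collapses to its
latest version. A missing FDA_DT sorts before any real date, so a dated
version always beats an undated one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DedupReason(str, Enum):
    MAX_FDA_DT = "max_fda_dt"
    MAX_PRIMARYID_TIE = "max_primaryid_tie"
    DELETED = "deleted"


@dataclass(frozen=True)
class DedupDecision:
    """Audit record for one case that lost at least one report version."""

    caseid: int
    retained_primaryid: int | None
    discarded_primaryids: tuple[int, ...]
    reason: DedupReason


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, list[DedupDecision]]:
    """Collapse multi-version cases to one row per CASEID.

    Returns the retained rows (sorted by ascending caseid) and a decision
    log with one entry per case that had discarded versions. Duplicate
    PRIMARYIDs in the input indicate a corrupt extract and are fatal.
    """
    if demo["primaryid"].duplicated().any():
        dup = demo.loc[demo["primaryid"].duplicated(), "primaryid"].iloc[0]
        raise ValueError(f"duplicate PRIMARYID in input: {dup} (corrupt extract)")

    # NaT sorts first under ascending sort, so an undated version never
    # beats a dated one; keep='last' then applies the max-FDA_DT /
    # max-PRIMARYID rule in one pass.
    ordered = demo.sort_values(
        ["caseid", "fda_dt", "primaryid"],
        ascending=True,
        na_position="first",
        kind="mergesort",
    )
    retained = ordered.drop_duplicates("caseid", keep="last")

    decisions: list[DedupDecision] = []
    loser_mask = ordered["caseid"].duplicated(keep="last")
    if loser_mask.any():
        winners = ordered[~ordered["caseid"].duplicated(keep="last")].set_index("caseid")
        losers = ordered[loser_mask]
        l_case = losers["caseid"].to_numpy()
        l_pid = losers["primaryid"].to_numpy()
        l_fda = losers["fda_dt"].to_numpy()
        w_fda = winners["fda_dt"].loc[l_case].to_numpy()
        tie = (l_fda == w_fda) | (pd.isna(l_fda) & pd.isna(w_fda))
        w_pid = winners["primaryid"]
        start = 0
        for end in np.flatnonzero(np.r_[l_case[1:] != l_case[:-1], True]) + 1:
            caseid = int(l_case[start])
            decisions.append(DedupDecision(
                caseid=caseid,
                retained_primaryid=int(w_pid.loc[caseid]),
                discarded_primaryids=tuple(int(p) for p in l_pid[start:end]),
                reason=(DedupReason.MAX_PRIMARYID_TIE if tie[start:end].any()
                        else DedupReason.MAX_FDA_DT),
            ))
            start = end
    return retained.sort_values("caseid").reset_index(drop=True), decisions


def remove_deleted(
    demo: pd.DataFrame, deleted_case_ids: set[int]
) -> tuple[pd.DataFrame, list[DedupDecision]]:
    """Drop retained rows whose CASEID is on the deleted-report list.

    Applied after :func:`deduplicate`, matching the published cleaning
    order. Deleted ids absent from the corpus are ignored (debug-logged).
    """
    if not deleted_case_ids:
        return demo.reset_index(drop=True), []
    mask = demo["caseid"].isin(deleted_case_ids)
    removed = demo[mask]
    decisions = [
        DedupDecision(caseid=int(r.caseid), retained_primaryid=None,
                      discarded_primaryids=(int(r.primaryid),),
                      reason=DedupReason.DELETED)
        for r in removed.itertuples()
    ]
    unseen = deleted_case_ids - set(demo["caseid"].dropna().astype(int))
    if unseen:
        logger.debug("%d deleted-list caseid(s) not present in corpus", len(unseen))
    return demo[~mask].reset_index(drop=True), decisions


def filter_satellites(
    corpus: dict[str, object], retained_demo: pd.DataFrame
) -> dict[str, object]:
    """Restrict satellite tables to PRIMARYIDs surviving deduplication."""
    keep = set(retained_demo["primaryid"].astype(int))
    out = dict(corpus)
    out["demo"] = retained_demo
    for name in ("drug", "reac", "indi", "outc", "ther"):
        df = corpus[name]
        out[name] = df[df["primaryid"].isin(keep)].reset_index(drop=True)
    return out


def decisions_to_frame(decisions: list[DedupDecision]) -> pd.DataFrame:
    """Audit log as a flat table (caseid, retained, discarded, reason)."""
    return pd.DataFrame(
        [
            {
                "caseid": d.caseid,
                "retained_primaryid": d.retained_primaryid,
                "discarded_primaryids": ";".join(map(str, d.discarded_primaryids)),
                "reason": d.reason.value,
            }
            for d in decisions
        ],
        columns=["caseid", "retained_primaryid", "discarded_primaryids", "reason"],
    )
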