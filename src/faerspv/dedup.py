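"""Case-level deduplication of DEMO records.

Rule: per CASEID keep the record with the latest FDA_DT; among ties on
(CASEID, FDA_DT) keep the highest PRIMARYID.  PRIMARYIDs are compared
numerically when every contender parses as an integer, lexicographically
otherwise.  Records whose FDA_DT has no parseable year go to an
"undated" bin and survive only when their CASEID has no dated record.
Only exact CASEID matches are merged; no fuzzy matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

from .faers_io import parse_partial_date

__all__ = ["DedupDecision", "deduplicate", "write_decision_log"]


@dataclass(frozen=True)
class DedupDecision:
    """Audit entry for one CASEID with more than one report version."""

    caseid: str
    kept_primaryid: str
    dropped_primaryids: tuple[str, ...]
    undated_fallback: bool = False

    def __post_init__(self) -> None:
        if self.kept_primaryid in self.dropped_primaryids:
            raise ValueError("kept primaryid cannot also be dropped")


@dataclass
class DedupResult:
    kept_primaryids: list[str]
    decisions: list[DedupDecision] = field(default_factory=list)
    n_undated_kept: int = 0


def _primaryid_sort_values(ids: pd.Series) -> pd.Series:
    as_num = pd.to_numeric(ids, errors="coerce")
    if as_num.notna().all():
        return as_num
    return ids.astype(str)


def deduplicate(demo: pd.DataFrame) -> DedupResult:
    """Reduce a DEMO table to one report per CASEID.

    Returns the kept PRIMARYIDs in deterministic (ascending CASEID)
    order, plus a decision log covering every CASEID where something was
    dropped.  Idempotent: running on an already-unique table keeps every
    record and logs nothing.
    """
    required = {"primaryid", "caseid", "fda_dt"}
    missing = required - set(demo.columns)
    if missing:
        raise KeyError(f"DEMO table lacks column(s) {sorted(missing)}")
    if demo.empty:
        return DedupResult(kept_primaryids=[])

    work = demo.loc[:, ["primaryid", "caseid", "fda_dt"]].copy()
    work["primaryid"] = work["primaryid"].astype(str)
    work["caseid"] = work["caseid"].astype(str)
    parsed = work["fda_dt"].map(parse_partial_date)
    work["_dated"] = parsed.notna()
    work["_datekey"] = [p.sort_key() if p is not None else (0, 0, 0) for p in parsed]

    kept: list[str] = []
    decisions: list[DedupDecision] = []
    n_undated_kept = 0
    for caseid, group in work.groupby("caseid", sort=True):
        dated = group[group["_dated"]]
        pool = dated if not dated.empty else group
        fallback = dated.empty
        if len(group) == 1:
            kept.append(group["primaryid"].iloc[0])
            if fallback:
                n_undated_kept += 1
            continue
        best_date = max(pool["_datekey"])
        contenders = pool[pool["_datekey"] == best_date]
        order = _primaryid_sort_values(contenders["primaryid"])
        winner = contenders["primaryid"].iloc[int(order.reset_index(drop=True).idxmax())]
        dropped = tuple(p for p in group["primaryid"] if p != winner)
        kept.append(winner)
        if fallback:
            n_undated_kept += 1
        decisions.append(
            DedupDecision(
                caseid=str(caseid),
                kept_primaryid=winner,
                dropped_primaryids=dropped,
                undated_fallback=fallback,
            )
        )
    return DedupResult(kept_primaryids=kept, decisions=decisions, n_undated_kept=n_undated_kept)


def write_decision_log(result: DedupResult, path: Union[str, Path]) -> None:
    """Write the decision log as a "$"-delimited audit file."""
    rows = [
        {
            "caseid": d.caseid,
            "kept_primaryid": d.kept_primaryid,
            "dropped_primaryids": ";".join(d.dropped_primaryids),
            "undated_fallback": str(d.undated_fallback).lower(),
        }
        for d in result.decisions
    ]
    pd.DataFrame(rows, columns=["caseid", "kept_primaryid", "dropped_primaryids", "undated_fallback"]).to_csv(
        path, sep="$", index=False
    )
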