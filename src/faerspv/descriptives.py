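"""Time-to-onset computation and demographic/outcome summary tables.

Onset is the calendar-day difference between the event start date and
the earliest fully dated start of an index drug; reports with partial or
missing dates, or with the event before therapy start, are excluded with
a single recorded reason (first failing rule wins).  Quantiles use the
linear-interpolation convention between order statistics (numpy's
default, the common "type 7" rule); the convention is echoed in output
metadata.

Cohort summaries mirror the usual characteristics table of a
spontaneous-reporting analysis: per-subgroup and overall counts with
percentages of subgroup size (one decimal) for gender, reporting-year
bins, indication categories, outcome codes, reporter countries and
reporter occupations.  Outcome rows are non-exclusive (a report may be
both DE and HO); all other characteristics are single-valued so their
category counts, including Unknown/Unspecified, sum to the subgroup
size.  Age is carried but only its missingness is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CaseReport, DrugLexicon, RegimenClass
from .faers_io import parse_partial_date

QUANTILE_RULE = "linear interpolation (type 7)"

EXCLUSION_REASONS = (
    "partial_or_missing_event_date",
    "partial_or_missing_start_date",
    "event_before_start",
)

#: default day-range bins for the onset percentage table
DEFAULT_ONSET_BINS: tuple[int, ...] = (30, 60, 90, 180, 360)

OUTCOME_LABELS = {
    "DE": "Death (DE)",
    "LT": "Life-threatening (LT)",
    "HO": "Hospitalization (HO)",
    "DS": "Disability (DS)",
    "CA": "Congenital anomaly (CA)",
    "RI": "Required intervention (RI)",
    "OT": "Other serious (OT)",
}

REPORTER_LABELS = {
    "MD": "Physician (MD)",
    "PH": "Pharmacist (PH)",
    "CN": "Consumer (CN)",
    "HP": "Health professional (HP)",
    "OT": "Other health professional (OT)",
}

YEAR_BIN_LABELS = ("2019-2023", "2014-2018", "2009-2013", "2008 and before")

SUBGROUP_ORDER = (
    RegimenClass.MONO,
    RegimenClass.PLUS_CHEMO,
    RegimenClass.PLUS_ICI,
    RegimenClass.PLUS_TARGETED,
)


@dataclass(frozen=True)
class OnsetRecord:
    """Days from index-therapy start to event, or why a report was excluded."""

    primaryid: str
    regimen: Optional[RegimenClass]
    onset_days: Optional[int] = None
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.onset_days is None) == (self.exclusion_reason is None):
            raise ValueError("exactly one of onset_days / exclusion_reason must be set")
        if self.onset_days is not None and self.onset_days < 0:
            raise ValueError("onset_days must be nonnegative")
        if self.exclusion_reason is not None and self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")

    @property
    def usable(self) -> bool:
        return self.onset_days is not None


@dataclass(frozen=True)
class OnsetSummary:
    n_used: int
    median_days: float
    q1_days: float
    q3_days: float
    cumulative_curve: tuple[tuple[float, float], ...]
    quantile_rule: str = QUANTILE_RULE

    @property
    def empty(self) -> bool:
        return self.n_used == 0


def compute_onset(report: CaseReport, lexicon: DrugLexicon) -> OnsetRecord:
    """Derive one onset record for a target-event cohort report.

    Uses the earliest index-drug therapy start carrying a full date; both
    the event date and that start date must resolve to a calendar day.
    Same-day start and event yields zero days.
    """
    event = parse_partial_date(report.event_dt)
    if event is None or not event.is_full:
        return OnsetRecord(
            primaryid=report.primaryid,
            regimen=report.regimen,
            exclusion_reason="partial_or_missing_event_date",
        )
    starts = [
        parse_partial_date(d.start_dt)
        for d in report.drugs
        if lexicon.is_index(d.name)
    ]
    full_starts = [s.to_date() for s in starts if s is not None and s.is_full]
    if not full_starts:
        return OnsetRecord(
            primaryid=report.primaryid,
            regimen=report.regimen,
            exclusion_reason="partial_or_missing_start_date",
        )
    start = min(full_starts)
    delta = (event.to_date() - start).days
    if delta < 0:
        return OnsetRecord(
            primaryid=report.primaryid,
            regimen=report.regimen,
            exclusion_reason="event_before_start",
        )
    return OnsetRecord(primaryid=report.primaryid, regimen=report.regimen, onset_days=delta)


def compute_onsets(
    reports: Iterable[CaseReport], lexicon: DrugLexicon
) -> list[OnsetRecord]:
    return [compute_onset(r, lexicon) for r in reports]


def summarize_onset(
    records: Iterable[OnsetRecord],
    regimen: Optional[RegimenClass] = None,
) -> OnsetSummary:
    """Median, quartiles and empirical CDF of usable onset records."""
    days = sorted(
        r.onset_days
        for r in records
        if r.usable and (regimen is None or r.regimen == regimen)
    )
    if not days:
        return OnsetSummary(0, math.nan, math.nan, math.nan, ())
    arr = np.asarray(days, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    n = len(arr)
    curve: list[tuple[float, float]] = []
    for value in sorted(set(days)):
        frac = float(np.searchsorted(arr, value, side="right")) / n
        curve.append((float(value), frac))
    return OnsetSummary(
        n_used=n,
        median_days=float(med),
        q1_days=float(q1),
        q3_days=float(q3),
        cumulative_curve=tuple(curve),
    )


def onset_bin_table(
    records: Iterable[OnsetRecord],
    edges: Sequence[int] = DEFAULT_ONSET_BINS,
    regimen: Optional[RegimenClass] = None,
) -> pd.DataFrame:
    """Counts and percentages of usable onsets per day-range bin."""
    days = [
        r.onset_days
        for r in records
        if r.usable and (regimen is None or r.regimen == regimen)
    ]
    edges = sorted(edges)
    labels = []
    low = 0
    for e in edges:
        labels.append(f"{low}-{e}")
        low = e + 1
    labels.append(f">{edges[-1]}")
    counts = [0] * len(labels)
    for d in days:
        idx = int(np.searchsorted(edges, d, side="left"))
        counts[idx] += 1
    total = len(days)
    pct = [round(100.0 * c / total, 1) if total else math.nan for c in counts]
    return pd.DataFrame({"bin": labels, "count": counts, "pct": pct})


@dataclass
class CohortSummary:
    """Characteristic tables with per-subgroup and overall counts.

    ``counts[characteristic]`` is a category-by-group DataFrame whose
    columns are "Overall" plus the four regimen subgroups.
    """

    subgroup_sizes: dict[str, int]
    counts: dict[str, pd.DataFrame]
    quantile_rule: str = QUANTILE_RULE

    def percentages(self, characteristic: str) -> pd.DataFrame:
        frame = self.counts[characteristic]
        out = frame.astype(float).copy()
        for col in frame.columns:
            size = self.subgroup_sizes.get(col, 0)
            out[col] = (
                (100.0 * frame[col] / size).round(1) if size else math.nan
            )
        return out

    def formatted(self, characteristic: str) -> pd.DataFrame:
        """"count (pct%)" cells, Table-style."""
        counts = self.counts[characteristic]
        pct = self.percentages(characteristic)
        return pd.DataFrame(
            {
                col: [
                    f"{counts.at[i, col]} ({pct.at[i, col]:.1f}%)"
                    for i in counts.index
                ]
                for col in counts.columns
            },
            index=counts.index,
        )


def _year_bin(fda_dt: str) -> str:
    parsed = parse_partial_date(fda_dt)
    if parsed is None:
        return "Unknown"
    y = parsed.year
    if y >= 2019:
        return YEAR_BIN_LABELS[0]
    if y >= 2014:
        return YEAR_BIN_LABELS[1]
    if y >= 2009:
        return YEAR_BIN_LABELS[2]
    return YEAR_BIN_LABELS[3]


def _indication_category(report: CaseReport, lexicon: DrugLexicon) -> str:
    if not report.indications:
        return "Unspecified"
    texts = [str(p).casefold() for p in report.indications]
    for category, keywords in lexicon.indication_categories:
        for kw in keywords:
            if any(kw in t for t in texts):
                return category
    return "Others"


def _country_category(report: CaseReport, lexicon: DrugLexicon) -> str:
    raw = report.reporter_country.strip().casefold()
    if not raw:
        return "Unspecified"
    for name, aliases in lexicon.countries:
        if raw in aliases or raw == name.casefold():
            return name
    return "Others"


def summarize_cohort(
    reports: Sequence[CaseReport],
    lexicon: Optional[DrugLexicon] = None,
) -> CohortSummary:
    """Build the characteristics table for a classified, flagged cohort."""
    lexicon = lexicon or DrugLexicon.default()
    groups: dict[str, list[CaseReport]] = {"Overall": list(reports)}
    for rc in SUBGROUP_ORDER:
        groups[rc.value] = [r for r in reports if r.regimen == rc]
    sizes = {name: len(members) for name, members in groups.items()}

    def _single_valued(categories: Sequence[str], classify) -> pd.DataFrame:
        frame = pd.DataFrame(0, index=list(categories), columns=list(groups), dtype=int)
        for name, members in groups.items():
            for r in members:
                frame.at[classify(r), name] += 1
        return frame

    gender = _single_valued(
        ["Female", "Male", "Unknown"],
        lambda r: {"F": "Female", "M": "Male"}.get(r.sex.strip().upper(), "Unknown"),
    )
    years = _single_valued(list(YEAR_BIN_LABELS) + ["Unknown"], lambda r: _year_bin(r.fda_dt))
    indication_order = [c for c, _ in lexicon.indication_categories] + ["Others", "Unspecified"]
    indications = _single_valued(indication_order, lambda r: _indication_category(r, lexicon))
    country_order = [c for c, _ in lexicon.countries] + ["Others", "Unspecified"]
    countries = _single_valued(country_order, lambda r: _country_category(r, lexicon))
    reporters = _single_valued(
        list(REPORTER_LABELS.values()) + ["Unspecified"],
        lambda r: REPORTER_LABELS.get(r.occp_cod.strip().upper(), "Unspecified"),
    )
    age_missing = _single_valued(
        ["Reported", "Missing"],
        lambda r: "Reported" if r.age.strip() else "Missing",
    )

    # outcome rows are non-exclusive; Unspecified counts reports with no code
    outcome_rows = list(OUTCOME_LABELS.values()) + ["Unspecified"]
    outcomes = pd.DataFrame(0, index=outcome_rows, columns=list(groups), dtype=int)
    for name, members in groups.items():
        for r in members:
            listed = [c for c in r.outcomes if c in OUTCOME_LABELS]
            if not listed:
                outcomes.at["Unspecified", name] += 1
            for code in listed:
                outcomes.at[OUTCOME_LABELS[code], name] += 1

    return CohortSummary(
        subgroup_sizes=sizes,
        counts={
            "gender": gender,
            "reporting_year": years,
            "indications": indications,
            "outcomes": outcomes,
            "countries": countries,
            "reporters": reporters,
            "age_missingness": age_missing,
        },
    )
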