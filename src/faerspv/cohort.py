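"""Index-drug cohort construction and regimen classification.

A report enters the cohort when at least one of its drug names, after
normalization, exactly equals an index synonym (biosimilar names are
excluded via a configurable deny-list).  Each cohort report is assigned
exactly one regimen class from its co-medication categories using a
configurable precedence, and flagged when any of its reaction preferred
terms matches the target PT set (case-insensitive exact match, no
dictionary-hierarchy expansion).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .errors import ConfigurationError
from .faers_io import QuarterTables

_WS = re.compile(r"\s+")

#: regimen precedence applied when several co-medication categories co-occur
DEFAULT_PRECEDENCE: tuple[str, ...] = ("chemotherapy", "ici", "targeted")


class RegimenClass(enum.Enum):
    """Mutually exclusive treatment-regimen subgroups."""

    MONO = "MONO"
    PLUS_CHEMO = "PLUS_CHEMO"
    PLUS_ICI = "PLUS_ICI"
    PLUS_TARGETED = "PLUS_TARGETED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_CATEGORY_TO_REGIMEN = {
    "chemotherapy": RegimenClass.PLUS_CHEMO,
    "ici": RegimenClass.PLUS_ICI,
    "targeted": RegimenClass.PLUS_TARGETED,
}


def normalize_drugname(raw: object, strip_dosage: bool = False) -> str:
    """Trim, collapse internal whitespace and case-fold a free-text drug name.

    With ``strip_dosage`` enabled, trailing dosage tokens such as
    ``"10 mg"`` or ``"100mg/ml"`` are removed.
    """
    text = _WS.sub(" ", str(raw)).strip().casefold()
    if strip_dosage:
        text = re.sub(r"\s+\d+(\.\d+)?\s*(mg|mcg|ug|g|ml|mg/ml|%)\.?$", "", text)
    return text


@dataclass(frozen=True)
class DrugLexicon:
    """Named drug categories with normalized membership sets."""

    index_synonyms: frozenset[str]
    chemotherapy: frozenset[str]
    ici: frozenset[str]
    targeted: frozenset[str]
    biosimilar_names: frozenset[str] = frozenset()
    biosimilar_prefixes: tuple[str, ...] = ()
    target_pts: frozenset[str] = frozenset()
    indication_categories: tuple[tuple[str, tuple[str, ...]], ...] = ()
    countries: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self) -> None:
        for cat in ("chemotherapy", "ici", "targeted"):
            overlap = self.index_synonyms & getattr(self, cat)
            if overlap:
                raise ConfigurationError(
                    f"index_synonyms overlap category {cat!r}: {sorted(overlap)}"
                )

    def category_sets(self) -> Mapping[str, frozenset[str]]:
        return {
            "chemotherapy": self.chemotherapy,
            "ici": self.ici,
            "targeted": self.targeted,
        }

    def is_denied(self, normalized: str) -> bool:
        if normalized in self.biosimilar_names:
            return True
        return any(normalized.startswith(p) for p in self.biosimilar_prefixes)

    def is_index(self, normalized: str) -> bool:
        return normalized in self.index_synonyms and not self.is_denied(normalized)

    @staticmethod
    def from_dict(cfg: Mapping) -> "DrugLexicon":
        def _normset(key: str) -> frozenset[str]:
            return frozenset(normalize_drugname(n) for n in cfg.get(key, []))

        deny = cfg.get("biosimilar_denylist", {}) or {}
        target = frozenset(str(p).strip().casefold() for p in cfg.get("target_pts", []))
        indications = tuple(
            (str(cat), tuple(str(k).casefold() for k in keys))
            for cat, keys in (cfg.get("indication_categories", {}) or {}).items()
        )
        countries = tuple(
            (str(c), tuple(str(a).casefold() for a in aliases))
            for c, aliases in (cfg.get("countries", {}) or {}).items()
        )
        lex = DrugLexicon(
            index_synonyms=_normset("index_synonyms"),
            chemotherapy=_normset("chemotherapy"),
            ici=_normset("ici"),
            targeted=_normset("targeted"),
            biosimilar_names=frozenset(
                normalize_drugname(n) for n in deny.get("names", [])
            ),
            biosimilar_prefixes=tuple(
                normalize_drugname(p) for p in deny.get("prefixes", [])
            ),
            target_pts=target,
            indication_categories=indications,
            countries=countries,
        )
        if not lex.index_synonyms:
            raise ConfigurationError("index_synonyms must not be empty")
        return lex

    @staticmethod
    def from_yaml(path: Union[str, Path]) -> "DrugLexicon":
        with open(path, "r", encoding="utf-8") as fh:
            return DrugLexicon.from_dict(yaml.safe_load(fh))

    @staticmethod
    def default() -> "DrugLexicon":
        """The packaged lexicon (index synonyms plus the three categories)."""
        ref = resources.files("faerspv.data") / "default_lexicon.yaml"
        return DrugLexicon.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


@dataclass(frozen=True)
class DrugEntry:
    name: str  # normalized
    role: str = ""
    start_dt: Optional[str] = None


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated safety report in the analysis data model."""

    primaryid: str
    caseid: str = ""
    sex: str = ""
    fda_dt: str = ""
    event_dt: str = ""
    occp_cod: str = ""
    reporter_country: str = ""
    age: str = ""
    drugs: tuple[DrugEntry, ...] = ()
    reactions: frozenset[str] = frozenset()
    outcomes: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()
    regimen: Optional[RegimenClass] = None
    is_target_event: bool = False

    def has_index_drug(self, lexicon: DrugLexicon) -> bool:
        return any(lexicon.is_index(d.name) for d in self.drugs)


def flag_target_events(report: CaseReport, target_pts: Iterable[str]) -> bool:
    """Report-level flag: any reaction PT equals a target PT (case-insensitive)."""
    targets = {str(p).strip().casefold() for p in target_pts}
    if not targets:
        raise ConfigurationError("target_pts must not be empty")
    return any(str(r).strip().casefold() in targets for r in report.reactions)


def classify_regimen(
    report: CaseReport,
    lexicon: DrugLexicon,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    roles: Optional[Iterable[str]] = None,
) -> RegimenClass:
    """Assign the mutually exclusive regimen class for an index-drug report.

    Co-medication category membership is computed from normalized names;
    when several categories co-occur the first category in ``precedence``
    wins.  ``roles`` optionally restricts which drug role codes count as
    co-medication (default: all roles, mirroring the analysis choice of
    not restricting by role).  Invariant to drug order within the report.
    """
    if not report.has_index_drug(lexicon):
        raise ValueError(f"report {report.primaryid} carries no index drug")
    unknown = [c for c in precedence if c not in _CATEGORY_TO_REGIMEN]
    if unknown:
        raise ConfigurationError(f"unknown precedence categories: {unknown}")
    role_filter = {r.upper() for r in roles} if roles is not None else None
    categories = lexicon.category_sets()
    present: set[str] = set()
    for drug in report.drugs:
        if lexicon.is_index(drug.name):
            continue
        if role_filter is not None and drug.role.upper() not in role_filter:
            continue
        for cat, names in categories.items():
            if drug.name in names:
                present.add(cat)
    for cat in precedence:
        if cat in present:
            return _CATEGORY_TO_REGIMEN[cat]
    return RegimenClass.MONO


def select_index_reports(
    drug_table: pd.DataFrame,
    lexicon: DrugLexicon,
    within: Optional[Iterable[str]] = None,
) -> list[str]:
    """PRIMARYIDs of reports naming the index drug, in stable source order.

    ``within`` optionally restricts the search to the given (e.g.
    deduplicated) report keys.
    """
    if not lexicon.index_synonyms:
        raise ConfigurationError("lexicon has no index synonyms")
    names = drug_table["drugname"].map(normalize_drugname)
    is_index = names.map(lexicon.is_index)
    ids = drug_table.loc[is_index, "primaryid"].astype(str)
    if within is not None:
        allowed = {str(p) for p in within}
        ids = ids[ids.isin(allowed)]
    return list(dict.fromkeys(ids))


def target_event_primaryids(
    reac_table: pd.DataFrame, target_pts: Iterable[str]
) -> set[str]:
    """PRIMARYIDs with at least one target-PT reaction (background flagging)."""
    targets = {str(p).strip().casefold() for p in target_pts}
    if not targets:
        raise ConfigurationError("target_pts must not be empty")
    hits = reac_table["pt"].astype(str).str.strip().str.casefold().isin(targets)
    return set(reac_table.loc[hits, "primaryid"].astype(str))


def build_case_reports(
    tables: QuarterTables,
    primaryids: Sequence[str],
    lexicon: DrugLexicon,
    target_pts: Optional[Iterable[str]] = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    roles: Optional[Iterable[str]] = None,
) -> list[CaseReport]:
    """Assemble :class:`CaseReport` objects for the given report keys.

    Joins DEMO, DRUG, REAC, THER, OUTC and INDI on PRIMARYID; THER start
    dates attach to drugs via DSG_DRUG_SEQ (a drug with several therapy
    rows contributes one entry per row).  Reports with an index drug get
    a regimen class and a target-event flag.
    """
    wanted = [str(p) for p in primaryids]
    wanted_set = set(wanted)
    target = (
        {str(p).strip().casefold() for p in target_pts}
        if target_pts is not None
        else set(lexicon.target_pts)
    )

    demo = tables.demo[tables.demo["primaryid"].astype(str).isin(wanted_set)]
    demo_by_id = {str(r["primaryid"]): r for _, r in demo.iterrows()}

    def _grouped(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
        sub = frame[frame["primaryid"].astype(str).isin(wanted_set)]
        return {str(k): g for k, g in sub.groupby(sub["primaryid"].astype(str))}

    drugs_by_id = _grouped(tables.drug)
    reac_by_id = _grouped(tables.reac)
    ther_by_id = _grouped(tables.ther)
    outc_by_id = _grouped(tables.outc)
    indi_by_id = _grouped(tables.indi)

    reports: list[CaseReport] = []
    for pid in wanted:
        demo_row = demo_by_id.get(pid)
        ther = ther_by_id.get(pid)
        starts: dict[str, list[str]] = {}
        if ther is not None:
            for _, row in ther.iterrows():
                starts.setdefault(str(row["dsg_drug_seq"]), []).append(
                    str(row.get("start_dt", "") or "")
                )
        entries: list[DrugEntry] = []
        drug_rows = drugs_by_id.get(pid)
        if drug_rows is not None:
            for _, row in drug_rows.iterrows():
                name = normalize_drugname(row["drugname"])
                role = str(row.get("role_cod", "") or "")
                seq_starts = starts.get(str(row.get("drug_seq", "")), [None])
                for s in seq_starts:
                    entries.append(DrugEntry(name=name, role=role, start_dt=s))
        reac = reac_by_id.get(pid)
        reactions = (
            frozenset(str(p).strip() for p in reac["pt"] if str(p).strip())
            if reac is not None
            else frozenset()
        )
        outc = outc_by_id.get(pid)
        outcomes = (
            frozenset(str(c).strip().upper() for c in outc["outc_cod"] if str(c).strip())
            if outc is not None
            else frozenset()
        )
        indi = indi_by_id.get(pid)
        indications = (
            frozenset(str(p).strip() for p in indi["indi_pt"] if str(p).strip())
            if indi is not None
            else frozenset()
        )
        report = CaseReport(
            primaryid=pid,
            caseid=str(demo_row["caseid"]) if demo_row is not None else "",
            sex=str(demo_row.get("sex", "") or "") if demo_row is not None else "",
            fda_dt=str(demo_row.get("fda_dt", "") or "") if demo_row is not None else "",
            event_dt=str(demo_row.get("event_dt", "") or "") if demo_row is not None else "",
            occp_cod=str(demo_row.get("occp_cod", "") or "") if demo_row is not None else "",
            reporter_country=str(demo_row.get("reporter_country", "") or "")
            if demo_row is not None
            else "",
            age=str(demo_row.get("age", "") or "") if demo_row is not None else "",
            drugs=tuple(entries),
            reactions=reactions,
            outcomes=outcomes,
            indications=indications,
        )
        if report.has_index_drug(lexicon):
            report = replace(
                report,
                regimen=classify_regimen(report, lexicon, precedence, roles),
                is_target_event=flag_target_events(report, target) if target else False,
            )
        reports.append(report)
    return reports
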