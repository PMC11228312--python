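"""Reading and validation of FAERS-format quarterly ASCII files.

Dialect: "$"-delimited, one header row naming the columns, no quoting,
UTF-8 with replacement for undecodable bytes.  Only the PRIMARYID-era
schema is supported; legacy ISR-era files are out of scope.  Dates are
kept as structured partial dates (year, optional month, optional day)
rather than being coerced to a sentinel.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import FormatError, IngestionError

logger = logging.getLogger(__name__)

#: canonical column names per table; the first group is mandatory for the
#: table to be usable, the second is carried when present.
TABLE_SCHEMAS: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "demo": (
        ("primaryid", "caseid", "fda_dt"),
        ("event_dt", "sex", "occp_cod", "reporter_country", "age", "age_cod"),
    ),
    "drug": (("primaryid", "drug_seq", "drugname"), ("role_cod",)),
    "reac": (("primaryid", "pt"), ()),
    "ther": (("primaryid", "dsg_drug_seq"), ("start_dt", "end_dt")),
    "outc": (("primaryid", "outc_cod"), ()),
    "indi": (("primaryid", "indi_drug_seq", "indi_pt"), ()),
    "rpsr": (("primaryid",), ("rpsr_cod",)),
}

#: legacy / variant spellings mapped onto canonical names (case-insensitive).
COLUMN_ALIASES: Mapping[str, str] = {
    "gndr_cod": "sex",
    "outc_code": "outc_cod",
    "lot_nbr": "lot_num",
}

MANDATORY_TABLES = ("demo", "drug", "reac")
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


@dataclass(frozen=True, order=True)
class PartialDate:
    """A date known at least to the year, possibly missing month and/or day."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def is_full(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> _dt.date:
        if not self.is_full:
            raise ValueError(f"partial date {self} has no day resolution")
        return _dt.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        """Total order placing partial dates before any refinement of them."""
        return (self.year, self.month or 0, self.day or 0)


def parse_partial_date(s: object) -> Optional[PartialDate]:
    """Parse a FAERS date string into a :class:`PartialDate`.

    Accepts ``YYYYMMDD``, ``YYYYMM`` and ``YYYY``; anything that does not
    yield a plausible calendar year returns ``None``.  Total function:
    never raises on content.

    >>> parse_partial_date("20200213")
    PartialDate(year=2020, month=2, day=13)
    >>> parse_partial_date("2020")
    PartialDate(year=2020, month=None, day=None)
    >>> parse_partial_date("00000000") is None
    True
    """
    if s is None:
        return None
    text = str(s).strip()
    if not text.isdigit() or len(text) not in (4, 6, 8):
        return None
    year = int(text[:4])
    if not 1000 <= year <= 9999:
        return None
    if len(text) == 4:
        return PartialDate(year)
    month = int(text[4:6])
    if not 1 <= month <= 12:
        return PartialDate(year)
    if len(text) == 6:
        return PartialDate(year, month)
    day = int(text[6:8])
    if not 1 <= day <= calendar.monthrange(year, month)[1]:
        return PartialDate(year, month)
    return PartialDate(year, month, day)


@dataclass
class QuarterTables:
    """Typed record tables for one quarterly file set.

    Each table is a :class:`pandas.DataFrame` of strings in stable source
    order with canonical lower-case column names.  ``malformed_rows``
    counts physical data rows that could not be split into the expected
    number of fields, per table.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    rpsr: Optional[pd.DataFrame] = None
    malformed_rows: dict[str, int] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _empty_table(name: str) -> pd.DataFrame:
    mandatory, optional = TABLE_SCHEMAS[name]
    return pd.DataFrame(columns=list(mandatory) + list(optional), dtype=str)


def _canonical_column(raw: str) -> str:
    name = raw.strip().lower()
    return COLUMN_ALIASES.get(name, name)


def read_table(path: Union[str, Path], name: str) -> tuple[pd.DataFrame, int]:
    """Read one "$"-delimited table; returns (frame, malformed row count).

    Malformed rows (more fields than the header declares) are counted and
    logged, not silently dropped into the frame.  Short rows are padded
    with empty strings.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise FormatError(f"{path}: no header row")
    columns = [_canonical_column(c) for c in lines[0].split("$")]
    mandatory, _ = TABLE_SCHEMAS[name]
    missing = [c for c in mandatory if c not in columns]
    if missing:
        raise FormatError(
            f"{path}: header lacks mandatory column(s) {missing} for {name.upper()}"
        )
    # the dialect has no quoting, so a plain split is exact; rows with more
    # fields than the header are malformed, shorter rows pad with ""
    ncol = len(columns)
    rows: list[list[str]] = []
    bad = 0
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("$")
        if len(fields) > ncol:
            bad += 1
            continue
        if len(fields) < ncol:
            fields = fields + [""] * (ncol - len(fields))
        rows.append(fields)
    frame = pd.DataFrame(rows, columns=columns, dtype=str)
    if frame.empty:
        frame = pd.DataFrame(columns=columns, dtype=str)
    # carry optional canonical columns as empty strings when absent
    for col in TABLE_SCHEMAS[name][1]:
        if col not in frame.columns:
            frame[col] = ""
    if bad:
        logger.warning("%s: %d malformed row(s) skipped", path, bad)
    frame = frame.reset_index(drop=True)
    return frame, bad


def _match_files(directory: Path) -> dict[str, Path]:
    found: dict[str, Path] = {}
    for entry in sorted(directory.iterdir()):
        if not entry.is_file():
            continue
        lower = entry.name.lower()
        for name in TABLE_SCHEMAS:
            if lower.startswith(name) and name not in found:
                found[name] = entry
    return found


def read_quarter(
    dir_or_files: Union[str, Path, Mapping[str, Union[str, Path]], Sequence[Union[str, Path]]],
) -> QuarterTables:
    """Load a FAERS quarterly file set into typed tables.

    ``dir_or_files`` may be a directory (files matched by name prefix:
    DEMO*, DRUG*, REAC*, THER*, OUTC*, INDI*, RPSR*), an explicit mapping
    ``{"demo": path, ...}``, or a sequence of paths matched by prefix.
    DEMO, DRUG and REAC are mandatory; the remaining tables default to
    empty.  RPSR is read when present but ignored by the analysis.
    """
    if isinstance(dir_or_files, Mapping):
        files = {k.lower(): Path(v) for k, v in dir_or_files.items()}
    elif isinstance(dir_or_files, (str, Path)):
        directory = Path(dir_or_files)
        if not directory.is_dir():
            raise IngestionError(f"{directory} is not a directory")
        files = _match_files(directory)
    else:
        files = {}
        for p in map(Path, dir_or_files):
            lower = p.name.lower()
            for name in TABLE_SCHEMAS:
                if lower.startswith(name) and name not in files:
                    files[name] = p
    for name in MANDATORY_TABLES:
        if name not in files:
            raise IngestionError(f"mandatory {name.upper()} file not found")
        if not files[name].exists():
            raise IngestionError(f"{files[name]} does not exist")

    tables: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    sources: dict[str, str] = {}
    for name in TABLE_SCHEMAS:
        if name in files and files[name].exists():
            tables[name], malformed[name] = read_table(files[name], name)
            sources[name] = str(files[name])
        elif name != "rpsr":
            tables[name] = _empty_table(name)
            malformed[name] = 0
    return QuarterTables(
        demo=tables["demo"],
        drug=tables["drug"],
        reac=tables["reac"],
        ther=tables["ther"],
        outc=tables["outc"],
        indi=tables["indi"],
        rpsr=tables.get("rpsr"),
        malformed_rows=malformed,
        sources=sources,
    )


def concat_quarters(quarters: Iterable[QuarterTables]) -> QuarterTables:
    """Concatenate several quarterly table sets in source order."""
    quarters = list(quarters)
    if not quarters:
        raise IngestionError("no quarters to concatenate")

    def _cat(name: str) -> pd.DataFrame:
        frames = [q.table(name) for q in quarters if q.table(name) is not None]
        if not frames:
            return _empty_table(name)
        return pd.concat(frames, ignore_index=True)

    malformed: dict[str, int] = {}
    for q in quarters:
        for k, v in q.malformed_rows.items():
            malformed[k] = malformed.get(k, 0) + v
    return QuarterTables(
        demo=_cat("demo"),
        drug=_cat("drug"),
        reac=_cat("reac"),
        ther=_cat("ther"),
        outc=_cat("outc"),
        indi=_cat("indi"),
        rpsr=None,
        malformed_rows=malformed,
    )


def read_quarters(root: Union[str, Path]) -> QuarterTables:
    """Read every quarter directory under ``root`` (or ``root`` itself).

    A directory is treated as a quarter when it directly contains a
    DEMO* file; quarters are concatenated in sorted directory order.
    """
    root = Path(root)
    if not root.is_dir():
        raise IngestionError(f"{root} is not a directory")
    if "demo" in _match_files(root):
        return read_quarter(root)
    subdirs = [d for d in sorted(root.iterdir()) if d.is_dir() and "demo" in _match_files(d)]
    if not subdirs:
        raise IngestionError(f"no quarterly file sets found under {root}")
    return concat_quarters(read_quarter(d) for d in subdirs)
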