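"""Synthetic FAERS-shaped quarterly file sets with known ground truth.

The generator emulates the statistical structure the downstream stages
assume: reports carrying free-text drug names, MedDRA-style preferred
terms, outcome codes, therapy dates with partial/missing values, and
case duplicates re-submitted across quarters.  Event assignment for a
report carrying drug groups G uses

    odds = baseline_odds * prod(multiplier(g) for g in G)

so the realized drug-event odds ratio per group is known and tunable.
Onset days are drawn from a log-normal parameterized by (median,
dispersion); drug names get random case and occasional trailing
whitespace to exercise normalization.  Everything is deterministic given
the seed: truth-level draws and file-cosmetic draws use two independent
child streams of the config seed, so in-memory truth simulation and file
generation agree.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DegenerateTableError, UnknownGroupError

TARGET_PTS = ("Pulmonary haemorrhage", "Haemoptysis")

NONTARGET_PTS = (
    "Nausea",
    "Epistaxis",
    "Fatigue",
    "Headache",
    "Hypertension",
    "Diarrhoea",
    "Proteinuria",
    "Pyrexia",
    "Anaemia",
    "Vomiting",
)

FILLER_DRUGS = (
    "Aspirin",
    "Metformin",
    "Omeprazole",
    "Lisinopril",
    "Atorvastatin",
    "Levothyroxine",
    "Amlodipine",
    "Dexamethasone",
)

INDICATION_PTS = (
    "Non-small cell lung cancer",
    "Colorectal cancer",
    "Breast cancer",
    "Renal cell carcinoma",
    "Gastric cancer",
    "Ovarian cancer",
    "Hepatocellular carcinoma",
    "Glioblastoma",
)

COUNTRIES = ("US", "JP", "CN", "GB", "DE", "FR", "")
COUNTRY_P = (0.45, 0.15, 0.07, 0.06, 0.06, 0.06, 0.15)
SEXES = ("F", "M", "")
SEX_P = (0.40, 0.42, 0.18)
OCCUPATIONS = ("MD", "PH", "CN", "HP", "OT", "")
OCCUPATION_P = (0.45, 0.08, 0.12, 0.06, 0.19, 0.10)

DEFAULT_OUTCOME_PROBS: Mapping[str, float] = {
    "DE": 0.18,
    "LT": 0.04,
    "HO": 0.25,
    "DS": 0.02,
    "OT": 0.31,
    "": 0.20,
}


@dataclass(frozen=True)
class GroupSpec:
    """One drug category with its marginal carriage probability and the
    multiplicative effect it has on the target-event odds."""

    name: str
    drug_pool: tuple[str, ...]
    marginal_prob: float
    odds_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("group_specs: name must be non-empty")
        if not self.drug_pool:
            raise ConfigurationError(f"group_specs[{self.name}]: drug_pool must be non-empty")
        if not 0.0 < self.marginal_prob < 1.0:
            raise ConfigurationError(
                f"group_specs[{self.name}]: marginal_prob must be in (0,1)"
            )
        if self.odds_multiplier < 0:
            raise ConfigurationError(
                f"group_specs[{self.name}]: odds_multiplier must be >= 0"
            )


@dataclass(frozen=True)
class SimulationConfig:
    n_reports: int
    baseline_event_prob: float
    group_specs: tuple[GroupSpec, ...]
    duplicate_rate: float = 0.0
    partial_date_rate: float = 0.0
    missing_event_date_rate: float = 0.0
    onset_median_days: float = 40.0
    onset_dispersion: float = 1.0
    seed: int = 0
    n_quarters: int = 4
    first_year: int = 2020
    first_quarter: int = 1
    outcome_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS)
    )

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be >= 1")
        if not 0.0 < self.baseline_event_prob < 1.0:
            raise ConfigurationError("baseline_event_prob must be in (0,1)")
        if not self.group_specs:
            raise ConfigurationError("group_specs must contain at least one group")
        names = [g.name for g in self.group_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("group_specs: group names must be unique")
        for fname in ("duplicate_rate", "partial_date_rate", "missing_event_date_rate"):
            v = getattr(self, fname)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{fname} must be in [0,1)")
        if self.onset_median_days <= 0:
            raise ConfigurationError("onset_median_days must be > 0")
        if self.onset_dispersion <= 0:
            raise ConfigurationError("onset_dispersion must be > 0")
        if self.n_quarters < 1:
            raise ConfigurationError("n_quarters must be >= 1")
        if not 1 <= self.first_quarter <= 4:
            raise ConfigurationError("first_quarter must be in 1..4")
        total = sum(self.outcome_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError("outcome_probs must sum to 1")

    @staticmethod
    def from_dict(cfg: Mapping) -> "SimulationConfig":
        cfg = dict(cfg)
        raw_groups = cfg.pop("group_specs", cfg.pop("groups", None))
        if raw_groups is None:
            raise ConfigurationError("group_specs is required")
        groups = []
        for g in raw_groups:
            if isinstance(g, Mapping):
                groups.append(
                    GroupSpec(
                        name=str(g["name"]),
                        drug_pool=tuple(str(d) for d in g["drug_pool"]),
                        marginal_prob=float(g["marginal_prob"]),
                        odds_multiplier=float(g.get("odds_multiplier", 1.0)),
                    )
                )
            else:  # (name, pool, prob, multiplier) tuple form
                name, pool, prob, mult = g
                groups.append(
                    GroupSpec(
                        name=str(name),
                        drug_pool=tuple(str(d) for d in pool),
                        marginal_prob=float(prob),
                        odds_multiplier=float(mult),
                    )
                )
        known = {f for f in SimulationConfig.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration field(s): {sorted(unknown)}")
        return SimulationConfig(group_specs=tuple(groups), **cfg)

    @staticmethod
    def from_file(path: Union[str, Path]) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return SimulationConfig.from_dict(data)


def example_config(
    n_reports: int = 5000, seed: int = 0, **overrides
) -> SimulationConfig:
    """A ready-to-run configuration with an index-drug group and the three
    co-medication categories, each with a distinct odds multiplier."""
    groups = (
        GroupSpec("index", ("Bevacizumab", "Avastin"), 0.06, 4.0),
        GroupSpec(
            "chemotherapy",
            ("Carboplatin", "Cisplatin", "Paclitaxel", "Gemcitabine", "Pemetrexed"),
            0.12,
            1.5,
        ),
        GroupSpec("ici", ("Atezolizumab", "Nivolumab", "Pembrolizumab"), 0.03, 1.0),
        GroupSpec("targeted", ("Erlotinib", "Sorafenib", "Cetuximab"), 0.05, 1.2),
    )
    defaults = dict(
        n_reports=n_reports,
        baseline_event_prob=0.02,
        group_specs=groups,
        duplicate_rate=0.08,
        partial_date_rate=0.15,
        missing_event_date_rate=0.2,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class GroundTruth:
    """Realized per-report assignments for one generated unique cohort."""

    def __init__(self, config: SimulationConfig, reports: pd.DataFrame):
        self.config = config
        self.multipliers = {g.name: g.odds_multiplier for g in config.group_specs}
        self.reports = reports  # one row per unique report

    def __len__(self) -> int:
        return len(self.reports)

    def membership(self, group: str) -> np.ndarray:
        col = f"in_{group}"
        if col not in self.reports.columns:
            raise UnknownGroupError(group)
        return self.reports[col].to_numpy(dtype=bool)

    def contingency(self, group: str) -> tuple[int, int, int, int]:
        member = self.membership(group)
        event = self.reports["event"].to_numpy(dtype=bool)
        a = int(np.sum(member & event))
        b = int(np.sum(member & ~event))
        c = int(np.sum(~member & event))
        d = int(np.sum(~member & ~event))
        return a, b, c, d


def truth_odds_ratio(truth: GroundTruth, group: str) -> float:
    """Exact odds ratio realized in the generated unique reports.

    Computed from the realized 2x2, not the configured multiplier.
    Raises :class:`DegenerateTableError` when a margin is empty (e.g. no
    events anywhere) or a denominator cell is zero.
    """
    a, b, c, d = truth.contingency(group)
    if a + c == 0:
        raise DegenerateTableError(f"group {group!r}: no events anywhere")
    if b == 0 or c == 0:
        raise DegenerateTableError(f"group {group!r}: zero denominator cell (b={b}, c={c})")
    return (a * d) / (b * c)


def _draw_truth(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    """Membership, event and onset draws — the seed-stable truth stream."""
    n = config.n_reports
    q = config.baseline_event_prob
    odds = np.full(n, q / (1.0 - q))
    data: dict[str, np.ndarray] = {}
    for g in config.group_specs:
        member = rng.random(n) < g.marginal_prob
        data[f"in_{g.name}"] = member
        odds = odds * np.where(member, g.odds_multiplier, 1.0)
    p = odds / (1.0 + odds)
    data["event"] = rng.random(n) < p
    mu = math.log(config.onset_median_days)
    onset = np.exp(rng.normal(mu, config.onset_dispersion, n))
    data["onset_days"] = np.maximum(0, np.rint(onset)).astype(int)
    frame = pd.DataFrame(data)
    frame.insert(0, "caseid", [str(10_000_000 + i) for i in range(n)])
    frame.insert(1, "primaryid", [f"{10_000_000 + i}1" for i in range(n)])
    group_names = [g.name for g in config.group_specs]
    member_cols = [data[f"in_{g}"] for g in group_names]
    frame["groups"] = [
        ",".join(name for name, m in zip(group_names, row) if m)
        for row in zip(*member_cols)
    ]
    return frame


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """In-memory ground truth only — no files; shares the truth stream
    with :func:`generate`, so both realize identical assignments."""
    truth_seed, _ = np.random.SeedSequence(config.seed).spawn(2)
    return GroundTruth(config, _draw_truth(np.random.default_rng(truth_seed), config))


def _quarter_bounds(year: int, quarter: int) -> tuple[_dt.date, _dt.date]:
    start = _dt.date(year, 3 * (quarter - 1) + 1, 1)
    if quarter == 4:
        end = _dt.date(year + 1, 1, 1)
    else:
        end = _dt.date(year, 3 * quarter + 1, 1)
    return start, end - _dt.timedelta(days=1)


def _fmt(d: Optional[_dt.date]) -> str:
    return d.strftime("%Y%m%d") if d is not None else ""


def _truncate(datestr: str, rng: np.random.Generator) -> str:
    return datestr[:6] if rng.random() < 0.5 else datestr[:4]


def _vary_case(name: str, rng: np.random.Generator) -> str:
    style = rng.integers(0, 4)
    if style == 0:
        out = name.upper()
    elif style == 1:
        out = name.lower()
    elif style == 2:
        out = name.title()
    else:
        out = name
    if rng.random() < 0.15:
        out = out + "  "
    return out


def generate(
    config: SimulationConfig, outdir: Union[str, Path]
) -> tuple[list[Path], GroundTruth]:
    """Write DEMO/DRUG/REAC/THER/OUTC/INDI quarterly files under ``outdir``.

    Each quarter directory (``<year>q<n>``) holds a contiguous slice of
    reports with FDA_DT inside the quarter.  A ``duplicate_rate``
    fraction of cases is re-emitted with the same CASEID, a later
    FDA_DT and a higher PRIMARYID (identical content otherwise), so the
    standard deduplication rule removes exactly the injected copies.
    Returns the quarter directories and the :class:`GroundTruth` of the
    unique reports.  Byte-identical for identical config (incl. seed).
    """
    outdir = Path(outdir)
    truth_seed, noise_seed = np.random.SeedSequence(config.seed).spawn(2)
    truth_frame = _draw_truth(np.random.default_rng(truth_seed), config)
    rng = np.random.default_rng(noise_seed)
    n = config.n_reports

    quarters: list[tuple[int, int]] = []
    year, qtr = config.first_year, config.first_quarter
    for _ in range(config.n_quarters):
        quarters.append((year, qtr))
        qtr += 1
        if qtr == 5:
            year, qtr = year + 1, 1
    q_index = (np.arange(n) * config.n_quarters) // n

    group_names = [g.name for g in config.group_specs]
    pools = {g.name: g.drug_pool for g in config.group_specs}

    rows: dict[str, list[list[str]]] = {
        name: [] for name in ("demo", "drug", "reac", "ther", "outc", "indi")
    }
    row_quarter: dict[str, list[int]] = {name: [] for name in rows}
    outcome_codes = list(config.outcome_probs)
    outcome_p = np.array([config.outcome_probs[c] for c in outcome_codes])

    fda_dates: list[_dt.date] = []
    for i in range(n):
        qy, qq = quarters[q_index[i]]
        qstart, qend = _quarter_bounds(qy, qq)
        fda = qstart + _dt.timedelta(days=int(rng.integers(0, (qend - qstart).days + 1)))
        fda_dates.append(fda)

    def _emit(i: int, primaryid: str, fda: _dt.date, quarter: int) -> None:
        caseid = truth_frame.at[i, "caseid"]
        onset = int(truth_frame.at[i, "onset_days"])
        lag = int(rng.integers(0, 90))
        start = fda - _dt.timedelta(days=onset + lag)
        event = start + _dt.timedelta(days=onset)

        start_s, event_s = _fmt(start), _fmt(event)
        if rng.random() < config.missing_event_date_rate:
            event_s = ""
        elif rng.random() < config.partial_date_rate:
            event_s = _truncate(event_s, rng)
        if rng.random() < config.partial_date_rate:
            start_s = _truncate(start_s, rng)

        sex = SEXES[rng.choice(len(SEXES), p=SEX_P)]
        occ = OCCUPATIONS[rng.choice(len(OCCUPATIONS), p=OCCUPATION_P)]
        country = COUNTRIES[rng.choice(len(COUNTRIES), p=COUNTRY_P)]
        age = str(int(rng.integers(30, 85))) if rng.random() < 0.05 else ""
        rows["demo"].append(
            [primaryid, caseid, _fmt(fda), event_s, sex, occ, country, age]
        )
        row_quarter["demo"].append(quarter)

        drugnames: list[str] = []
        for g in group_names:
            if truth_frame.at[i, f"in_{g}"]:
                pool = pools[g]
                drugnames.append(pool[int(rng.integers(0, len(pool)))])
        drugnames.append(FILLER_DRUGS[int(rng.integers(0, len(FILLER_DRUGS)))])
        for seq, name in enumerate(drugnames, start=1):
            role = "PS" if seq == 1 else ("SS" if seq == 2 else "C")
            rows["drug"].append([primaryid, str(seq), _vary_case(name, rng), role])
            row_quarter["drug"].append(quarter)
            rows["ther"].append([primaryid, str(seq), start_s])
            row_quarter["ther"].append(quarter)

        if truth_frame.at[i, "event"]:
            rows["reac"].append([primaryid, TARGET_PTS[int(rng.integers(0, len(TARGET_PTS)))]])
            row_quarter["reac"].append(quarter)
        rows["reac"].append(
            [primaryid, NONTARGET_PTS[int(rng.integers(0, len(NONTARGET_PTS)))]]
        )
        row_quarter["reac"].append(quarter)

        code = outcome_codes[int(rng.choice(len(outcome_codes), p=outcome_p))]
        if code:
            rows["outc"].append([primaryid, code])
            row_quarter["outc"].append(quarter)

        rows["indi"].append(
            [primaryid, "1", INDICATION_PTS[int(rng.integers(0, len(INDICATION_PTS)))]]
        )
        row_quarter["indi"].append(quarter)

    for i in range(n):
        _emit(i, truth_frame.at[i, "primaryid"], fda_dates[i], int(q_index[i]))

    # inject duplicates: same CASEID, later FDA_DT, higher PRIMARYID
    n_dup = int(math.floor(config.duplicate_rate * n))
    if n_dup:
        dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False))
        _, last_end = _quarter_bounds(*quarters[-1])
        for i in dup_idx:
            i = int(i)
            fda = fda_dates[i] + _dt.timedelta(days=int(rng.integers(30, 120)))
            if fda > last_end:
                fda = last_end
            dup_quarter = next(
                qi for qi, q in enumerate(quarters) if fda <= _quarter_bounds(*q)[1]
            )
            _emit(i, f"{truth_frame.at[i, 'caseid']}2", fda, dup_quarter)

    headers = {
        "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "occp_cod",
                 "reporter_country", "age"],
        "drug": ["primaryid", "drug_seq", "drugname", "role_cod"],
        "reac": ["primaryid", "pt"],
        "ther": ["primaryid", "dsg_drug_seq", "start_dt"],
        "outc": ["primaryid", "outc_cod"],
        "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
    }
    quarter_dirs: list[Path] = []
    for qi, (qy, qq) in enumerate(quarters):
        qdir = outdir / f"{qy}q{qq}"
        qdir.mkdir(parents=True, exist_ok=True)
        quarter_dirs.append(qdir)
        suffix = f"{qy % 100:02d}q{qq}"
        for name, header in headers.items():
            path = qdir / f"{name.upper()}{suffix}.txt"
            lines = ["$".join(header)]
            for row, rq in zip(rows[name], row_quarter[name]):
                if rq == qi:
                    lines.append("$".join(row))
            path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return quarter_dirs, GroundTruth(config, truth_frame)
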