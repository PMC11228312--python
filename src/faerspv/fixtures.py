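"""Deterministic fixture cohorts with prescribed characteristic counts.

Useful for validating the summary tables against externally known counts
and percentages: each subgroup gets exactly the requested number of
reports carrying a given sex, outcome, indication, reporting year and
reporter occupation, assigned independently of one another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .cohort import CaseReport, RegimenClass


@dataclass(frozen=True)
class SubgroupSpec:
    """Characteristic counts for one regimen subgroup of ``size`` reports."""

    size: int
    deaths: int = 0
    male: int = 0
    lung_indication: int = 0
    reported_2014_2018: int = 0
    md_reporter: int = 0

    def __post_init__(self) -> None:
        for name in ("deaths", "male", "lung_indication", "reported_2014_2018", "md_reporter"):
            v = getattr(self, name)
            if not 0 <= v <= self.size:
                raise ValueError(f"{name}={v} outside [0, size={self.size}]")


def build_characteristic_cohort(
    specs: Mapping[RegimenClass, SubgroupSpec],
) -> list[CaseReport]:
    """Target-event cohort realizing the per-subgroup counts exactly.

    Within each subgroup the first ``deaths`` reports carry outcome DE
    (the rest HO), the first ``male`` are sex M (the rest F), the first
    ``lung_indication`` carry a lung-cancer indication PT (the rest
    none), the first ``reported_2014_2018`` have an FDA receipt date in
    2015 (the rest 2020), and the first ``md_reporter`` have occupation
    MD (the rest blank).
    """
    reports: list[CaseReport] = []
    serial = 0
    for regimen, spec in specs.items():
        for j in range(spec.size):
            serial += 1
            reports.append(
                CaseReport(
                    primaryid=f"{serial}",
                    caseid=f"C{serial}",
                    sex="M" if j < spec.male else "F",
                    fda_dt="20150615" if j < spec.reported_2014_2018 else "20200615",
                    occp_cod="MD" if j < spec.md_reporter else "",
                    outcomes=frozenset({"DE"}) if j < spec.deaths else frozenset({"HO"}),
                    indications=frozenset({"Non-small cell lung cancer"})
                    if j < spec.lung_indication
                    else frozenset(),
                    reactions=frozenset({"Haemoptysis"}),
                    regimen=regimen,
                    is_target_event=True,
                )
            )
    return reports


def reference_cohort() -> list[CaseReport]:
    """The default validation cohort: four subgroups (150/292/13/42
    reports) with per-subgroup death, sex, indication, reporting-year and
    reporter counts fixed to known values."""
    specs = {
        RegimenClass.MONO: SubgroupSpec(
            size=150, deaths=57, male=66, lung_indication=60,
            reported_2014_2018=67, md_reporter=77,
        ),
        RegimenClass.PLUS_CHEMO: SubgroupSpec(
            size=292, deaths=148, male=121, lung_indication=176,
            reported_2014_2018=91, md_reporter=178,
        ),
        RegimenClass.PLUS_ICI: SubgroupSpec(
            size=13, deaths=6, male=9, lung_indication=10,
            reported_2014_2018=0, md_reporter=10,
        ),
        RegimenClass.PLUS_TARGETED: SubgroupSpec(
            size=42, deaths=15, male=17, lung_indication=18,
            reported_2014_2018=20, md_reporter=26,
        ),
    }
    return build_characteristic_cohort(specs)
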