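"""Disproportionality statistics: 2x2 tables, reporting odds ratios and
subgroup chi-square comparisons.

The counting unit is the unique deduplicated report for both the drug
group and the background cells; a drug-event-pair counting mode is not
implemented here (sensitivity analyses can rebuild tables from pair
counts and reuse :func:`compute_ror` unchanged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from scipy import stats

from .cohort import CaseReport, RegimenClass
from .errors import ConsistencyError

#: printed normal quantile used for the 95% interval
DEFAULT_Z = 1.96
#: minimum case count for a signal of disproportionate reporting
MIN_CASES = 3


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts: a/b inside the drug group, c/d outside it.

    ``a`` counts target-event reports in the group, ``b`` the remaining
    group reports, ``c`` target-event reports outside the group and
    ``d`` everything else; ``a+b+c+d`` is the analysis population size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
            if iv != v or iv < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, iv)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "ContingencyTable":
        """Swap the drug and event axes."""
        return ContingencyTable(self.a, self.c, self.b, self.d)

    def with_haldane(self) -> tuple[float, float, float, float]:
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class SignalResult:
    """A reporting odds ratio with its Wald interval and signal flag."""

    ror: float
    ci_low: float
    ci_high: float
    n_cases: int
    is_signal: bool
    z_quantile: float = DEFAULT_Z
    estimable: bool = True

    def as_dict(self) -> dict:
        return {
            "ror": self.ror,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_cases": self.n_cases,
            "is_signal": self.is_signal,
            "estimable": self.estimable,
        }


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    p_value: float
    dof: int = 1
    low_expected_warning: bool = False


def build_contingency(
    cohort: Sequence[CaseReport],
    group: Optional[RegimenClass],
    background: Union[pd.DataFrame, Iterable[tuple[str, bool]]],
) -> ContingencyTable:
    """Count the 2x2 of a regimen group (or whole cohort) against the
    full deduplicated report set.

    ``background`` lists every deduplicated report as (primaryid,
    target-event flag) pairs or an equivalent two-column DataFrame; the
    group's reports must be a subset of it.
    """
    if isinstance(background, pd.DataFrame):
        cols = list(background.columns)
        bg_pairs = list(
            zip(background[cols[0]].astype(str), background[cols[1]].astype(bool))
        )
    else:
        bg_pairs = [(str(p), bool(f)) for p, f in background]
    bg_ids = {p for p, _ in bg_pairs}
    if len(bg_ids) != len(bg_pairs):
        raise ConsistencyError("background contains duplicate primaryids")

    members = [
        r for r in cohort if group is None or r.regimen == group
    ]
    member_ids = {r.primaryid for r in members}
    outside = member_ids - bg_ids
    if outside:
        raise ConsistencyError(
            f"{len(outside)} group report(s) missing from background"
        )
    a = sum(1 for r in members if r.is_target_event)
    b = len(members) - a
    bg_events = sum(1 for _, f in bg_pairs if f)
    c = bg_events - a
    d = len(bg_pairs) - len(members) - c
    if c < 0 or d < 0:
        raise ConsistencyError("group event counts exceed background counts")
    return ContingencyTable(a=a, b=b, c=c, d=d)


def compute_ror(
    table: ContingencyTable,
    z: float = DEFAULT_Z,
    haldane: bool = False,
) -> SignalResult:
    """Reporting odds ratio with its log-scale Wald confidence interval.

    ror = (a*d)/(b*c); ci = exp(ln ror +/- z*sqrt(1/a + 1/b + 1/c + 1/d)).
    A zero cell yields a non-estimable result unless ``haldane`` adds the
    +0.5 continuity correction.  The signal flag requires the interval's
    lower limit to exceed one with at least :data:`MIN_CASES` cases.
    """
    n_cases = table.a
    if haldane:
        a, b, c, d = table.with_haldane()
    else:
        a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) <= 0:
        return SignalResult(
            ror=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
            n_cases=n_cases,
            is_signal=False,
            z_quantile=z,
            estimable=False,
        )
    ror = (a * d) / (b * c)
    half_width = z * math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    ci_low = math.exp(math.log(ror) - half_width)
    ci_high = math.exp(math.log(ror) + half_width)
    return SignalResult(
        ror=ror,
        ci_low=ci_low,
        ci_high=ci_high,
        n_cases=n_cases,
        is_signal=bool(ci_low > 1.0 and n_cases >= MIN_CASES),
        z_quantile=z,
    )


def compare_groups(
    table_a: ContingencyTable,
    table_b: ContingencyTable,
    yates: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square comparing event proportions of two disjoint groups.

    Builds the 2x2 of (event, non-event) rows from the two groups' a/b
    cells; no continuity correction by default.  An expected cell below
    one attaches a warning flag rather than raising.
    """
    observed = [[table_a.a, table_a.b], [table_b.a, table_b.b]]
    row_sums = [sum(r) for r in observed]
    col_sums = [observed[0][j] + observed[1][j] for j in range(2)]
    total = sum(row_sums)
    if total == 0 or 0 in row_sums or 0 in col_sums:
        return ChiSquareResult(chi2=math.nan, p_value=math.nan, low_expected_warning=True)
    expected_min = min(
        row_sums[i] * col_sums[j] / total for i in range(2) for j in range(2)
    )
    chi2, p, dof, _ = stats.chi2_contingency(observed, correction=yates)
    return ChiSquareResult(
        chi2=float(chi2),
        p_value=float(p),
        dof=int(dof),
        low_expected_warning=bool(expected_min < 1.0),
    )


def signal_table(results: dict[str, tuple[ContingencyTable, SignalResult]]) -> pd.DataFrame:
    """Flatten per-group tables and results into a delimited-friendly frame."""
    rows = []
    for name, (t, r) in results.items():
        rows.append(
            {
                "group": name,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_cases": r.n_cases,
                "is_signal": r.is_signal,
                "estimable": r.estimable,
            }
        )
    return pd.DataFrame(rows)
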