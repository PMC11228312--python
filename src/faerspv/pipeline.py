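"""End-to-end orchestration: ingest -> dedup -> cohort -> signals -> summaries.

Produces a flow-count report for the filtering chain, the signal table,
subgroup chi-square comparisons, characteristics and onset summaries,
and a machine-readable run manifest sufficient to re-run bit-identically
in simulate mode.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .cohort import (
    DEFAULT_PRECEDENCE,
    CaseReport,
    DrugLexicon,
    RegimenClass,
    build_case_reports,
    select_index_reports,
    target_event_primaryids,
)
from .dedup import deduplicate, write_decision_log
from .descriptives import (
    SUBGROUP_ORDER,
    CohortSummary,
    OnsetSummary,
    compute_onsets,
    onset_bin_table,
    summarize_cohort,
    summarize_onset,
)
from .errors import ConfigurationError, StageError
from .faers_io import QuarterTables, read_quarters
from .signals import (
    DEFAULT_Z,
    ChiSquareResult,
    ContingencyTable,
    SignalResult,
    build_contingency,
    compare_groups,
    compute_ror,
    signal_table,
)
from .synthetic import SimulationConfig, generate

logger = logging.getLogger(__name__)

GROUP_LABELS = {
    None: "ALL_INDEX",
    RegimenClass.MONO: "MONO",
    RegimenClass.PLUS_CHEMO: "PLUS_CHEMO",
    RegimenClass.PLUS_ICI: "PLUS_ICI",
    RegimenClass.PLUS_TARGETED: "PLUS_TARGETED",
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; files XOR simulation as input."""

    output_dir: Union[str, Path]
    input_dir: Optional[Union[str, Path]] = None
    simulation: Optional[SimulationConfig] = None
    lexicon_path: Optional[Union[str, Path]] = None
    target_pts: Optional[Sequence[str]] = None
    precedence: Sequence[str] = DEFAULT_PRECEDENCE
    comedication_roles: Optional[Sequence[str]] = None
    yates: bool = False
    haldane: bool = False
    z_quantile: float = DEFAULT_Z
    counting_unit: str = "report"
    figures: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one input source required: input_dir XOR simulation"
            )
        if self.seed is not None and self.simulation is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)


@dataclass
class PipelineResult:
    flow: dict[str, int]
    signals: pd.DataFrame
    comparisons: pd.DataFrame
    cohort_summary: CohortSummary
    onset_summaries: dict[str, OnsetSummary]
    onset_bins: pd.DataFrame
    manifest: dict
    cohort: list[CaseReport] = field(default_factory=list)
    tables: Optional[QuarterTables] = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    lexicon = (
        DrugLexicon.from_yaml(config.lexicon_path)
        if config.lexicon_path
        else DrugLexicon.default()
    )
    target_pts = (
        list(config.target_pts) if config.target_pts else sorted(lexicon.target_pts)
    )
    if not target_pts:
        raise ConfigurationError("no target preferred terms configured")

    stage_log: list[dict] = []

    def _log(stage: str, n_in: int, n_out: int, t0: float) -> None:
        elapsed = time.perf_counter() - t0
        # manifest must be bit-identical across reruns: keep timings out of it
        stage_log.append({"stage": stage, "in": n_in, "out": n_out})
        logger.info("stage=%s in=%d out=%d elapsed=%.3fs", stage, n_in, n_out, elapsed)

    # --- ingest ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.simulation is not None:
            faers_dir = outdir / "faers"
            generate(config.simulation, faers_dir)
            tables = read_quarters(faers_dir)
        else:
            tables = read_quarters(config.input_dir)
    except Exception as exc:
        raise StageError(f"stage 'ingest' failed: {exc}") from exc
    rows_read = len(tables.demo)
    _log("ingest", rows_read, rows_read, t0)

    # --- dedup ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        dedup_result = deduplicate(tables.demo)
    except Exception as exc:
        raise StageError(f"stage 'dedup' failed: {exc}") from exc
    kept = dedup_result.kept_primaryids
    write_decision_log(dedup_result, outdir / "dedup_log.txt")
    _log("dedup", rows_read, len(kept), t0)

    # --- cohort ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        target_ids = target_event_primaryids(tables.reac, target_pts)
        index_ids = select_index_reports(tables.drug, lexicon, within=kept)
        cohort = build_case_reports(
            tables,
            index_ids,
            lexicon,
            target_pts=target_pts,
            precedence=config.precedence,
            roles=config.comedication_roles,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'cohort' failed: {exc}") from exc
    target_cohort = [r for r in cohort if r.is_target_event]
    _log("cohort", len(kept), len(cohort), t0)

    # --- signals --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        background = pd.DataFrame(
            {"primaryid": kept, "is_target_event": [p in target_ids for p in kept]}
        )
        results: dict[str, tuple[ContingencyTable, SignalResult]] = {}
        per_group_tables: dict[Optional[RegimenClass], ContingencyTable] = {}
        for group, label in GROUP_LABELS.items():
            table = build_contingency(cohort, group, background)
            per_group_tables[group] = table
            results[label] = (
                table,
                compute_ror(table, z=config.z_quantile, haldane=config.haldane),
            )
        signals = signal_table(results)
        comparisons = _compare_to_mono(per_group_tables, config.yates)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'signals' failed: {exc}") from exc
    _log("signals", len(cohort), len(signals), t0)

    # --- descriptives ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        summary = summarize_cohort(target_cohort, lexicon)
        onset_records = compute_onsets(target_cohort, lexicon)
        onset_summaries = {"Overall": summarize_onset(onset_records)}
        for rc in SUBGROUP_ORDER:
            onset_summaries[rc.value] = summarize_onset(onset_records, regimen=rc)
        bins = onset_bin_table(onset_records)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'descriptives' failed: {exc}") from exc
    _log("descriptives", len(target_cohort), len(onset_records), t0)

    flow = {
        "rows_read": rows_read,
        "after_dedup": len(kept),
        "index_reports": len(cohort),
        "target_event_reports": len(target_cohort),
    }
    for rc in SUBGROUP_ORDER:
        flow[f"regimen_{rc.value}"] = sum(
            1 for r in target_cohort if r.regimen == rc
        )

    manifest = {
        "package": "faerspv",
        "version": __version__,
        "seed": config.simulation.seed if config.simulation is not None else None,
        "config": _config_echo(config),
        "decisions": {
            "counting_unit": config.counting_unit,
            "regimen_precedence": list(config.precedence),
            "z_quantile": config.z_quantile,
            "chi_square_yates": config.yates,
            "haldane_correction": config.haldane,
            "quantile_rule": summary.quantile_rule,
        },
        "library_versions": _library_versions(),
        "stages": stage_log,
        "flow": flow,
    }

    result = PipelineResult(
        flow=flow,
        signals=signals,
        comparisons=comparisons,
        cohort_summary=summary,
        onset_summaries=onset_summaries,
        onset_bins=bins,
        manifest=manifest,
        cohort=cohort,
        tables=tables,
    )
    _write_outputs(result, outdir, config)
    return result


def _compare_to_mono(
    tables: dict[Optional[RegimenClass], ContingencyTable], yates: bool
) -> pd.DataFrame:
    mono = tables.get(RegimenClass.MONO)
    rows = []
    for rc in (RegimenClass.PLUS_CHEMO, RegimenClass.PLUS_ICI, RegimenClass.PLUS_TARGETED):
        res: ChiSquareResult = compare_groups(tables[rc], mono, yates=yates)
        rows.append(
            {
                "comparison": f"{rc.value}_vs_MONO",
                "chi2": res.chi2,
                "p_value": res.p_value,
                "dof": res.dof,
                "low_expected_warning": res.low_expected_warning,
            }
        )
    return pd.DataFrame(rows)


def _config_echo(config: RunConfig) -> dict:
    echo: dict = {
        "input_dir": str(config.input_dir) if config.input_dir else None,
        "output_dir": str(config.output_dir),
        "lexicon_path": str(config.lexicon_path) if config.lexicon_path else None,
        "target_pts": list(config.target_pts) if config.target_pts else None,
        "precedence": list(config.precedence),
        "comedication_roles": list(config.comedication_roles)
        if config.comedication_roles
        else None,
        "yates": config.yates,
        "haldane": config.haldane,
        "figures": config.figures,
    }
    if config.simulation is not None:
        sim = dataclasses.asdict(config.simulation)
        sim["group_specs"] = [dataclasses.asdict(g) for g in config.simulation.group_specs]
        echo["simulation"] = sim
    return echo


def _library_versions() -> dict:
    import numpy, pandas, scipy  # noqa: E401

    return {
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
    }


def _write_outputs(result: PipelineResult, outdir: Path, config: RunConfig) -> None:
    pd.DataFrame(
        [{"step": k, "count": v} for k, v in result.flow.items()]
    ).to_csv(outdir / "flow.tsv", sep="\t", index=False)
    result.signals.to_csv(outdir / "signals.tsv", sep="\t", index=False)
    result.comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)

    frames = []
    for characteristic, counts in result.cohort_summary.counts.items():
        pct = result.cohort_summary.percentages(characteristic)
        frame = counts.copy()
        frame.columns = [f"{c}_n" for c in frame.columns]
        for c in pct.columns:
            frame[f"{c}_pct"] = pct[c]
        frame.insert(0, "category", frame.index)
        frame.insert(0, "characteristic", characteristic)
        frames.append(frame.reset_index(drop=True))
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "cohort_summary.tsv", sep="\t", index=False
    )

    onset_rows = []
    cdf_rows = []
    for label, s in result.onset_summaries.items():
        onset_rows.append(
            {
                "group": label,
                "n_used": s.n_used,
                "median_days": s.median_days,
                "q1_days": s.q1_days,
                "q3_days": s.q3_days,
            }
        )
        for day, frac in s.cumulative_curve:
            cdf_rows.append({"group": label, "days": day, "cumulative_fraction": frac})
    pd.DataFrame(
        onset_rows, columns=["group", "n_used", "median_days", "q1_days", "q3_days"]
    ).to_csv(outdir / "onset_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        cdf_rows, columns=["group", "days", "cumulative_fraction"]
    ).to_csv(outdir / "onset_cdf.tsv", sep="\t", index=False)
    result.onset_bins.to_csv(outdir / "onset_bins.tsv", sep="\t", index=False)

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if config.figures:
        from . import plots

        plots.forest_plot(result.signals, outdir / "forest.png")
        plots.onset_cdf_plot(result.onset_summaries, outdir / "onset_cdf.png")
        plots.outcome_bars(result.cohort_summary, outdir / "outcome_bars.png")
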