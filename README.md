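# faerspv

Pharmacovigilance signal detection for FAERS-format quarterly files.

The package implements a complete spontaneous-reporting-system analysis
pipeline for an index drug (by default bevacizumab/Avastin) and a target
adverse-event preferred-term set (by default *Pulmonary haemorrhage* and
*Haemoptysis*):

1. **Ingestion** (`faerspv.faers_io`) — reads the `$`-delimited FAERS
   quarterly ASCII dialect (DEMO/DRUG/REAC/THER/OUTC/INDI, RPSR read but
   ignored), with case-insensitive headers, legacy column aliases,
   structured partial dates, and explicit malformed-row accounting.
2. **Deduplication** (`faerspv.dedup`) — per CASEID keep the record with
   the latest FDA_DT, ties broken by the higher PRIMARYID (numeric when
   possible), with an audit log of every decision.
3. **Cohort building** (`faerspv.cohort`) — selects reports naming the
   index drug (exact match on normalized names; biosimilar deny-list),
   classifies each into a mutually exclusive regimen subgroup
   (monotherapy / plus-chemotherapy / plus-ICI / plus-targeted) via a
   packaged drug lexicon and a configurable category precedence, and
   flags target-event reports.
4. **Signal statistics** (`faerspv.signals`) — 2×2 contingency tables
   against the full deduplicated background, reporting odds ratios with
   the log-scale Wald 95% CI (`exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`),
   the positive-signal rule (CI lower limit > 1 with ≥ 3 cases), and
   Pearson chi-square subgroup comparisons.
5. **Time-to-onset & descriptives** (`faerspv.descriptives`) — calendar
   days from the earliest fully dated index-therapy start to the event
   date (partial/missing dates and event-before-start excluded with
   recorded reasons), median/IQR, empirical CDF, day-range bins, and a
   characteristics table (gender, reporting-year bins, indications,
   outcomes, countries, reporters) with per-subgroup percentages.
6. **Synthetic FAERS generator** (`faerspv.synthetic`) — produces
   quarterly file sets with a known ground-truth association structure
   (per-group odds multipliers, log-normal onset, injected duplicates,
   partial/missing dates, free-text drug-name noise), byte-deterministic
   given a seed, so the whole pipeline is testable without a download.

## Command line

```sh
# write a synthetic quarterly file set
faerspv simulate -o data/sim --n-reports 5000 --seed 1

# validate and count an existing file set
faerspv ingest -i data/sim

# run the analysis on files
faerspv analyze -i data/sim -o results/run --figures

# simulate + analyze in one go
faerspv all --n-reports 5000 --seed 1 -o results/run

# re-render figures from a completed run
faerspv report -o results/run
```

`analyze`/`all` write under the output directory: `flow.tsv` (filtering
chain counts), `signals.tsv`, `comparisons.tsv` (chi-square vs
monotherapy), `cohort_summary.tsv`, `onset_summary.tsv`,
`onset_cdf.tsv`, `onset_bins.tsv`, `dedup_log.txt`, and `manifest.json`
(config echo, seed, decisions in effect, stage log — sufficient to
re-run bit-identically in simulate mode).  Simulation parameters can be
given as a YAML file (`-c`), with command-line flags taking precedence;
the drug lexicon / vocabularies are YAML as well (`--lexicon`, see
`src/faerspv/data/default_lexicon.yaml` for the packaged default).

## Analysis conventions

- Counting unit is the unique deduplicated report, for both the drug
  group and background cells.
- The normal quantile is fixed at 1.96 (not the exact 97.5% quantile).
- Zero cells make a ROR non-estimable by default; Haldane +0.5 is
  available behind a flag.
- Regimen precedence when categories co-occur is
  chemotherapy > ICI > targeted (configurable, echoed in the manifest).
- Quartiles use linear interpolation between order statistics (type 7).
- Reporting year is taken from the FDA receipt date (FDA_DT).
- Only PRIMARYID-era FAERS schemas are supported (no legacy ISR files).
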