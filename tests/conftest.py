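from __future__ import annotations

import pytest

from faerspv.cohort import DrugLexicon
from faerspv.pipeline import RunConfig, run_pipeline
from faerspv.synthetic import example_config, generate


@pytest.fixture(scope="session")
def lexicon() -> DrugLexicon:
    return DrugLexicon.default()


@pytest.fixture(scope="session")
def sim_config():
    # high index prevalence / event rate so every stage sees real counts
    return example_config(
        n_reports=2000,
        seed=20240101,
        baseline_event_prob=0.03,
        duplicate_rate=0.1,
        partial_date_rate=0.1,
        missing_event_date_rate=0.1,
    )


@pytest.fixture(scope="session")
def generated(tmp_path_factory, sim_config):
    """One shared synthetic quarterly file set: (root dir, quarter dirs, truth)."""
    root = tmp_path_factory.mktemp("faers")
    dirs, truth = generate(sim_config, root)
    return root, dirs, truth


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory, sim_config):
    out = tmp_path_factory.mktemp("run")
    return run_pipeline(RunConfig(output_dir=out, simulation=sim_config)), out
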