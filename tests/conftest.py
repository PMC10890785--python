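import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.helpers

from fusionatlas.fusion_classify import classify_all, filter_candidates, resolve_models
from fusionatlas.io_formats import read_annotation, read_genome
from fusionatlas.synthetic_data import (
    SimulationConfig,
    simulate_expression,
    simulate_fusions,
    simulate_genome_annotation,
)


@pytest.fixture(scope="session")
def sim_cfg() -> SimulationConfig:
    return SimulationConfig(seed=101)


@pytest.fixture(scope="session")
def sim_genome(sim_cfg, tmp_path_factory):
    return simulate_genome_annotation(sim_cfg, tmp_path_factory.mktemp("sim"))


@pytest.fixture(scope="session")
def genome(sim_genome):
    return read_genome(sim_genome.fasta_path)


@pytest.fixture(scope="session")
def models(sim_genome):
    return read_annotation(sim_genome.gtf_path)


@pytest.fixture(scope="session")
def resolved(models):
    return resolve_models(models)


@pytest.fixture(scope="session")
def fusion_data(sim_cfg, sim_genome, genome):
    """(calls, truth) for the default stage-series simulation."""
    return simulate_fusions(sim_cfg, sim_genome, genome)


@pytest.fixture(scope="session")
def classified(fusion_data, resolved, genome):
    calls, _ = fusion_data
    return classify_all(filter_candidates(calls), resolved, genome)


@pytest.fixture(scope="session")
def expression_data(sim_cfg, fusion_data):
    """(libraries, parent_counts, truth) for the default simulation."""
    calls, _ = fusion_data
    return simulate_expression(sim_cfg, calls)
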