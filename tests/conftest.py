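"""Shared end-to-end simulation fixtures.

The expensive simulations (20-30 kb genomes) are built once per session and
shared between the module-level invariant tests and the acceptance suite.
"""

from dataclasses import dataclass
from typing import List

import pytest
from hypothesis import settings

from cloverasm.pipeline import PipelineResult, RunConfig, assemble
from cloverasm.read_io import LibrarySpec, ReadRecord
from cloverasm.simulate import (
    SimConfig,
    censor_pairs,
    pairs_to_records,
    random_genome,
    simulate_pair_records,
)

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@dataclass
class Scenario:
    genome: str
    reads: List[ReadRecord]
    sim: SimConfig
    result: PipelineResult = None
    result_alt: PipelineResult = None


@pytest.fixture(scope="session")
def errorfree_20kb():
    """Repeat-free 20 kb genome, 100 bp error-free pairs at 30x, k=31, p=0."""
    sim = SimConfig(genome_length=20_000, read_length=100, coverage=30,
                    error_rate=0.0, insert_mean=300, insert_sd=30, seed=7)
    genome = random_genome(sim)
    reads = pairs_to_records(simulate_pair_records(genome, sim))
    result = assemble(reads, RunConfig(k=31, p=0, cs=0, ss=5))
    return Scenario(genome, reads, sim, result)


@pytest.fixture(scope="session")
def noisy_20kb():
    """The same genome scale with 1% substitution errors, assembled with
    k=21 at both p=0 and p=1 (sp=0.6, cs=5)."""
    sim = SimConfig(genome_length=20_000, read_length=100, coverage=30,
                    error_rate=0.01, insert_mean=300, insert_sd=30, seed=7)
    genome = random_genome(sim)
    reads = pairs_to_records(simulate_pair_records(genome, sim))
    scenario = Scenario(genome, reads, sim)
    scenario.result = assemble(reads, RunConfig(k=21, p=1, sp=0.6, cs=5, ss=5))
    scenario.result_alt = assemble(reads, RunConfig(k=21, p=0, sp=0.6, cs=5, ss=5))
    return scenario


GAP_INTERVALS = [(10_000, 10_300), (20_300, 20_600)]


@pytest.fixture(scope="session")
def three_segment_scaffold():
    """Three 10 kb segments with two 300 bp uncovered gaps; insert 500+-30.

    Reads overlapping a gap are censored so the gaps cannot assemble, but
    gap-spanning pairs remain for the scaffolder (ss=5).
    """
    sim = SimConfig(genome_length=30_600, read_length=50, coverage=50,
                    error_rate=0.0, insert_mean=500, insert_sd=30, seed=11)
    genome = random_genome(sim)
    pairs = censor_pairs(simulate_pair_records(genome, sim), GAP_INTERVALS,
                         sim.read_length)
    reads = pairs_to_records(pairs)
    lib = LibrarySpec("mate1.fastq", "mate2.fastq", insert_size=500)
    result = assemble(reads, RunConfig(k=31, p=0, cs=0, ss=5, libraries=[lib]))
    return Scenario(genome, reads, sim, result)
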