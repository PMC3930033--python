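from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from genomescreen import (
    LaneRecipe,
    ReferenceGenome,
    SamplingPlan,
    build_panel,
    default_adapters,
    demo_panel,
    sample_fastq,
    simulate_genome,
    simulate_lane,
)


@pytest.fixture(scope="session")
def small_panel():
    """Three disjoint random genomes: target, contaminant, control."""
    panel = build_panel([
        simulate_genome(20_000, 101, "human"),
        simulate_genome(20_000, 102, "mouse"),
        simulate_genome(5_000, 103, "phix", is_control=True),
    ])
    panel.build_indexes(12)
    return panel


@pytest.fixture(scope="session")
def session_demo_panel():
    panel = demo_panel(seed=0, genome_length=20_000)
    panel.build_indexes(12)
    return panel


@pytest.fixture(scope="session")
def adapters():
    return default_adapters()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(seq: str, positions: list[int]) -> str:
    """Substitute at the given positions (always to a different base)."""
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


def screened_lane(panel, adapters, recipe: LaneRecipe, tmp_path: Path,
                  sample_size: int, seed: int = 1, dataset_id: str = "lane"):
    """Simulate a lane and sample it back; returns (reads, truth)."""
    fq = tmp_path / f"{dataset_id}.fastq.gz"
    truth = simulate_lane(recipe, panel, adapters, fq, None)
    plan = SamplingPlan(sample_size=sample_size, trim_length=36, seed=seed)
    reads = sample_fastq([fq], plan, dataset_id=dataset_id)
    return reads, truth
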