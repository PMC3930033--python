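"""Synthetic genomes, adapters, and contaminated lanes with ground truth.

Everything the screen consumes can be generated here at desk scale:
random reference genomes (optionally with a homologous region copied
between two genomes, to exercise rank-based assignment), a spike-in
control genome, and FASTQ lanes mixed from several origins at stated
fractions with per-base substitution noise and 3' adapter read-through.
Each simulated lane comes with a truth table recording every read's
origin unit, whether it carries adapter, and how many substitutions fell
in its first 36 bases — the ground truth the tests compare against.

The error model is substitution-only (no indels), matching the ungapped
species aligner; quality strings are constant Phred 37 because the
screen carries qualities through but does not use them computationally.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel import AdapterSet, ReferenceGenome, ReferencePanel, build_panel

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
RANDOM_ORIGIN = "random"
# Illumina TruSeq universal adapter, the standard 3' read-through sequence
TRUSEQ_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
DEFAULT_QUALITY_CHAR = chr(37 + 33)  # constant Phred 37


@dataclass(frozen=True)
class LaneRecipe:
    """Composition of one simulated lane.

    ``fractions`` maps origin unit ids (plus optionally ``"random"`` for
    unmappable sequence) to proportions summing to 1. A fraction
    ``adapter_readthrough_fraction`` of reads, drawn from any origin
    class, is built as a short genomic fragment followed by adapter
    sequence so that at least ``min_readthrough`` adapter bases fall
    inside the read.
    """

    fractions: dict[str, float]
    total_reads: int = 10_000
    read_length: int = 100
    substitution_rate: float = 0.0
    adapter_readthrough_fraction: float = 0.0
    min_readthrough: int = 16
    seed: int = 0

    def __post_init__(self):
        total = sum(self.fractions.values())
        if any(f < 0 or f > 1 for f in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        if self.read_length < 36:
            raise ValueError("read_length must be at least 36")


@dataclass
class TruthRecord:
    read_id: str
    origin_unit: str
    had_adapter: bool
    n_substitutions_in_first_36: int


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def simulate_genome(
    length: int, seed: int, genome_id: str = "genome", **kwargs
) -> ReferenceGenome:
    """Uniform random A/C/G/T genome of exactly *length* bases."""
    if length < 1000:
        raise ValueError("genome length must be at least 1000 bases")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, length)
    kwargs.setdefault("display_name", genome_id)
    return ReferenceGenome(
        genome_id=genome_id, sequences=[(f"{genome_id}_1", seq)], **kwargs
    )


def simulate_homolog(
    parent: ReferenceGenome,
    shared_span: int,
    seed: int,
    genome_id: str = "homolog",
    **kwargs,
) -> tuple[ReferenceGenome, tuple[int, int]]:
    """Genome sharing a copied span with *parent*, novel random flanks.

    The copied span is taken from the middle of the parent's first
    sequence and placed between two random flanks of equal total length,
    so the child genome has the same length as the parent. Returns the
    child and the (start, end) interval of the shared span *within the
    child*, as ground truth for homology-resolution tests.
    """
    parent_seq = parent.sequences[0][1]
    if shared_span >= len(parent_seq):
        raise ValueError("shared_span must be shorter than the parent sequence")
    rng = np.random.default_rng(seed)
    src_start = (len(parent_seq) - shared_span) // 2
    shared = parent_seq[src_start : src_start + shared_span]
    flank_total = len(parent_seq) - shared_span
    left = flank_total // 2
    child_seq = (
        _random_sequence(rng, left)
        + shared
        + _random_sequence(rng, flank_total - left)
    )
    kwargs.setdefault("display_name", genome_id)
    child = ReferenceGenome(
        genome_id=genome_id, sequences=[(f"{genome_id}_1", child_seq)], **kwargs
    )
    return child, (left, left + shared_span)


def default_adapters() -> AdapterSet:
    return AdapterSet([("truseq_adapter", TRUSEQ_ADAPTER)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Apply per-base substitutions at *rate*; returns (sequence, count in
    first 36 bases). Substitutions always change the base."""
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        choices = BASES[BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    n36 = int(np.sum(hits < 36))
    return arr.tobytes().decode("ascii"), n36


def simulate_lane(
    recipe: LaneRecipe,
    panel: ReferencePanel,
    adapters: AdapterSet,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
) -> list[TruthRecord]:
    """Write a FASTQ lane mixed per *recipe*, plus its truth table.

    Reads are drawn uniformly from the member genomes of each origin unit
    at the recipe fractions (``"random"`` produces unmappable sequence),
    substitution noise is applied at the stated per-base rate, and the
    adapter-read-through fraction of reads is built as fragment + adapter
    suffix. Returns the truth records; writes them as TSV if
    ``truth_path`` is given.
    """
    for unit_id in recipe.fractions:
        if unit_id != RANDOM_ORIGIN and unit_id not in panel.units:
            raise ValueError(f"recipe names unknown unit {unit_id!r}")
    rng = np.random.default_rng(recipe.seed)
    origins = sorted(recipe.fractions)
    probs = np.array([recipe.fractions[o] for o in origins])
    origin_draws = rng.choice(len(origins), size=recipe.total_reads, p=probs)
    adapter_seqs = [seq for _, seq in adapters.adapters]
    L = recipe.read_length
    truth: list[TruthRecord] = []
    fastq_path = Path(fastq_path)
    opener = gzip.open if fastq_path.suffix == ".gz" else open
    with opener(fastq_path, "wt") as fq:
        for i, origin_idx in enumerate(origin_draws):
            origin = origins[origin_idx]
            read_id = f"sim_{i:06d}"
            has_adapter = (
                recipe.adapter_readthrough_fraction > 0
                and rng.random() < recipe.adapter_readthrough_fraction
            )
            if has_adapter:
                # fragment short enough that >= min_readthrough adapter
                # bases land inside the read (all within the first 36)
                frag_len = int(rng.integers(0, 36 - recipe.min_readthrough + 1))
            else:
                frag_len = L
            if origin == RANDOM_ORIGIN:
                fragment = _random_sequence(rng, frag_len)
            else:
                unit = panel.units[origin]
                genome = panel.genomes[
                    unit.member_genomes[rng.integers(0, len(unit.member_genomes))]
                ]
                seq_id, seq = genome.sequences[
                    rng.integers(0, len(genome.sequences))
                ]
                start = int(rng.integers(0, len(seq) - frag_len + 1))
                fragment = seq[start : start + frag_len]
            if has_adapter:
                suffix = ""
                while len(fragment) + len(suffix) < L:
                    suffix += adapter_seqs[
                        int(rng.integers(0, len(adapter_seqs)))
                    ]
                read_seq = (fragment + suffix)[:L]
            else:
                read_seq = fragment
            read_seq, n36 = _mutate(read_seq, recipe.substitution_rate, rng)
            fq.write(
                f"@{read_id}\n{read_seq}\n+\n{DEFAULT_QUALITY_CHAR * len(read_seq)}\n"
            )
            truth.append(TruthRecord(read_id, origin, has_adapter, n36))
    if truth_path is not None:
        with open(truth_path, "w") as th:
            th.write("read_id\torigin_unit\thad_adapter\tn_substitutions_in_first_36\n")
            for rec in truth:
                th.write(
                    f"{rec.read_id}\t{rec.origin_unit}\t"
                    f"{int(rec.had_adapter)}\t{rec.n_substitutions_in_first_36}\n"
                )
    return truth


def demo_panel(seed: int = 0, genome_length: int = 50_000) -> ReferencePanel:
    """Four-genome demo panel: target, contaminant, a pooled two-genome
    bacterial collection, and a spike-in control."""
    genomes = [
        simulate_genome(genome_length, seed + 1, "human", display_name="Human"),
        simulate_genome(genome_length, seed + 2, "mouse", display_name="Mouse"),
        simulate_genome(
            genome_length // 10, seed + 3, "ecoli",
            display_name="E. coli", collection_id="bacteria",
        ),
        simulate_genome(
            genome_length // 10, seed + 4, "bsubtilis",
            display_name="B. subtilis", collection_id="bacteria",
        ),
        simulate_genome(
            max(1000, genome_length // 10), seed + 5, "phix",
            display_name="PhiX control", is_control=True,
        ),
    ]
    return build_panel(genomes)
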