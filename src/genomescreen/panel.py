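"""Reference panel: genomes, reporting units, adapters, and k-mer indexing.

The screen aligns sampled reads against a configurable panel of reference
genomes. Genomes may be grouped into *collections* (e.g. a pooled set of
bacterial references) that are indexed per member genome but counted and
reported as a single *reporting unit*. One genome may be flagged as the
sequencing spike-in control (typically phi X 174), which the report
distinguishes from targets and contaminants.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import yaml
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


class PanelError(ValueError):
    """Fatal problem in the panel configuration or its FASTA files."""


@dataclass
class ReferenceGenome:
    """A reference genome: one or more DNA sequences plus panel metadata."""

    genome_id: str
    display_name: str
    sequences: list[tuple[str, str]]
    collection_id: str | None = None
    is_control: bool = False

    def __post_init__(self) -> None:
        cleaned = []
        for seq_id, seq in self.sequences:
            seq = seq.upper()
            if not seq:
                raise PanelError(
                    f"genome {self.genome_id!r}: sequence {seq_id!r} is empty"
                )
            bad = set(seq) - VALID_BASES
            if bad:
                raise PanelError(
                    f"genome {self.genome_id!r}: sequence {seq_id!r} contains "
                    f"invalid characters {sorted(bad)}"
                )
            cleaned.append((seq_id, seq))
        self.sequences = cleaned

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.sequences)


@dataclass(frozen=True)
class ReportingUnit:
    """A single genome or a pooled collection reported as one entity.

    Roles (target / control / other) are assigned per dataset at screen
    time, never stored here.
    """

    unit_id: str
    member_genomes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_genomes:
            raise PanelError(f"reporting unit {self.unit_id!r} has no members")


@dataclass
class AdapterSet:
    """Adapter and primer sequences screened against every sampled read."""

    adapters: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        cleaned = []
        for adapter_id, seq in self.adapters:
            if adapter_id in seen:
                raise PanelError(f"duplicate adapter id {adapter_id!r}")
            seen.add(adapter_id)
            seq = seq.upper()
            if len(seq) < 8:
                raise PanelError(
                    f"adapter {adapter_id!r} is shorter than 8 bases"
                )
            cleaned.append((adapter_id, seq))
        self.adapters = cleaned

    def __len__(self) -> int:
        return len(self.adapters)


class KmerIndex:
    """Exact k-mer postings for one genome (forward strand only).

    Every N-free window of length ``k`` of every sequence appears exactly
    once at its 0-based offset. Queries are matched on both strands by
    reverse-complementing the query, so only the forward strand is stored.
    """

    def __init__(self, genome_id: str, k: int):
        self.genome_id = genome_id
        self.k = k
        self.postings: dict[str, list[tuple[str, int]]] = {}

    def add_sequence(self, seq_id: str, seq: str) -> None:
        k = self.k
        postings = self.postings
        # track the most recent N so windows overlapping it are skipped
        last_n = -1
        for i, base in enumerate(seq):
            if base == "N":
                last_n = i
            start = i - k + 1
            if start < 0 or last_n >= start:
                continue
            postings.setdefault(seq[start : i + 1], []).append((seq_id, start))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.postings.get(kmer, [])

    def __len__(self) -> int:
        return len(self.postings)


def build_index(genome: ReferenceGenome, k: int = 12) -> KmerIndex:
    """Index every N-free k-mer of *genome* at its offset.

    ``k`` must be at least 8 and no longer than the read trim length used
    for screening; a ``k`` exceeding every sequence in the genome is fatal.
    """
    if k < 8:
        raise PanelError(f"seed length k={k} is below the minimum of 8")
    if all(len(seq) < k for _, seq in genome.sequences):
        raise PanelError(
            f"genome {genome.genome_id!r}: seed length k={k} exceeds every sequence"
        )
    index = KmerIndex(genome.genome_id, k)
    for seq_id, seq in genome.sequences:
        index.add_sequence(seq_id, seq)
    return index


@dataclass
class ReferencePanel:
    """Validated set of reference genomes with their reporting units."""

    genomes: dict[str, ReferenceGenome]
    units: dict[str, ReportingUnit]
    indexes: dict[str, KmerIndex] = field(default_factory=dict)

    @property
    def control_units(self) -> list[str]:
        return [
            u.unit_id
            for u in self.units.values()
            if any(self.genomes[g].is_control for g in u.member_genomes)
        ]

    def unit_of_genome(self, genome_id: str) -> str:
        g = self.genomes[genome_id]
        return g.collection_id if g.collection_id else g.genome_id

    def build_indexes(self, k: int = 12) -> None:
        for genome_id, genome in self.genomes.items():
            self.indexes[genome_id] = build_index(genome, k)


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record id, uppercase sequence) from a FASTA file (gzip allowed)."""
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            yield record.id, str(record.seq).upper()


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def load_adapters(path: str | Path) -> AdapterSet:
    """Load adapter/primer sequences from FASTA."""
    adapters = list(read_fasta(path))
    if not adapters:
        raise PanelError(f"adapter FASTA {path} contains no sequences")
    return AdapterSet(adapters)


def build_panel(genomes: list[ReferenceGenome]) -> ReferencePanel:
    """Assemble a panel from in-memory genomes, grouping collections."""
    if not genomes:
        raise PanelError("empty panel: no genomes supplied")
    by_id: dict[str, ReferenceGenome] = {}
    for g in genomes:
        if g.genome_id in by_id:
            raise PanelError(f"duplicate genome_id {g.genome_id!r}")
        by_id[g.genome_id] = g
    members: dict[str, list[str]] = {}
    for g in genomes:
        unit_id = g.collection_id if g.collection_id else g.genome_id
        members.setdefault(unit_id, []).append(g.genome_id)
    units = {
        unit_id: ReportingUnit(unit_id, tuple(sorted(ids)))
        for unit_id, ids in members.items()
    }
    return ReferencePanel(genomes=by_id, units=units)


def load_panel(panel_config: str | Path) -> ReferencePanel:
    """Load and validate a reference panel from a YAML config.

    The config holds a ``genomes`` list with per-genome entries
    ``{id, name, fasta, collection (optional), control (optional)}``.
    FASTA paths are resolved relative to the config file. Genomes sharing
    a ``collection`` merge into one reporting unit.
    """
    config_path = Path(panel_config)
    if not config_path.exists():
        raise PanelError(f"panel config not found: {config_path}")
    with open(config_path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict) or not config.get("genomes"):
        raise PanelError(f"panel config {config_path} declares no genomes")
    base = config_path.parent
    genomes = []
    for entry in config["genomes"]:
        fasta = Path(entry["fasta"])
        if not fasta.is_absolute():
            fasta = base / fasta
        if not fasta.exists():
            raise PanelError(
                f"genome {entry.get('id', '?')!r}: FASTA file not found: {fasta}"
            )
        genomes.append(
            ReferenceGenome(
                genome_id=str(entry["id"]),
                display_name=str(entry.get("name", entry["id"])),
                sequences=list(read_fasta(fasta)),
                collection_id=entry.get("collection"),
                is_control=bool(entry.get("control", False)),
            )
        )
    panel = build_panel(genomes)
    if len(panel.control_units) > 1:
        raise PanelError(
            f"panel flags more than one control unit: {panel.control_units}"
        )
    return panel
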