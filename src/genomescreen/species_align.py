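"""Ungapped read-to-genome alignment, seeded by exact k-mers.

Each trimmed read is placed end-to-end (no gaps) on every reference
genome, on both strands, and accepted when its minimum mismatch
(Hamming) count over all reachable placements is at most
``max_mismatches``. Placements are found by exact k-mer seeds: with the
default trim length of 36 and seed length k=12, partitioning the read
into 36/12 = 3 non-overlapping seeds guarantees by pigeonhole that any
placement with at most 2 mismatches contains at least one exact seed, so
seeding loses no qualifying alignment. An N in the read or the reference
always counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panel import KmerIndex, ReferenceGenome, ReferencePanel
from .sampling import SampledRead

DEFAULT_MAX_MISMATCHES = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadAlignment:
    """Best alignment of one read to one reporting unit."""

    read_id: str
    unit_id: str
    best_mismatches: int
    aligned_length: int


@dataclass
class SpeciesAlignmentSet:
    """All (read, reporting unit) alignments for one dataset."""

    dataset_id: str
    alignments: list[ReadAlignment]
    sampled_count: int
    max_mismatches: int

    def by_read(self) -> dict[str, list[ReadAlignment]]:
        grouped: dict[str, list[ReadAlignment]] = {}
        for aln in self.alignments:
            grouped.setdefault(aln.read_id, []).append(aln)
        return grouped

    def unit_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for aln in self.alignments:
            counts[aln.unit_id] = counts.get(aln.unit_id, 0) + 1
        return counts


def _seed_offsets(read_len: int, k: int) -> list[int]:
    """Non-overlapping k-windows covering the read, plus the tail window."""
    offsets = list(range(0, read_len - k + 1, k))
    tail = read_len - k
    if tail not in offsets:
        offsets.append(tail)
    return offsets


def _mismatches(query: str, ref: str, start: int, limit: int) -> int:
    """Hamming distance of query vs ref[start:start+len(query)], early exit
    past ``limit``; N on either side is a mismatch."""
    count = 0
    for i, q in enumerate(query):
        r = ref[start + i]
        if q != r or q == "N":
            count += 1
            if count > limit:
                return count
    return count


def align_read(
    read: SampledRead,
    genome: ReferenceGenome,
    index: KmerIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> tuple[int, int] | None:
    """Best ungapped end-to-end placement of *read* on *genome*.

    Returns ``(best_mismatches, aligned_length)`` for the minimum-Hamming
    placement over both strands reachable via at least one exact k-mer
    seed, or None if no placement has at most ``max_mismatches``
    mismatches. Non-alignment is a normal outcome, not an error.
    """
    k = index.k
    query = read.bases
    if len(query) < k:
        return None
    seqs = dict(genome.sequences)
    best: int | None = None
    offsets = _seed_offsets(len(query), k)
    for oriented in (query, reverse_complement(query)):
        seen: set[tuple[str, int]] = set()
        for seed_off in offsets:
            seed = oriented[seed_off : seed_off + k]
            if "N" in seed:
                continue
            for seq_id, hit_off in index.lookup(seed):
                start = hit_off - seed_off
                if start < 0:
                    continue
                placement = (seq_id, start)
                if placement in seen:
                    continue
                seen.add(placement)
                ref = seqs[seq_id]
                if start + len(oriented) > len(ref):
                    continue
                mm = _mismatches(oriented, ref, start, max_mismatches)
                if mm <= max_mismatches and (best is None or mm < best):
                    best = mm
                    if best == 0:
                        return 0, len(query)
    if best is None:
        return None
    return best, len(query)


def align_sample(
    reads: list[SampledRead],
    panel: ReferencePanel,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    dataset_id: str | None = None,
) -> SpeciesAlignmentSet:
    """Align every read to every reporting unit of the panel.

    For each (read, unit) pair, at most one ReadAlignment is kept: the
    minimum mismatch count over all member genomes of the unit. Reads
    aligning to no unit contribute to the unmapped tally implicitly
    (``sampled_count`` minus distinct aligned read ids).
    """
    if not panel.indexes:
        panel.build_indexes()
    if dataset_id is None:
        dataset_id = reads[0].dataset_id if reads else "dataset"
    alignments: list[ReadAlignment] = []
    unit_members = [
        (unit_id, [panel.genomes[g] for g in unit.member_genomes])
        for unit_id, unit in sorted(panel.units.items())
    ]
    for read in reads:
        for unit_id, members in unit_members:
            unit_best: tuple[int, int] | None = None
            for genome in members:
                result = align_read(
                    read, genome, panel.indexes[genome.genome_id], max_mismatches
                )
                if result is not None and (
                    unit_best is None or result[0] < unit_best[0]
                ):
                    unit_best = result
                    if unit_best[0] == 0:
                        break
            if unit_best is not None:
                alignments.append(
                    ReadAlignment(read.read_id, unit_id, unit_best[0], unit_best[1])
                )
    return SpeciesAlignmentSet(
        dataset_id=dataset_id,
        alignments=alignments,
        sampled_count=len(reads),
        max_mismatches=max_mismatches,
    )


def export_alignments(alignment_set: SpeciesAlignmentSet, path) -> None:
    """Write alignments as a tab-separated audit table."""
    with open(path, "w") as handle:
        handle.write("read_id\tunit_id\tmismatches\n")
        for aln in alignment_set.alignments:
            handle.write(f"{aln.read_id}\t{aln.unit_id}\t{aln.best_mismatches}\n")
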