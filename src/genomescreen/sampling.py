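"""Read sampling and trimming.

A fixed-size sample of reads is drawn uniformly without replacement from
one or more FASTQ files (single-pass reservoir sampling, seeded for
reproducibility) and trimmed to a fixed screening length from the 5' end.
Trimming makes results comparable across runs of different read lengths
and keeps 3' adapter read-through visible within the screened bases.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_SAMPLE_SIZE = 100_000
DEFAULT_TRIM_LENGTH = 36
# Phred+33 printable range
_QUAL_MIN, _QUAL_MAX = 33, 126


class FastqError(ValueError):
    """Malformed FASTQ input."""


@dataclass(frozen=True)
class SampledRead:
    """A sampled, trimmed read with its per-base Phred qualities."""

    read_id: str
    bases: str
    qualities: tuple[int, ...]
    dataset_id: str
    original_length: int

    def __post_init__(self):
        if len(self.bases) != len(self.qualities):
            raise FastqError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )


@dataclass(frozen=True)
class SamplingPlan:
    """How many reads to sample, the trim length, and the sampling seed."""

    sample_size: int = DEFAULT_SAMPLE_SIZE
    trim_length: int = DEFAULT_TRIM_LENGTH
    seed: int = 0

    def __post_init__(self):
        if self.sample_size < 1:
            raise ValueError("sample_size must be at least 1")
        if self.trim_length < 8:
            raise ValueError("trim_length must be at least the seed length")


def trim_read(read: SampledRead, trim_length: int) -> SampledRead:
    """Truncate bases and qualities to the first ``trim_length`` positions.

    Reads already shorter pass through unchanged (their full length is
    used for alignment); ``original_length`` is preserved. Idempotent.
    """
    if len(read.bases) <= trim_length:
        return read
    return replace(
        read,
        bases=read.bases[:trim_length],
        qualities=read.qualities[:trim_length],
    )


def _open_fastq(path: str | Path) -> IO[str]:
    path = Path(path)
    if not path.exists():
        raise FastqError(f"FASTQ file not found: {path}")
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality string), with record-numbered errors."""
    record_no = 0
    with _open_fastq(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                record_no += 1
                if len(seq) != len(qual):
                    raise FastqError(
                        f"{path}: record {record_no}: sequence length "
                        f"{len(seq)} != quality length {len(qual)}"
                    )
                yield title, seq, qual
        except ValueError as exc:
            if isinstance(exc, FastqError):
                raise
            raise FastqError(
                f"{path}: malformed FASTQ at record {record_no + 1}: {exc}"
            ) from exc


def _decode_qualities(qual: str, read_id: str) -> tuple[int, ...]:
    scores = []
    for ch in qual:
        code = ord(ch)
        if code < _QUAL_MIN or code > _QUAL_MAX:
            raise FastqError(
                f"read {read_id!r}: quality character {ch!r} outside the "
                "Phred+33 printable range"
            )
        scores.append(code - _QUAL_MIN)
    return tuple(scores)


def sample_fastq(
    files: Iterable[str | Path],
    plan: SamplingPlan,
    dataset_id: str = "dataset",
) -> list[SampledRead]:
    """Draw a uniform sample of reads across all supplied FASTQ files.

    Single-pass reservoir sampling without replacement: every read in the
    input has equal probability of inclusion regardless of file order or
    position, and the result is deterministic for a fixed seed. Returns
    ``min(sample_size, total reads)`` reads, trimmed to ``plan.trim_length``.
    Sampled reads are returned in their order of appearance in the input.
    """
    files = list(files)
    if not files:
        raise FastqError("no FASTQ files supplied")
    rng = np.random.default_rng(plan.seed)
    n = plan.sample_size
    reservoir: list[tuple[int, str, str, str]] = []
    total = 0
    for path in files:
        for title, seq, qual in _iter_fastq(path):
            if total < n:
                reservoir.append((total, title, seq, qual))
            else:
                j = int(rng.integers(0, total + 1))
                if j < n:
                    reservoir[j] = (total, title, seq, qual)
            total += 1
    if total == 0:
        raise FastqError(f"no reads found in input: {files}")
    reservoir.sort(key=lambda item: item[0])
    reads = []
    for _, title, seq, qual in reservoir:
        read_id = title.split()[0]
        read = SampledRead(
            read_id=read_id,
            bases=seq.upper(),
            qualities=_decode_qualities(qual, read_id),
            dataset_id=dataset_id,
            original_length=len(seq),
        )
        reads.append(trim_read(read, plan.trim_length))
    return reads


def mean_quality(reads: list[SampledRead]) -> float:
    """Mean Phred score over all bases of all reads (nan for no reads)."""
    total = sum(sum(r.qualities) for r in reads)
    bases = sum(len(r.qualities) for r in reads)
    return total / bases if bases else float("nan")
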