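"""Ranking reporting units and resolving multi-aligned reads.

Reads frequently align to several species because of sequence homology
(e.g. human reads also mapping to mouse). To avoid counting homology as
contamination, reporting units are ranked by their total aligned-read
counts and every read is assigned to the single highest-ranked unit it
aligns to: the dominant (usually target) species absorbs shared reads,
and a lower-ranked unit accumulates only reads that map to it uniquely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .species_align import SpeciesAlignmentSet

ROLE_TARGET = "target"
ROLE_CONTROL = "control"
ROLE_OTHER = "other"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class UnitRanking:
    """Deterministic ordering of all units with at least one alignment."""

    order: tuple[str, ...]
    tie_break: str = "target-first-then-lexicographic"

    def rank_of(self, unit_id: str) -> int:
        return self.order.index(unit_id)


@dataclass
class UnitSummary:
    unit_id: str
    role: str
    aligned_count: int
    assigned_count: int
    assigned_error_rate: float


@dataclass
class DatasetSummary:
    """Per-dataset screen result: the numbers behind one report bar.

    Conservation invariant: assigned counts over all units plus
    ``unmapped_count`` equal ``sampled_count``. ``adapter_count`` is
    independent — a read can be both species-assigned and adapter-positive.
    """

    dataset_id: str
    sampled_count: int
    unit_summaries: list[UnitSummary]
    unmapped_count: int
    adapter_count: int = 0
    expected_control_fraction: float | None = None
    mean_quality: float = float("nan")
    max_mismatches: int = 2
    trim_length: int = 36

    @property
    def target_fraction(self) -> float:
        assigned = sum(
            u.assigned_count for u in self.unit_summaries if u.role == ROLE_TARGET
        )
        return assigned / self.sampled_count if self.sampled_count else 0.0

    @property
    def control_fraction(self) -> float:
        assigned = sum(
            u.assigned_count for u in self.unit_summaries if u.role == ROLE_CONTROL
        )
        return assigned / self.sampled_count if self.sampled_count else 0.0

    @property
    def adapter_fraction(self) -> float:
        return self.adapter_count / self.sampled_count if self.sampled_count else 0.0

    @property
    def unmapped_fraction(self) -> float:
        return self.unmapped_count / self.sampled_count if self.sampled_count else 0.0


def rank_units(
    alignment_set: SpeciesAlignmentSet,
    target_units: set[str] | None = None,
) -> UnitRanking:
    """Rank units by descending aligned-read count.

    Ties break deterministically: a declared target unit first, then
    lexicographic unit id.
    """
    targets = target_units or set()
    counts = alignment_set.unit_counts()
    order = sorted(
        counts,
        key=lambda u: (-counts[u], 0 if u in targets else 1, u),
    )
    return UnitRanking(order=tuple(order))


def assign_reads(
    alignment_set: SpeciesAlignmentSet, ranking: UnitRanking
) -> dict[str, str]:
    """Assign every aligned read to its single highest-ranked unit."""
    rank = {unit_id: i for i, unit_id in enumerate(ranking.order)}
    assignments: dict[str, str] = {}
    for read_id, alns in alignment_set.by_read().items():
        assignments[read_id] = min(alns, key=lambda a: rank[a.unit_id]).unit_id
    return assignments


def summarize(
    alignment_set: SpeciesAlignmentSet,
    assignments: dict[str, str],
    roles: dict[str, str],
    expected_control_fraction: float | None = None,
    mean_quality: float = float("nan"),
    trim_length: int = 36,
) -> DatasetSummary:
    """Collate per-unit assigned counts and error rates for one dataset.

    ``roles`` maps every panel unit id to target/control/other; it must
    cover every aligned unit. The error rate of a unit is total
    mismatches over total aligned bases of the reads *assigned* to it, so
    shared homologous reads do not dilute a contaminant's error rate.
    """
    aligned_counts = alignment_set.unit_counts()
    for unit_id in aligned_counts:
        if unit_id not in roles:
            raise ValueError(f"role map does not cover unit {unit_id!r}")
    mismatches: dict[str, int] = {u: 0 for u in roles}
    bases: dict[str, int] = {u: 0 for u in roles}
    assigned_counts: dict[str, int] = {u: 0 for u in roles}
    for aln in alignment_set.alignments:
        if assignments.get(aln.read_id) == aln.unit_id:
            assigned_counts[aln.unit_id] += 1
            mismatches[aln.unit_id] += aln.best_mismatches
            bases[aln.unit_id] += aln.aligned_length
    summaries = [
        UnitSummary(
            unit_id=unit_id,
            role=roles[unit_id],
            aligned_count=aligned_counts.get(unit_id, 0),
            assigned_count=assigned_counts[unit_id],
            assigned_error_rate=(
                mismatches[unit_id] / bases[unit_id] if bases[unit_id] else 0.0
            ),
        )
        for unit_id in sorted(roles)
    ]
    unmapped = alignment_set.sampled_count - len(assignments)
    return DatasetSummary(
        dataset_id=alignment_set.dataset_id,
        sampled_count=alignment_set.sampled_count,
        unit_summaries=summaries,
        unmapped_count=unmapped,
        expected_control_fraction=expected_control_fraction,
        mean_quality=mean_quality,
        max_mismatches=alignment_set.max_mismatches,
        trim_length=trim_length,
    )


def make_role_map(
    panel_units: list[str],
    target_unit: str | None,
    control_units: list[str],
) -> dict[str, str]:
    """Role map for one dataset: its declared target, the panel's
    control unit(s), everything else a potential contaminant."""
    if target_unit is not None and target_unit not in panel_units:
        raise ValueError(f"target unit {target_unit!r} not in panel")
    for c in control_units:
        if c not in panel_units:
            raise ValueError(f"control unit {c!r} not in panel")
    roles = {}
    for unit_id in panel_units:
        if unit_id == target_unit:
            roles[unit_id] = ROLE_TARGET
        elif unit_id in control_units:
            roles[unit_id] = ROLE_CONTROL
        else:
            roles[unit_id] = ROLE_OTHER
    return roles
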