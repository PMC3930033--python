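"""Adapter/primer detection by local alignment with affine gaps.

Adapter contamination differs from cross-species contamination in that
only part of a read may be adapter: when the sequenced fragment is
shorter than the read length, the 3' end of the read runs through into
the ligated adapter. A local alignment (Smith–Waterman with Gotoh's
three-state affine-gap recurrence) therefore scores the best-matching
*substring* pair between read and adapter. A read is adapter-positive
when its best hit reaches ``min_score`` (roughly: that many matched
bases) at ``min_identity`` over the aligned columns. Detection is
independent of the species screen: a read can be counted in both.

``sw_gotoh_local`` is the reference single-pair DP with traceback;
``screen_adapters`` accelerates the scan with a numpy-vectorised scoring
pass over all reads at once, then recovers spans by running the
reference DP only on reads whose score clears the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import AdapterSet
from .sampling import SampledRead
from .species_align import reverse_complement

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap local alignment scores and acceptance thresholds.

    ``gap_open`` is the cost of the first gapped column and ``gap_extend``
    of each further one. ``min_score`` ≈ the number of matched bases a
    hit must contain; 16 is long enough that random 36-base reads
    essentially never qualify against a fixed adapter.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    min_score: float = 16.0
    min_identity: float = 0.9

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0 < self.match):
            raise ValueError("require gap_open <= gap_extend <= 0 < match")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


@dataclass(frozen=True)
class AdapterHit:
    """Best local-alignment match of one read against the adapter set."""

    read_id: str
    adapter_id: str
    score: float
    read_span: tuple[int, int]
    adapter_span: tuple[int, int]
    identity: float


def sw_gotoh_local(
    a: str, b: str, scoring: AlignmentScoring | None = None
) -> tuple[float, tuple[int, int], tuple[int, int], float]:
    """Optimal local alignment of *a* vs *b* under affine gap costs.

    Three-state dynamic programme (match/mismatch, gap-in-a, gap-in-b)
    with traceback. Returns ``(score, a_span, b_span, identity)`` where
    the spans are 0-based half-open intervals and identity is matching
    columns over aligned columns. Score 0 means no positive-scoring
    local alignment exists; the spans are then empty.
    """
    if scoring is None:
        scoring = AlignmentScoring()
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best, best_pos = 0.0, (0, 0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i][j - 1] + scoring.gap_open, E[i][j - 1] + scoring.gap_extend
            )
            F[i][j] = max(
                H[i - 1][j] + scoring.gap_open, F[i - 1][j] + scoring.gap_extend
            )
            sub = scoring.match if ai == b[j - 1] else scoring.mismatch
            h = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, best_pos = h, (i, j)
    if best <= 0:
        return 0.0, (0, 0), (0, 0), 0.0
    # traceback from the best cell to the first zero H cell
    i, j = best_pos
    state = "H"
    matches = columns = 0
    end_a, end_b = i, j
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            sub = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            if H[i][j] == H[i - 1][j - 1] + sub:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i][j - 1] + scoring.gap_open:
                state = "H"
            j -= 1
        else:  # F
            columns += 1
            if F[i][j] == H[i - 1][j] + scoring.gap_open:
                state = "H"
            i -= 1
    identity = matches / columns if columns else 0.0
    return best, (i, end_a), (j, end_b), identity


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def batch_local_scores(
    reads: list[str], adapter: str, scoring: AlignmentScoring
) -> np.ndarray:
    """Best local-alignment score of each read against one adapter.

    Identical recurrence to :func:`sw_gotoh_local`, vectorised across
    reads: the DP advances over adapter positions (rows) and read
    positions (columns) while numpy carries all reads in parallel.
    Shorter reads are padded with a sentinel that can never match.
    """
    if not reads:
        return np.zeros(0)
    max_len = max(len(r) for r in reads)
    pad = np.zeros((len(reads), max_len), dtype=np.uint8)  # 0 matches nothing
    for idx, r in enumerate(reads):
        pad[idx, : len(r)] = _encode(r)
    adapter_arr = _encode(adapter)
    n_reads = len(reads)
    H = np.zeros((n_reads, max_len + 1))
    F = np.full((n_reads, max_len + 1), NEG_INF)  # gap consuming adapter
    best = np.zeros(n_reads)
    go, ge = scoring.gap_open, scoring.gap_extend
    for base in adapter_arr:
        sub = np.where(pad == base, scoring.match, scoring.mismatch)
        H_new = np.zeros((n_reads, max_len + 1))
        F_new = np.full((n_reads, max_len + 1), NEG_INF)
        E = np.full((n_reads, max_len + 1), NEG_INF)  # gap consuming read
        for j in range(1, max_len + 1):
            E[:, j] = np.maximum(H_new[:, j - 1] + go, E[:, j - 1] + ge)
            F_new[:, j] = np.maximum(H[:, j] + go, F[:, j] + ge)
            h = np.maximum(H[:, j - 1] + sub[:, j - 1], 0.0)
            h = np.maximum(h, E[:, j])
            h = np.maximum(h, F_new[:, j])
            H_new[:, j] = h
        H, F = H_new, F_new
        np.maximum(best, H.max(axis=1), out=best)
    # positions beyond a read's true length can only produce scores built
    # from mismatches/gaps against the sentinel, which never exceed a
    # prefix's genuine best because the sentinel always mismatches
    return best


def screen_adapters(
    reads: list[SampledRead],
    adapters: AdapterSet,
    scoring: AlignmentScoring | None = None,
) -> list[AdapterHit]:
    """Find the best adapter hit, if any, for each read.

    Both orientations of every adapter are screened (reverse-complement
    hits carry the same adapter id). At most one hit per read is kept:
    the highest-scoring placement meeting both ``min_score`` and
    ``min_identity``. Qualities are ignored (FASTA semantics).
    """
    if scoring is None:
        scoring = AlignmentScoring()
    if len(adapters) == 0:
        raise ValueError("empty adapter set")
    if not reads:
        return []
    seqs = [r.bases for r in reads]
    oriented = []
    for adapter_id, seq in adapters.adapters:
        oriented.append((adapter_id, seq))
        rc = reverse_complement(seq)
        if rc != seq:
            oriented.append((adapter_id, rc))
    # vectorised scoring pass: best score per read per oriented adapter
    score_matrix = np.stack(
        [batch_local_scores(seqs, seq, scoring) for _, seq in oriented]
    )
    hits: list[AdapterHit] = []
    candidate_idx = np.nonzero(score_matrix.max(axis=0) >= scoring.min_score)[0]
    for idx in candidate_idx:
        read = reads[idx]
        best_hit: AdapterHit | None = None
        for adapter_id, seq in oriented:
            score, a_span, b_span, identity = sw_gotoh_local(
                read.bases, seq, scoring
            )
            if score < scoring.min_score or identity < scoring.min_identity:
                continue
            if best_hit is None or score > best_hit.score:
                best_hit = AdapterHit(
                    read_id=read.read_id,
                    adapter_id=adapter_id,
                    score=score,
                    read_span=a_span,
                    adapter_span=b_span,
                    identity=identity,
                )
        if best_hit is not None:
            hits.append(best_hit)
    return hits


def export_hits(hits: list[AdapterHit], path) -> None:
    """Write adapter hits as a tab-separated audit table."""
    with open(path, "w") as handle:
        handle.write("read_id\tadapter_id\tscore\tread_start\tread_end\tidentity\n")
        for h in hits:
            handle.write(
                f"{h.read_id}\t{h.adapter_id}\t{h.score:g}\t"
                f"{h.read_span[0]}\t{h.read_span[1]}\t{h.identity:.4f}\n"
            )
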