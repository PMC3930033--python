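"""Independent brute-force oracles the implementation is checked against.

These deliberately share no code with the package: the Hamming oracle
scans every offset of every strand, and the local-alignment oracle
enumerates alignments recursively instead of running the tabular DP.
"""

from __future__ import annotations

from functools import lru_cache

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_with_n(query: str, ref: str) -> int:
    """Mismatch count where N on either side always counts as mismatch."""
    return sum(1 for q, r in zip(query, ref) if q != r or q == "N")


def brute_best_hamming(
    query: str, sequences: list[str], max_mismatches: int
) -> int | None:
    """Minimum Hamming distance over all end-to-end placements of the
    query (both strands) on any sequence, or None if it exceeds the
    mismatch ceiling everywhere."""
    best = None
    for seq in sequences:
        for oriented in (query, revcomp(query)):
            for start in range(len(seq) - len(oriented) + 1):
                mm = hamming_with_n(oriented, seq[start : start + len(oriented)])
                if best is None or mm < best:
                    best = mm
    if best is None or best > max_mismatches:
        return None
    return best


def brute_local_affine_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Best affine-gap local alignment score by exhaustive enumeration.

    A local alignment is a global alignment of some non-empty substring
    pair; global alignments are enumerated recursively column by column
    (match/mismatch, gap-in-a, gap-in-b), with the affine cost depending
    on the previous column type. Memoised but structurally independent
    of the package's tabular three-state DP.
    """

    @lru_cache(maxsize=None)
    def global_score(sa: str, sb: str, prev: str) -> float:
        if not sa and not sb:
            return 0.0
        options = []
        if sa and sb:
            sub = match if sa[0] == sb[0] else mismatch
            options.append(sub + global_score(sa[1:], sb[1:], "M"))
        if sb:  # gap in a, consuming b
            cost = gap_extend if prev == "A" else gap_open
            options.append(cost + global_score(sa, sb[1:], "A"))
        if sa:  # gap in b, consuming a
            cost = gap_extend if prev == "B" else gap_open
            options.append(cost + global_score(sa[1:], sb, "B"))
        return max(options)

    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    score = global_score(a[i1:i2], b[j1:j2], "M")
                    if score > best:
                        best = score
    global_score.cache_clear()
    return best
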