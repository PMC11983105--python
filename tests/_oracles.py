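"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic-programming aligner:
the brute-force aligner exhaustively enumerates monotone alignment
paths (with an exact admissible bound for pruning), scoring each path
from scratch.
"""

from __future__ import annotations

from selictseq._dna import IUPAC


def brute_force_semiglobal(
    target: str,
    window: str,
    match: int = 5,
    mismatch: int = -4,
    gap_open: int = -24,
    gap_ext: int = -8,
) -> int:
    """Maximum semiglobal affine-gap alignment score by exhaustive path
    enumeration (branch-and-bound with the exact bound score + match *
    remaining, which never prunes an improving path)."""
    m, n = len(target), len(window)
    best = -(10**9)
    for j0 in range(n - m + 1):
        s = sum(
            match if window[j0 + i] in IUPAC[target[i]] else mismatch
            for i in range(m)
        )
        best = max(best, s)
    sub = [
        [match if window[j] in IUPAC[target[i]] else mismatch for j in range(n)]
        for i in range(m)
    ]

    def rec(i: int, j: int, score: int, last: str | None) -> None:
        nonlocal best
        if i == m:
            best = max(best, score)
            return
        if score + match * (m - i) <= best:
            return
        if j < n:
            rec(i + 1, j + 1, score + sub[i][j], "D")
        rec(i + 1, j, score + (gap_ext if last == "U" else gap_open), "U")
        if i > 0 and j < n:
            rec(i, j + 1, score + (gap_ext if last == "R" else gap_open), "R")

    for j0 in range(n + 1):
        rec(0, j0, 0, None)
    return best


def second_base_signature(read, genome) -> tuple[int, str, bool] | None:
    """Re-derive a read's second-aligned-base position and whether it
    carries the truncated-mutant signature, by walking the CIGAR one
    base at a time (independent of the pileup implementation).

    Returns (reference position, strand, is_mutant_signature) or None
    if fewer than two aligned bases.
    """
    pairs = []  # (query_offset, ref_position) for reference-consuming bases
    q, r = 0, read.start
    for op, n in read.cigar:
        for _ in range(n):
            if op == "M":
                pairs.append((q, r))
                q += 1
                r += 1
            elif op in ("I", "S"):
                q += 1
            elif op == "D":
                r += 1
    if len(pairs) < 2:
        return None
    qoff, rpos = pairs[1] if read.strand == "+" else pairs[-2]
    ref_base = genome.sequences[read.contig][rpos]
    call = read.seq[qoff]
    if read.strand == "+":
        mutant = ref_base == "A" and call == "G"
    else:
        mutant = ref_base == "T" and call == "C"
    return rpos, read.strand, mutant
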