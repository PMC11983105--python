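"""Affine-gap semiglobal alignment of a short target inside a window.

The alignment is global in the target (every target base is consumed,
possibly against gap columns) and local in the window: leading and
trailing window bases are free.  Gap runs cost ``gap_open`` for the
first gapped column and ``gap_extend`` for each additional one, so a
length-L gap costs ``|gap_open| + |gap_extend| * (L - 1)``.

Degenerate IUPAC codes in the target (used for PAM patterns, e.g. NGG or
NRG) score as a match against any base they admit; N always matches.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._dna import IUPAC, revcomp

NEG_INF = float("-inf")


@dataclass
class AlignParams:
    match: int = 5
    mismatch: int = -4
    gap_open: int = -24
    gap_extend: int = -8

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")


@dataclass
class Alignment:
    """Result of a semiglobal alignment.

    ``window_start``/``window_end`` are the half-open window coordinates
    consumed by the alignment; removing gaps from ``aligned_target``
    reproduces the target exactly.
    """

    score: int
    aligned_target: str
    aligned_window: str
    window_start: int
    window_end: int

    @property
    def n_columns(self) -> int:
        return len(self.aligned_target)


def _match_score(t_char: str, w_char: str, params: AlignParams) -> int:
    allowed = IUPAC.get(t_char)
    if allowed is None:
        raise ValueError(f"invalid target character {t_char!r}")
    return params.match if w_char in allowed else params.mismatch


def semiglobal_align(
    target: str, window: str, params: AlignParams | None = None
) -> Alignment:
    """Best-scoring semiglobal alignment of ``target`` within ``window``.

    Three-state Gotoh dynamic programming.  Ties are broken
    deterministically: the alignment ending leftmost in the window wins,
    and within a cell match/mismatch columns are preferred over target
    bulges over window bulges (biasing toward fewer gaps).
    """
    if params is None:
        params = AlignParams()
    if not target or not window:
        raise ValueError("target and window must be non-empty")
    target = target.upper()
    window = window.upper()
    m, n = len(target), len(window)

    # state 0 = M (diagonal), 1 = gap-in-window (target base unpaired),
    # 2 = gap-in-target (window base unpaired, internal only)
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    # parent[state][i][j] -> previous state, or -1 for alignment start
    ptr = [[[0] * (n + 1) for _ in range(m + 1)] for _ in range(3)]

    for j in range(n + 1):
        M[0][j] = 0  # free leading window gap: start anywhere
        ptr[0][0][j] = -1

    go, ge = params.gap_open, params.gap_extend
    for i in range(1, m + 1):
        ti = target[i - 1]
        row_m, row_x, row_y = M[i], Ix[i], Iy[i]
        prev_m, prev_x, prev_y = M[i - 1], Ix[i - 1], Iy[i - 1]
        for j in range(n + 1):
            # gap in window: consume target base against '-'
            open_x = prev_m[j] + go
            ext_x = prev_x[j] + ge
            if open_x >= ext_x:
                row_x[j], ptr[1][i][j] = open_x, 0
            else:
                row_x[j], ptr[1][i][j] = ext_x, 1
            if j == 0:
                continue
            # diagonal
            s = _match_score(ti, window[j - 1], params)
            best_prev, best_state = prev_m[j - 1], 0
            if prev_x[j - 1] > best_prev:
                best_prev, best_state = prev_x[j - 1], 1
            if prev_y[j - 1] > best_prev:
                best_prev, best_state = prev_y[j - 1], 2
            row_m[j] = best_prev + s
            ptr[0][i][j] = best_state
            # gap in target: consume window base against '-' (internal)
            open_y = row_m[j - 1] + go
            ext_y = row_y[j - 1] + ge
            if open_y >= ext_y:
                row_y[j], ptr[2][i][j] = open_y, 0
            else:
                row_y[j], ptr[2][i][j] = ext_y, 2

    # trailing window bases are free: end at the best (state, j) in row m
    best_score, best_j, best_state = NEG_INF, 0, 0
    for j in range(n + 1):
        for state, row in ((0, M[m]), (1, Ix[m])):
            if row[j] > best_score:
                best_score, best_j, best_state = row[j], j, state

    # traceback
    cols_t: list[str] = []
    cols_w: list[str] = []
    i, j, state = m, best_j, best_state
    window_end = best_j
    while True:
        prev_state = ptr[state][i][j]
        if state == 0:
            if prev_state == -1 and i == 0:
                break
            cols_t.append(target[i - 1])
            cols_w.append(window[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            cols_t.append(target[i - 1])
            cols_w.append("-")
            i = i - 1
        else:
            cols_t.append("-")
            cols_w.append(window[j - 1])
            j = j - 1
        state = prev_state
    window_start = j

    return Alignment(
        score=int(best_score),
        aligned_target="".join(reversed(cols_t)),
        aligned_window="".join(reversed(cols_w)),
        window_start=window_start,
        window_end=window_end,
    )


def penalty(alignment: Alignment, target_len: int, match: int = 5) -> int:
    """Alignment penalty: score shortfall from a perfect full-length match."""
    return match * target_len - alignment.score


def align_both_strands(
    target: str, window: str, params: AlignParams | None = None
) -> tuple[Alignment, str]:
    """Align against the window and its reverse complement.

    Returns the better alignment and the strand ('+' if the target reads
    left-to-right on the given window, '-' otherwise).  A tie keeps '+'.
    """
    fwd = semiglobal_align(target, window, params)
    rev = semiglobal_align(target, revcomp(window), params)
    if rev.score > fwd.score:
        return rev, "-"
    return fwd, "+"
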