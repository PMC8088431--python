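"""Cross-species conservation of confident HRE windows.

Confident windows from two species are compared by exact global alignment
(Needleman-Wunsch, linear gap penalty). A pair is called conserved when the
alignment identity reaches the configured minimum and the two 5-bp cores
are identical as read on their hit strands; windows are matched one-to-one,
best identity first.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scanner import HREWindow, ScanReport

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0
DEFAULT_MIN_IDENTITY = 0.7

_DIAG, _UP, _LEFT = 0, 1, 2


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class ConservedPair:
    window_a: HREWindow
    window_b: HREWindow
    alignment: AlignmentResult
    core_match: bool


def _pair_score(x: str, y: str, match: float, mismatch: float) -> float:
    # N is ambiguous and matches nothing, including another N
    if x == "N" or y == "N":
        return mismatch
    return match if x == y else mismatch


def pairwise_align(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> AlignmentResult:
    """Optimal global alignment under a linear gap penalty.

    Traceback ties are broken deterministically: diagonal, then up
    (gap in ``b``), then left (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    move = [[_LEFT] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
        move[i][0] = _UP
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = score[i], score[i - 1]
        mrow = move[i]
        for j in range(1, m + 1):
            d = prev[j - 1] + _pair_score(ai, b[j - 1], match, mismatch)
            u = prev[j] + gap
            l = row[j - 1] + gap
            # tie preference: diagonal > up > left
            if d >= u and d >= l:
                row[j], mrow[j] = d, _DIAG
            elif u >= l:
                row[j], mrow[j] = u, _UP
            else:
                row[j], mrow[j] = l, _LEFT
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == _DIAG and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif mv == _UP and i > 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score[n][m],
        identity=_identity(aligned_a, aligned_b),
    )


def _identity(aligned_a: str, aligned_b: str) -> float:
    """Fraction of matching columns, terminal gap columns excluded."""
    cols = len(aligned_a)
    lo, hi = 0, cols
    while lo < hi and (aligned_a[lo] == "-" or aligned_b[lo] == "-"):
        lo += 1
    while hi > lo and (aligned_a[hi - 1] == "-" or aligned_b[hi - 1] == "-"):
        hi -= 1
    span = hi - lo
    if span == 0:
        return 0.0
    matches = sum(
        1
        for x, y in zip(aligned_a[lo:hi], aligned_b[lo:hi])
        if x == y and x != "-" and x != "N"
    )
    return matches / span


def find_conserved(
    report_a: ScanReport,
    report_b: ScanReport,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> list[ConservedPair]:
    """Call conserved HREs between two species' confident windows.

    All confident-by-confident pairs are aligned; candidates need
    identity >= min_identity and exactly matching cores. Each window joins
    at most one pair (greedy, best identity first, deterministic
    tie-breaks on score then coordinates). Result sorted by identity
    descending.
    """
    if not (0 <= min_identity <= 1):
        raise ValueError("min_identity must be in [0, 1]")
    cand: list[tuple[float, float, int, int, ConservedPair]] = []
    wins_a = report_a.confident_windows()
    wins_b = report_b.confident_windows()
    for ia, wa in enumerate(wins_a):
        for ib, wb in enumerate(wins_b):
            aln = pairwise_align(
                wa.window_seq, wb.window_seq, match, mismatch, gap
            )
            core_ok = wa.core_seq == wb.core_seq
            if aln.identity >= min_identity and core_ok:
                cand.append(
                    (aln.identity, aln.score, ia, ib,
                     ConservedPair(wa, wb, aln, core_ok))
                )
    cand.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[ConservedPair] = []
    for identity, _score, ia, ib, pair in cand:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append(pair)
    return pairs
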