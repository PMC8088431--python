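"""Position-specific frequency matrix (PSFM) construction and scoring.

A candidate hypoxia-responsive element is scored as the product over window
positions of the per-position base frequencies. Scores are reported both raw
and normalized by the maximum attainable product, so the consensus window of
any matrix scores exactly 1.0 and thresholds are matrix-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: default confidence cutoff on the normalized score
DEFAULT_THRESHOLD = 0.05
#: default additive pseudocount used when building from counts
DEFAULT_PSEUDOCOUNT = 0.5

#: geometry of the scoring window: 8 bp upstream flank, 5 bp RCGTG core,
#: 20 bp downstream flank
WINDOW_WIDTH = 33
CORE_OFFSET = 8          # 0-based index of the first core base in the window
CORE_LENGTH = 5
FLANK_POSITIONS = tuple(
    i for i in range(WINDOW_WIDTH)
    if not (CORE_OFFSET <= i < CORE_OFFSET + CORE_LENGTH)
)


@dataclass(frozen=True)
class WindowScore:
    raw: float
    norm: float


@dataclass(frozen=True)
class PSFM:
    """Per-position nucleotide frequency matrix with background and cutoff.

    ``freq`` has shape (width, 4) over A,C,G,T; each row sums to 1.
    ``threshold`` is the normalized-score cutoff above which a window is
    called a confident HRE.
    """

    freq: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    threshold: float = DEFAULT_THRESHOLD
    name: str = "psfm"

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "freq", freq)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError(f"freq must be (width, 4), got {freq.shape}")
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each matrix row must sum to 1")
        if np.any(freq < 0):
            raise ValueError("frequencies must be non-negative")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    def consensus(self) -> str:
        """Highest-frequency base per position (ties broken in A,C,G,T order)."""
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))

    def max_product(self, positions: Sequence[int] | None = None) -> float:
        best = self.freq.max(axis=1)
        if positions is not None:
            best = best[list(positions)]
        return float(np.prod(best))


def build_psfm(
    training_windows: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    name: str = "trained",
) -> PSFM:
    """Estimate a PSFM from an alignment of equal-length validated windows.

    freq[i][b] = (count(b at i) + pseudocount) / (n + 4 * pseudocount)
    """
    if len(training_windows) < 2:
        raise ValueError("need at least 2 training windows")
    width = len(training_windows[0])
    counts = np.zeros((width, 4), dtype=float)
    for w in training_windows:
        if len(w) != width:
            raise ValueError(
                f"ragged training windows: expected width {width}, got {len(w)}"
            )
        for i, b in enumerate(w.upper()):
            if b not in _BASE_INDEX:
                raise ValueError(f"illegal base {b!r} in training window")
            counts[i, _BASE_INDEX[b]] += 1
    n = len(training_windows)
    freq = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PSFM(freq=freq, pseudocount=pseudocount, background=bg,
                threshold=threshold, name=name)


def score_window(
    m: PSFM, window: str, positions: Sequence[int] | None = None
) -> WindowScore | None:
    """Score one window; returns None (unscorable) if the window contains N.

    ``positions`` restricts scoring to a subset of window positions
    (e.g. flank-only scoring); default scores the full width.
    """
    if len(window) != m.width:
        raise ValueError(
            f"window length {len(window)} != matrix width {m.width}"
        )
    if "N" in window:
        return None
    idx = range(m.width) if positions is None else positions
    raw = 1.0
    for i in idx:
        b = window[i]
        if b not in _BASE_INDEX:
            raise ValueError(f"illegal base {b!r} in window")
        raw *= float(m.freq[i, _BASE_INDEX[b]])
    return WindowScore(raw=raw, norm=raw / m.max_product(positions))


def read_psfm(
    path: str | Path,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = DEFAULT_THRESHOLD,
) -> PSFM:
    """Read a PSFM from TSV (header A C G T, one row per position).

    Rows of counts are normalized with the configured pseudocount; rows
    that already sum to ~1 are taken as frequencies verbatim.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if [h.strip().upper() for h in header] != list(BASES):
        raise ValueError(
            f"{path}: expected header columns A C G T, got {header}"
        )
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        vals = [float(v) for v in ln.split("\t")]
        if len(vals) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 values")
        total = sum(vals)
        if total <= 0:
            raise ValueError(
                f"{path}: line {lineno}: row sums to {total}, must be positive"
            )
        if abs(total - 1.0) <= 1e-6:
            rows.append(vals)
        else:
            rows.append([(v + pseudocount) / (total + 4 * pseudocount)
                         for v in vals])
    return PSFM(freq=np.array(rows), pseudocount=pseudocount,
                threshold=threshold, name=path.stem)


def write_psfm(m: PSFM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BASES) + "\n")
        for row in m.freq:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Illustrative default matrix
# ---------------------------------------------------------------------------

#: 33-bp illustrative consensus: 8-bp upstream flank, ACGTG core, 20-bp
#: downstream flank. Chosen free of secondary RCGTG matches on either strand
#: so planted windows contribute exactly one core hit.
ILLUSTRATIVE_CONSENSUS = "TCTAGCAT" + "ACGTG" + "CTCAAGTCTCATGGTAGTCA"

#: per-position probabilities of the illustrative matrix
FLANK_CONSENSUS_PROB = 0.7     # flank positions: consensus 0.7, others 0.1
CORE_R_PROBS = (0.58, 0.39)    # first core base: A 0.58, G 0.39, C/T 0.015
CORE_FIXED_PROB = 0.97         # invariant core bases CGTG


def illustrative_matrix(threshold: float = DEFAULT_THRESHOLD) -> PSFM:
    """The bundled illustrative HRE matrix (synthetic, for demonstration).

    Built analytically from the synthetic generator's settings, not from
    published binding data: flanks favour a fixed consensus at probability
    0.7; the core is a strongly constrained RCGTG with the purine split
    58/39 between A and G. It demonstrates the scoring mechanism and
    calibrates the simulator; it is not a trained HIF1-binding model.
    """
    freq = np.zeros((WINDOW_WIDTH, 4))
    for i, base in enumerate(ILLUSTRATIVE_CONSENSUS):
        if i == CORE_OFFSET:  # R position of the core
            freq[i] = [CORE_R_PROBS[0], 0.015, CORE_R_PROBS[1], 0.015]
        elif CORE_OFFSET < i < CORE_OFFSET + CORE_LENGTH:
            freq[i] = [(1 - CORE_FIXED_PROB) / 3] * 4
            freq[i, _BASE_INDEX[base]] = CORE_FIXED_PROB
        else:
            freq[i] = [(1 - FLANK_CONSENSUS_PROB) / 3] * 4
            freq[i, _BASE_INDEX[base]] = FLANK_CONSENSUS_PROB
    return PSFM(freq=freq, pseudocount=0.0, threshold=threshold,
                name="illustrative")
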