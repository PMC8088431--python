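"""Core-motif scanning and 33-bp window scoring.

The HIF1 binding core is the 5-mer [A/G]CGTG. Each occurrence (either
strand) seeds a 33-bp scoring window spanning 8 bases 5' of the core
through 20 bases 3' of it on the hit strand; windows are scored against a
PSFM and called confident when the normalized score reaches the threshold.
Scoring the flanks alongside the core reduces the rate of misleading
matches that the 5-mer alone would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

from .matrix import (
    CORE_LENGTH,
    CORE_OFFSET,
    FLANK_POSITIONS,
    PSFM,
    WINDOW_WIDTH,
    _BASE_INDEX,
    score_window,
)
from .sequences import PromoterSequence, reverse_complement

CORE_PATTERNS_FWD = ("ACGTG", "GCGTG")
#: forward-strand 5-mers whose reverse complement is a core motif
CORE_PATTERNS_REV = ("CACGT", "CACGC")  # -> ACGTG, GCGTG on the minus strand

UPSTREAM_FLANK = 8
DOWNSTREAM_FLANK = 20

StrandMode = Literal["forward", "both"]


@dataclass(frozen=True)
class CoreHit:
    """One [A/G]CGTG occurrence.

    ``pos`` is the 1-based start of the 5-mer in forward coordinates;
    ``variant`` is the first core base as read on the hit strand.
    """

    seq_id: str
    pos: int
    strand: str
    variant: str


@dataclass
class HREWindow:
    """A 33-bp candidate HRE: core hit plus flanks, with its scores.

    ``window_seq`` is read on the hit strand; positions 9-13 (1-based) are
    the core. ``raw_prob``/``norm_score`` are None for unscorable windows
    (those containing N).
    """

    core: CoreHit
    window_seq: str
    raw_prob: float | None = None
    norm_score: float | None = None
    confident: bool = False
    upstream_offset: int = -UPSTREAM_FLANK
    downstream_offset: int = DOWNSTREAM_FLANK

    def __post_init__(self) -> None:
        if len(self.window_seq) != WINDOW_WIDTH:
            raise ValueError(
                f"window must be {WINDOW_WIDTH} bp, got {len(self.window_seq)}"
            )

    @property
    def core_seq(self) -> str:
        return self.window_seq[CORE_OFFSET : CORE_OFFSET + CORE_LENGTH]

    def forward_span(self) -> tuple[int, int]:
        """1-based inclusive span of the window in forward coordinates."""
        p = self.core.pos
        if self.core.strand == "+":
            return p - UPSTREAM_FLANK, p + CORE_LENGTH - 1 + DOWNSTREAM_FLANK
        return p - DOWNSTREAM_FLANK, p + CORE_LENGTH - 1 + UPSTREAM_FLANK


@dataclass
class ScanReport:
    """Per-sequence scan outcome with full count accounting."""

    seq_id: str
    n_core_hits: int
    n_windows: int
    n_boundary_dropped: int
    n_unscorable: int
    n_confident: int
    windows: list[HREWindow]
    parameters: dict = field(default_factory=dict)

    def confident_windows(self) -> list[HREWindow]:
        return [w for w in self.windows if w.confident]


def find_core_hits(
    p: PromoterSequence, strand_mode: StrandMode = "both"
) -> list[CoreHit]:
    """Every [A/G]CGTG occurrence, overlapping hits included.

    Positions are forward-coordinate starts of the 5-mer regardless of
    strand; output is sorted by position then strand.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    s = p.seq
    hits: list[CoreHit] = []
    for i in range(len(s) - 4):
        mer = s[i : i + 5]
        if mer in CORE_PATTERNS_FWD:
            hits.append(CoreHit(p.id, i + 1, "+", mer[0]))
        if strand_mode == "both" and mer in CORE_PATTERNS_REV:
            variant = "A" if mer == "CACGT" else "G"
            hits.append(CoreHit(p.id, i + 1, "-", variant))
    hits.sort(key=lambda h: (h.pos, h.strand))
    return hits


def extract_window(p: PromoterSequence, h: CoreHit) -> HREWindow | None:
    """Cut the 33-bp window around a core hit; None if it runs off an end.

    On the minus strand the window is the reverse complement of the
    forward slice pos-20 .. pos+12, so it still reads flank-core-flank in
    the hit strand's 5'->3' direction.
    """
    if h.seq_id != p.id:
        raise ValueError(f"hit {h.seq_id!r} does not refer to sequence {p.id!r}")
    if h.strand == "+":
        start = h.pos - UPSTREAM_FLANK
        end = h.pos + CORE_LENGTH - 1 + DOWNSTREAM_FLANK
    else:
        start = h.pos - DOWNSTREAM_FLANK
        end = h.pos + CORE_LENGTH - 1 + UPSTREAM_FLANK
    if start < 1 or end > len(p.seq):
        return None
    fwd = p.seq[start - 1 : end]
    window = fwd if h.strand == "+" else reverse_complement(fwd)
    return HREWindow(core=h, window_seq=window)


@dataclass(frozen=True)
class ScanConfig:
    threshold: float | None = None     # None -> the matrix's own threshold
    strand_mode: StrandMode = "both"
    flank_only: bool = False           # score the 28 flank positions only


def scan_promoter(
    p: PromoterSequence, m: PSFM, cfg: ScanConfig = ScanConfig()
) -> ScanReport:
    """find_core_hits -> extract_window -> score -> threshold, with counts.

    Deterministic for fixed inputs. Windows containing N are retained but
    flagged unscorable and never counted confident; ties at the threshold
    pass (closed threshold).
    """
    if m.width != WINDOW_WIDTH:
        raise ValueError(
            f"matrix width {m.width} != scanning window width {WINDOW_WIDTH}"
        )
    threshold = m.threshold if cfg.threshold is None else cfg.threshold
    positions = FLANK_POSITIONS if cfg.flank_only else None

    hits = find_core_hits(p, cfg.strand_mode)
    windows: list[HREWindow] = []
    n_dropped = n_unscorable = n_confident = 0
    for h in hits:
        w = extract_window(p, h)
        if w is None:
            n_dropped += 1
            continue
        score = score_window(m, w.window_seq, positions)
        if score is None:
            n_unscorable += 1
            windows.append(w)
            continue
        w = replace(
            w,
            raw_prob=score.raw,
            norm_score=score.norm,
            confident=score.norm >= threshold,
        )
        if w.confident:
            n_confident += 1
        windows.append(w)
    return ScanReport(
        seq_id=p.id,
        n_core_hits=len(hits),
        n_windows=len(windows),
        n_boundary_dropped=n_dropped,
        n_unscorable=n_unscorable,
        n_confident=n_confident,
        windows=windows,
        parameters={
            "threshold": threshold,
            "strand_mode": cfg.strand_mode,
            "flank_only": cfg.flank_only,
            "matrix": m.name,
        },
    )


def divergence_threshold(m: PSFM, n_substitutions: int) -> float:
    """Normalized-score cutoff tolerating a flank substitution budget.

    The normalized product score drops by a per-position factor
    f(worst)/f(best) for every base that departs from the consensus, so a
    sensible cutoff for sequences expected to differ from the motif model
    (e.g. cross-species scans at ~10% flank divergence) is the score of a
    window carrying ``n_substitutions`` worst-case flank substitutions,
    with the less-favoured core purine also allowed.
    """
    if n_substitutions < 0:
        raise ValueError("substitution budget must be non-negative")
    ratios = sorted(
        float(m.freq[i].min() / m.freq[i].max()) for i in FLANK_POSITIONS
    )
    t = 1.0
    for r in ratios[: min(n_substitutions, len(ratios))]:
        t *= r
    # allow either core purine: ratio of the two legal first-core-base freqs
    a, g = m.freq[CORE_OFFSET, _BASE_INDEX["A"]], m.freq[CORE_OFFSET, _BASE_INDEX["G"]]
    t *= min(a, g) / max(a, g)
    return max(t, 5e-324)


def core_hit_density(report: ScanReport, length: int) -> float:
    """Core hits per kb, the headline of a preliminary screen."""
    if length <= 0:
        raise ValueError("length must be positive")
    return 1000.0 * report.n_core_hits / length
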