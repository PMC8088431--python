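"""Synthetic promoters with planted HRE windows and known ground truth.

The generator emulates the scanned promoter setting: a ~5.5-kb region
(mirroring a -5000/+500 bp window around a transcription start site) of
i.i.d. background bases, with a chosen number of non-overlapping 33-bp
windows drawn position-wise from a PSFM written over the background at
recorded positions. A two-species mode shares a subset of planted sites
between species with controlled flank divergence, providing ground truth
for the conservation caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .matrix import BASES, CORE_LENGTH, CORE_OFFSET, PSFM, WINDOW_WIDTH, _BASE_INDEX
from .sequences import PromoterSequence, reverse_complement

_PLACEMENT_TRIES = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the promoter-scan setting: a 5,500-bp region, uniform
    base composition, ten planted sites kept at least 50 bp apart, 10%
    per-base flank divergence between species, and half of the sites
    shared by both species.
    """

    length: int = 5500
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_planted: int = 10
    min_spacing: int = 50
    flank_divergence: float = 0.1
    shared_fraction: float = 0.5
    seed: int = 0
    plant_strand: Literal["forward", "random"] = "forward"

    def __post_init__(self) -> None:
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("base_freqs must be 4 non-negative values summing to 1")
        if self.length < 1:
            raise ValueError("length must be positive")
        if self.n_planted < 0:
            raise ValueError("n_planted must be non-negative")
        if self.n_planted * (WINDOW_WIDTH + self.min_spacing) > self.length:
            raise ValueError(
                "cannot fit planted windows: reduce n_planted or min_spacing"
            )
        for name in ("flank_divergence", "shared_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        """The single PRNG for a run: NumPy PCG64 seeded from ``seed``."""
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted window (positions are window starts)."""

    strand: str
    membership: str                 # "A", "B", or "both"
    pos_a: int | None = None
    window_a: str | None = None
    pos_b: int | None = None
    window_b: str | None = None


@dataclass(frozen=True)
class PlantedTruth:
    sites: tuple[PlantedSite, ...] = field(default_factory=tuple)

    def positions(self, species: str = "A") -> list[int]:
        attr = "pos_a" if species == "A" else "pos_b"
        return sorted(
            getattr(s, attr) for s in self.sites if getattr(s, attr) is not None
        )

    def core_positions(self, species: str = "A") -> list[int]:
        """Forward-coordinate 1-based core starts, as the scanner reports them."""
        out = []
        for s in self.sites:
            pos = s.pos_a if species == "A" else s.pos_b
            if pos is None:
                continue
            if s.strand == "+":
                out.append(pos + CORE_OFFSET)
            else:
                # minus-strand window occupies pos..pos+32 forward; its core
                # 5-mer sits 20 bases in from the forward start
                out.append(pos + WINDOW_WIDTH - CORE_OFFSET - CORE_LENGTH)
        return sorted(out)


def generate_background(
    cfg: SimulationConfig, rng: np.random.Generator | None = None,
    seq_id: str | None = None,
) -> PromoterSequence:
    """I.i.d. background sequence from ``cfg.base_freqs``; seed-reproducible."""
    rng = cfg.rng() if rng is None else rng
    letters = rng.choice(list(BASES), size=cfg.length, p=list(cfg.base_freqs))
    return PromoterSequence(
        id=seq_id or f"synthetic_seed{cfg.seed}", seq="".join(letters)
    )


def draw_window(m: PSFM, rng: np.random.Generator) -> str:
    """One window sampled position-wise from the matrix.

    Core positions are forced legal: the first core base is drawn from the
    renormalized A/G frequencies and the remaining four are fixed to CGTG,
    so every planted window contains a scannable [A/G]CGTG.
    """
    if m.width != WINDOW_WIDTH:
        raise ValueError(f"matrix width {m.width} != {WINDOW_WIDTH}")
    out = []
    for i in range(m.width):
        if i == CORE_OFFSET:
            a = m.freq[i, _BASE_INDEX["A"]]
            g = m.freq[i, _BASE_INDEX["G"]]
            out.append("A" if rng.random() < a / (a + g) else "G")
        elif CORE_OFFSET < i < CORE_OFFSET + CORE_LENGTH:
            out.append("CGTG"[i - CORE_OFFSET - 1])
        else:
            out.append(BASES[rng.choice(4, p=m.freq[i])])
    return "".join(out)


def _choose_positions(
    cfg: SimulationConfig, n: int, rng: np.random.Generator
) -> list[int]:
    """Uniform non-overlapping 1-based window starts, min_spacing apart."""
    span = WINDOW_WIDTH + cfg.min_spacing
    chosen: list[int] = []
    for _ in range(_PLACEMENT_TRIES * max(n, 1)):
        if len(chosen) == n:
            break
        pos = int(rng.integers(1, cfg.length - WINDOW_WIDTH + 2))
        if all(abs(pos - q) >= span for q in chosen):
            chosen.append(pos)
    if len(chosen) < n:
        raise RuntimeError(
            "could not place windows without overlap; reduce n_planted "
            "or min_spacing"
        )
    return chosen


def _overwrite(seq: str, pos_1based: int, window: str) -> str:
    i = pos_1based - 1
    return seq[:i] + window + seq[i + len(window):]


def _plant_one(
    seq: str, pos: int, window: str, strand: str
) -> str:
    placed = window if strand == "+" else reverse_complement(window)
    return _overwrite(seq, pos, placed)


def plant_sites(
    bg: PromoterSequence, m: PSFM, cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PromoterSequence, PlantedTruth]:
    """Overwrite the background with ``cfg.n_planted`` matrix-drawn windows.

    Overwriting (rather than inserting) keeps all other coordinates
    stable. Truth records the exact placements; window starts are 1-based.
    """
    rng = cfg.rng() if rng is None else rng
    positions = _choose_positions(cfg, cfg.n_planted, rng)
    seq = bg.seq
    sites = []
    for pos in positions:
        strand = "+"
        if cfg.plant_strand == "random" and rng.random() < 0.5:
            strand = "-"
        window = draw_window(m, rng)
        seq = _plant_one(seq, pos, window, strand)
        sites.append(
            PlantedSite(strand=strand, membership="A", pos_a=pos, window_a=window)
        )
    sites.sort(key=lambda s: s.pos_a)
    return (
        PromoterSequence(id=bg.id, seq=seq, region=bg.region),
        PlantedTruth(sites=tuple(sites)),
    )


def mutate_flanks(
    window: str, divergence: float, rng: np.random.Generator
) -> str:
    """Substitute flank bases at the given per-base rate; core untouched."""
    out = list(window)
    for i in range(len(window)):
        if CORE_OFFSET <= i < CORE_OFFSET + CORE_LENGTH:
            continue
        if rng.random() < divergence:
            out[i] = rng.choice([b for b in BASES if b != window[i]])
    return "".join(out)


def expected_background_core_hits(
    length: int,
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    strand_mode: Literal["forward", "both"] = "forward",
) -> float:
    """Closed-form expected number of background [A/G]CGTG hits.

    Per forward position the core probability is
    (p_A + p_G) * p_C * p_G * p_T * p_G; both-strand mode adds the
    probability of the reverse-complement motifs (CACGT/CACGC) evaluated
    on the forward composition. Valid for i.i.d. backgrounds.
    """
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("base_freqs must be 4 non-negative values summing to 1")
    if length < 5:
        return 0.0
    pa, pc, pg, pt = freqs
    n_pos = length - 4
    p_fwd = (pa + pg) * pc * pg * pt * pg
    if strand_mode == "forward":
        return n_pos * p_fwd
    p_rev = pc * pa * pc * pg * (pt + pc)   # CACGT or CACGC on forward strand
    return n_pos * (p_fwd + p_rev)


def make_species_pair(
    cfg: SimulationConfig, m: PSFM
) -> tuple[PromoterSequence, PromoterSequence, PlantedTruth]:
    """Two synthetic promoters sharing planted HREs with flank divergence.

    Backgrounds are independent; round(shared_fraction * n_planted) drawn
    windows are planted in both species — the species-B copy with flank
    bases substituted at ``flank_divergence`` and the core preserved — and
    the remaining sites are private, alternating between species.
    """
    rng = cfg.rng()
    bg_a = generate_background(cfg, rng, seq_id=f"speciesA_seed{cfg.seed}")
    bg_b = generate_background(cfg, rng, seq_id=f"speciesB_seed{cfg.seed}")
    n_shared = int(round(cfg.shared_fraction * cfg.n_planted))
    n_private = cfg.n_planted - n_shared
    pos_a = _choose_positions(cfg, cfg.n_planted, rng)
    pos_b = _choose_positions(cfg, cfg.n_planted, rng)
    seq_a, seq_b = bg_a.seq, bg_b.seq
    sites: list[PlantedSite] = []
    ia = ib = 0
    for k in range(cfg.n_planted):
        strand = "+"
        if cfg.plant_strand == "random" and rng.random() < 0.5:
            strand = "-"
        window = draw_window(m, rng)
        if k < n_shared:
            wb = mutate_flanks(window, cfg.flank_divergence, rng)
            pa, pb = pos_a[ia], pos_b[ib]
            ia += 1
            ib += 1
            seq_a = _plant_one(seq_a, pa, window, strand)
            seq_b = _plant_one(seq_b, pb, wb, strand)
            sites.append(PlantedSite(strand=strand, membership="both",
                                     pos_a=pa, window_a=window,
                                     pos_b=pb, window_b=wb))
        elif (k - n_shared) % 2 == 0:
            pa = pos_a[ia]
            ia += 1
            seq_a = _plant_one(seq_a, pa, window, strand)
            sites.append(PlantedSite(strand=strand, membership="A",
                                     pos_a=pa, window_a=window))
        else:
            pb = pos_b[ib]
            ib += 1
            seq_b = _plant_one(seq_b, pb, window, strand)
            sites.append(PlantedSite(strand=strand, membership="B",
                                     pos_b=pb, window_b=window))
    return (
        replace(bg_a, seq=seq_a),
        replace(bg_b, seq=seq_b),
        PlantedTruth(sites=tuple(sites)),
    )
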