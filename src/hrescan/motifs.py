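"""IUPAC motif scanning and transcription-factor co-factor overlap.

Beyond the RCGTG core, hypoxia-responsive promoters carry supplementary
regulatory motifs; these are user-configured as IUPAC patterns and scanned
with the same position/strand conventions as the core search. The
co-factor step intersects a promoter-binding TF list with a list of
validated HIF1A interactors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from .sequences import PromoterSequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B",
    "N": "N",
}


@dataclass(frozen=True)
class IUPACMotif:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name!r} has an empty pattern")
        for ch in self.pattern.upper():
            if ch not in IUPAC:
                raise ValueError(
                    f"motif {self.name!r}: illegal IUPAC code {ch!r}"
                )

    def reverse_complement_pattern(self) -> str:
        return "".join(
            _IUPAC_COMPLEMENT[c] for c in reversed(self.pattern.upper())
        )


@dataclass(frozen=True)
class MotifHit:
    motif: str
    pos: int        # 1-based forward-coordinate start of the matched span
    strand: str


def _matches_at(seq: str, i: int, sets: list[str]) -> bool:
    for off, allowed in enumerate(sets):
        if seq[i + off] not in allowed:
            return False
    return True


def scan_iupac(
    p: PromoterSequence,
    motifs: Iterable[IUPACMotif],
    strand_mode: Literal["forward", "both"] = "both",
) -> list[MotifHit]:
    """All positions matching each IUPAC pattern, on the requested strands.

    With pattern RCGTG this reduces exactly to the core-hit scan. An N in
    the sequence matches only patterns that allow all four bases at that
    offset (i.e. only pattern code N).
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    hits: list[MotifHit] = []
    for motif in motifs:
        pat = motif.pattern.upper()
        fwd_sets = [IUPAC[c] + ("N" if IUPAC[c] == "ACGT" else "") for c in pat]
        searches = [(fwd_sets, "+")]
        if strand_mode == "both":
            rc = motif.reverse_complement_pattern()
            rc_sets = [IUPAC[c] + ("N" if IUPAC[c] == "ACGT" else "") for c in rc]
            searches.append((rc_sets, "-"))
        k = len(pat)
        for sets, strand in searches:
            for i in range(len(p.seq) - k + 1):
                if _matches_at(p.seq, i, sets):
                    hits.append(MotifHit(motif.name, i + 1, strand))
    hits.sort(key=lambda h: (h.motif, h.pos, h.strand))
    return hits


def read_motif_tsv(path: str | Path) -> list[IUPACMotif]:
    """Load motifs from TSV: name<TAB>pattern, '#' comments allowed."""
    motifs = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected name<TAB>pattern")
        motifs.append(IUPACMotif(name=parts[0].strip(), pattern=parts[1].strip()))
    return motifs


# ---------------------------------------------------------------------------
# TF co-factor overlap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TFTable:
    """Gene-symbol sets: TFs binding the promoter, and HIF1A interactors."""

    promoter_tfs: frozenset[str]
    interactors: frozenset[str]

    @staticmethod
    def _clean(symbols: Iterable[str]) -> frozenset[str]:
        return frozenset(s.strip().upper() for s in symbols if s.strip())

    @classmethod
    def from_symbols(cls, promoter_tfs: Iterable[str],
                     interactors: Iterable[str]) -> "TFTable":
        return cls(cls._clean(promoter_tfs), cls._clean(interactors))

    @classmethod
    def from_files(cls, promoter_path: str | Path,
                   interactor_path: str | Path) -> "TFTable":
        def load(path):
            return [
                ln for ln in Path(path).read_text().splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
        return cls.from_symbols(load(promoter_path), load(interactor_path))


def cofactor_overlap(t: TFTable) -> list[str]:
    """Promoter-binding TFs that are also validated HIF1A interactors, sorted.

    Raises on an empty input set, which signals a missing table rather
    than a biological absence of overlap.
    """
    if not t.promoter_tfs:
        raise ValueError("promoter TF set is empty — missing table?")
    if not t.interactors:
        raise ValueError("interactor set is empty — missing table?")
    return sorted(t.promoter_tfs & t.interactors)
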