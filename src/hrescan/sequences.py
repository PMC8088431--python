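"""Sequence containers, FASTA/BED I/O and coordinate conventions.

External citations of promoter regions use 1-based inclusive coordinates
(Ensembl style); all internal positions are sequence-local and 1-based.
BED output converts to the standard 0-based half-open convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: header dialect encoding a genomic region: species|chrom:start-end(strand)
_REGION_RE = re.compile(
    r"^(?P<species>[^|]+)\|(?P<chrom>[^:|]+):(?P<start>\d+)-(?P<end>\d+)"
    r"\((?P<strand>[+-])\)$"
)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval with a species label.

    Matches how promoter regions are cited (e.g. zebrafish trap1 upstream
    region, chromosome 3: 9,602,709-9,659,449).
    """

    species: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_header_suffix(self) -> str:
        return f"{self.species}|{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class PromoterSequence:
    """A named nucleotide sequence, optionally anchored to a genomic region.

    The sequence is stored uppercase over {A,C,G,T,N}; when a region is
    attached its span must equal the sequence length.
    """

    id: str
    seq: str
    region: GenomicRegion | None = None

    def __post_init__(self) -> None:
        bad = set(self.seq) - ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains illegal character(s): "
                f"{', '.join(sorted(bad))}"
            )
        if self.region is not None and self.region.length != len(self.seq):
            raise ValueError(
                f"region span {self.region.length} != sequence length "
                f"{len(self.seq)} for {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_sequence(raw: str, context: str = "") -> str:
    """Uppercase, map U->T (RNA input), and reject anything outside the alphabet."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise AlphabetError(
            f"illegal sequence character(s){where}: {', '.join(sorted(bad))}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N. An involution."""
    bad = set(seq.upper()) - ALPHABET
    if bad:
        raise AlphabetError(
            f"cannot complement character(s): {', '.join(sorted(bad))}"
        )
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _parse_region(header_id: str) -> GenomicRegion | None:
    m = _REGION_RE.match(header_id)
    if m is None:
        return None
    return GenomicRegion(
        species=m.group("species"),
        chrom=m.group("chrom"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        strand=m.group("strand"),
    )


def _validate_fasta_lines(text: str, path: str) -> None:
    seen_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            seen_header = True
        elif not seen_header:
            raise FastaParseError(
                f"{path}: line {lineno} precedes any '>' header: {stripped[:40]!r}"
            )
    if not seen_header:
        raise FastaParseError(f"{path}: no FASTA records found")


def read_fasta(path: str | Path) -> list[PromoterSequence]:
    """Read FASTA into :class:`PromoterSequence` records.

    Sequences are uppercased and U is normalized to T. A genomic region is
    parsed from headers of the form ``species|chrom:start-end(strand)``;
    other headers yield records without a region.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaParseError(f"{path}: empty file")
    _validate_fasta_lines(text, str(path))
    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        seq = normalize_sequence(str(rec.seq), context=f"record {rec.id!r}")
        records.append(
            PromoterSequence(id=rec.id, seq=seq, region=_parse_region(rec.id))
        )
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[PromoterSequence], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA.

    The region, when present, is encoded in the header using the same
    dialect that :func:`read_fasta` parses, so a round trip preserves it.
    """
    if not records:
        raise ValueError("no records to write")
    seq_records = []
    for p in records:
        header = p.region.to_header_suffix() if p.region is not None else p.id
        seq_records.append(SeqRecord(Seq(p.seq), id=header, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def extract_subregion(p: PromoterSequence, start_1based: int, end_1based: int) -> PromoterSequence:
    """Slice a sub-sequence in sequence-local 1-based inclusive coordinates.

    Genomic coordinates, when attached, are shifted assuming the stored
    sequence runs in forward genomic orientation.
    """
    n = len(p.seq)
    if not (1 <= start_1based <= end_1based <= n):
        raise IndexError(
            f"requested {start_1based}-{end_1based}, available 1-{n} in {p.id!r}"
        )
    sub = p.seq[start_1based - 1 : end_1based]
    region = None
    if p.region is not None:
        region = replace(
            p.region,
            start=p.region.start + start_1based - 1,
            end=p.region.start + end_1based - 1,
        )
    return PromoterSequence(
        id=f"{p.id}:{start_1based}-{end_1based}", seq=sub, region=region
    )


def feature_span(hit) -> tuple[str, int, int, str, str, float]:
    """Forward-coordinate span of a core hit or scored window, for BED.

    Returns (seq_id, start_1based, end_1based, name, strand, score_0_1).
    """
    # local import keeps the dependency one-way at class-definition time
    from .scanner import CoreHit, HREWindow

    if isinstance(hit, CoreHit):
        return (hit.seq_id, hit.pos, hit.pos + 4,
                f"core_{hit.pos}_{hit.strand}_{hit.variant}", hit.strand, 0.0)
    if isinstance(hit, HREWindow):
        start, end = hit.forward_span()
        score = hit.norm_score if hit.norm_score is not None else 0.0
        return (hit.core.seq_id, start, end,
                f"hre_{hit.core.pos}_{hit.core.strand}", hit.core.strand, score)
    raise TypeError(f"cannot write {type(hit).__name__} to BED")


def write_bed(hits: Iterable, path: str | Path) -> None:
    """Write core hits / windows as BED6 (0-based half-open).

    The score column is the normalized window probability rescaled to
    0-1000 and rounded; core hits without a score get 0.
    """
    with open(path, "w") as fh:
        for hit in hits:
            seq_id, start1, end1, name, strand, score = feature_span(hit)
            bed_score = int(round(max(0.0, min(1.0, score)) * 1000))
            fh.write(
                f"{seq_id}\t{start1 - 1}\t{end1}\t{name}\t{bed_score}\t{strand}\n"
            )
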