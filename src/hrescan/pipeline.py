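"""Full two-species analysis: scan both promoters, call conserved HREs.

Mirrors the promoter-study workflow: core-motif screen and PSFM scoring in
each species, then cross-species pairing of the confident windows, with an
optional supplementary-motif scan, all parameters echoed into every output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import yaml

from . import conserve, motifs, report, scanner, sequences
from .matrix import PSFM, illustrative_matrix, read_psfm

log = logging.getLogger("hrescan")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters, with per-parameter provenance.

    Precedence: CLI flag > config file > built-in default. ``sources``
    maps each field to where its value came from.
    """

    threshold: float | None = None      # None -> matrix's own threshold
    strand_mode: str = "both"
    flank_only: bool = False
    match: float = conserve.DEFAULT_MATCH
    mismatch: float = conserve.DEFAULT_MISMATCH
    gap: float = conserve.DEFAULT_GAP
    min_identity: float = conserve.DEFAULT_MIN_IDENTITY
    sources: Mapping[str, str] = field(default_factory=dict, compare=False)

    @classmethod
    def resolve(
        cls,
        config_file: str | Path | None = None,
        **overrides,
    ) -> "RunConfig":
        values: dict = {}
        sources: dict[str, str] = {}
        names = {f.name for f in fields(cls)} - {"sources"}
        for name in names:
            sources[name] = "default"
        if config_file is not None:
            loaded = yaml.safe_load(Path(config_file).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"{config_file}: expected flat key-value mapping")
            for k, v in loaded.items():
                if k not in names:
                    raise ValueError(f"{config_file}: unknown parameter {k!r}")
                values[k] = v
                sources[k] = "config-file"
        for k, v in overrides.items():
            if k not in names:
                raise ValueError(f"unknown parameter {k!r}")
            if v is not None:
                values[k] = v
                sources[k] = "cli"
        return cls(**values, sources=sources)

    def echo(self) -> dict:
        out = {}
        for f in fields(self):
            if f.name == "sources":
                continue
            src = self.sources.get(f.name, "default") if self.sources else "default"
            out[f.name] = f"{getattr(self, f.name)} [{src}]"
        return out

    def scan_config(self) -> scanner.ScanConfig:
        return scanner.ScanConfig(
            threshold=self.threshold,
            strand_mode=self.strand_mode,  # type: ignore[arg-type]
            flank_only=self.flank_only,
        )


@dataclass
class Summary:
    """Headline counts of a two-species run."""

    n_hits_a: int
    n_confident_a: int
    n_hits_b: int
    n_confident_b: int
    n_conserved: int
    pairs: list[conserve.ConservedPair]
    report_a: scanner.ScanReport
    report_b: scanner.ScanReport
    motif_hits: dict[str, int] = field(default_factory=dict)

    def format_table(self) -> str:
        lines = [
            "sequence\tcore_hits\tconfident",
            f"{self.report_a.seq_id}\t{self.n_hits_a}\t{self.n_confident_a}",
            f"{self.report_b.seq_id}\t{self.n_hits_b}\t{self.n_confident_b}",
            f"conserved_pairs\t{self.n_conserved}",
        ]
        for i, p in enumerate(self.pairs, start=1):
            lines.append(
                f"pair_{i}\t{p.window_a.core.seq_id}:{p.window_a.core.pos}"
                f"({p.window_a.core.strand})\t"
                f"{p.window_b.core.seq_id}:{p.window_b.core.pos}"
                f"({p.window_b.core.strand})\t"
                f"identity={p.alignment.identity:.3f}\tcore={p.window_a.core_seq}"
            )
        return "\n".join(lines)


def load_matrix(source: str | Path | None, threshold: float | None = None) -> PSFM:
    """Load a PSFM from TSV, or the bundled illustrative matrix for None
    or the literal name ``"illustrative"``."""
    if source is None or str(source) == "illustrative":
        m = illustrative_matrix()
    else:
        m = read_psfm(source)
    if threshold is not None:
        from dataclasses import replace
        m = replace(m, threshold=threshold)
    return m


def run_full_analysis(
    fasta_a: str | Path,
    fasta_b: str | Path,
    matrix: PSFM,
    cfg: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
    motif_file: str | Path | None = None,
) -> Summary:
    """Scan two promoters, call conserved HREs, optionally scan aux motifs.

    When ``outdir`` is given, writes per-species scan TSV/BED, a pairs
    TSV, and a plain-text summary. Raises (rather than exiting) on any
    stage failure; the CLI maps that to a non-zero exit.
    """
    recs_a = sequences.read_fasta(fasta_a)
    recs_b = sequences.read_fasta(fasta_b)
    seq_a, seq_b = recs_a[0], recs_b[0]
    for s in (seq_a, seq_b):
        if len(s.seq) < scanner.WINDOW_WIDTH:
            raise ValueError(
                f"sequence {s.id!r} is shorter than one scoring window "
                f"({len(s.seq)} < {scanner.WINDOW_WIDTH} bp)"
            )
    scan_cfg = cfg.scan_config()
    log.info("scanning %s (%d bp)", seq_a.id, len(seq_a.seq))
    rep_a = scanner.scan_promoter(seq_a, matrix, scan_cfg)
    log.info("scanning %s (%d bp)", seq_b.id, len(seq_b.seq))
    rep_b = scanner.scan_promoter(seq_b, matrix, scan_cfg)
    for rep in (rep_a, rep_b):
        log.info(
            "%s: %d core hits, %d windows, %d confident",
            rep.seq_id, rep.n_core_hits, rep.n_windows, rep.n_confident,
        )
    pairs = conserve.find_conserved(
        rep_a, rep_b,
        min_identity=cfg.min_identity,
        match=cfg.match, mismatch=cfg.mismatch, gap=cfg.gap,
    )
    log.info("%d conserved pair(s)", len(pairs))

    motif_counts: dict[str, int] = {}
    if motif_file is not None:
        motif_list = motifs.read_motif_tsv(motif_file)
        for s in (seq_a, seq_b):
            hits = motifs.scan_iupac(s, motif_list, cfg.strand_mode)  # type: ignore[arg-type]
            for h in hits:
                key = f"{s.id}:{h.motif}"
                motif_counts[key] = motif_counts.get(key, 0) + 1

    summary = Summary(
        n_hits_a=rep_a.n_core_hits, n_confident_a=rep_a.n_confident,
        n_hits_b=rep_b.n_core_hits, n_confident_b=rep_b.n_confident,
        n_conserved=len(pairs), pairs=pairs,
        report_a=rep_a, report_b=rep_b, motif_hits=motif_counts,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        echo = cfg.echo()
        echo["matrix"] = matrix.name
        for tag, rep in (("a", rep_a), ("b", rep_b)):
            rep.parameters.update(echo)
            report.write_scan_tsv(rep, outdir / f"scan_{tag}.tsv")
            sequences.write_bed(rep.windows, outdir / f"scan_{tag}.bed")
        report.write_pairs_tsv(pairs, outdir / "pairs.tsv", params=echo)
        (outdir / "summary.txt").write_text(summary.format_table() + "\n")
    return summary
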