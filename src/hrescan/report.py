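"""Tabular report I/O: scan TSVs, conserved-pair TSVs, parameter echoes.

Every TSV carries its generating parameters as ``# key=value`` header
lines so a run is fully reconstructable from any output file.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path
from typing import Mapping

import pandas as pd

from .conserve import ConservedPair
from .scanner import CoreHit, HREWindow, ScanReport

SCAN_COLUMNS = [
    "seq_id", "core_pos", "strand", "variant", "window_start", "window_end",
    "window_seq", "raw_prob", "norm_score", "confident", "unscorable",
]

PAIR_COLUMNS = [
    "seq_id_a", "pos_a", "strand_a", "window_a",
    "seq_id_b", "pos_b", "strand_b", "window_b",
    "identity", "score", "core_match",
]


def _echo_header(params: Mapping) -> str:
    return "".join(f"# {k}={params[k]}\n" for k in sorted(params))


def scan_report_frame(report: ScanReport) -> pd.DataFrame:
    rows = []
    for w in report.windows:
        start, end = w.forward_span()
        rows.append({
            "seq_id": w.core.seq_id,
            "core_pos": w.core.pos,
            "strand": w.core.strand,
            "variant": w.core.variant,
            "window_start": start,
            "window_end": end,
            "window_seq": w.window_seq,
            "raw_prob": w.raw_prob,
            "norm_score": w.norm_score,
            "confident": w.confident,
            "unscorable": w.raw_prob is None,
        })
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def write_scan_tsv(report: ScanReport, path: str | Path) -> None:
    params = dict(report.parameters)
    params.update(
        seq_id=report.seq_id,
        n_core_hits=report.n_core_hits,
        n_windows=report.n_windows,
        n_boundary_dropped=report.n_boundary_dropped,
        n_unscorable=report.n_unscorable,
        n_confident=report.n_confident,
    )
    frame = scan_report_frame(report)
    with open(path, "w") as fh:
        fh.write(_echo_header(params))
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_scan_tsv(path: str | Path) -> ScanReport:
    """Rebuild a ScanReport from its TSV (counts from the header echo)."""
    text = Path(path).read_text()
    params: dict[str, str] = {}
    body_lines = []
    for ln in text.splitlines():
        if ln.startswith("# ") and "=" in ln:
            k, v = ln[2:].split("=", 1)
            params[k.strip()] = v.strip()
        else:
            body_lines.append(ln)
    frame = pd.read_csv(StringIO("\n".join(body_lines)), sep="\t")
    windows = []
    for _, row in frame.iterrows():
        unscorable = bool(row["unscorable"])
        windows.append(HREWindow(
            core=CoreHit(
                seq_id=str(row["seq_id"]),
                pos=int(row["core_pos"]),
                strand=str(row["strand"]),
                variant=str(row["variant"]),
            ),
            window_seq=str(row["window_seq"]),
            raw_prob=None if unscorable else float(row["raw_prob"]),
            norm_score=None if unscorable else float(row["norm_score"]),
            confident=bool(row["confident"]),
        ))

    def count(key: str, fallback: int) -> int:
        return int(params[key]) if key in params else fallback

    n_windows = count("n_windows", len(windows))
    return ScanReport(
        seq_id=params.get("seq_id", windows[0].core.seq_id if windows else "?"),
        n_core_hits=count("n_core_hits", n_windows),
        n_windows=n_windows,
        n_boundary_dropped=count("n_boundary_dropped", 0),
        n_unscorable=count("n_unscorable", sum(w.raw_prob is None for w in windows)),
        n_confident=count("n_confident", sum(w.confident for w in windows)),
        windows=windows,
        parameters={k: v for k, v in params.items() if not k.startswith("n_")
                    and k != "seq_id"},
    )


def pairs_frame(pairs: list[ConservedPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append({
            "seq_id_a": p.window_a.core.seq_id,
            "pos_a": p.window_a.core.pos,
            "strand_a": p.window_a.core.strand,
            "window_a": p.window_a.window_seq,
            "seq_id_b": p.window_b.core.seq_id,
            "pos_b": p.window_b.core.pos,
            "strand_b": p.window_b.core.strand,
            "window_b": p.window_b.window_seq,
            "identity": p.alignment.identity,
            "score": p.alignment.score,
            "core_match": p.core_match,
        })
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def write_pairs_tsv(
    pairs: list[ConservedPair], path: str | Path, params: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        if params:
            fh.write(_echo_header(params))
        pairs_frame(pairs).to_csv(fh, sep="\t", index=False, lineterminator="\n")
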