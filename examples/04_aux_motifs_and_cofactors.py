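"""Supplementary hypoxia motifs and the TF co-factor overlap.

Scans a synthetic promoter for user-defined IUPAC motifs (the core RCGTG
plus generic examples), then intersects a promoter-binding TF table with
a list of validated HIF1A interactors to propose co-factors.
"""

import hrescan as hs

cfg = hs.SimulationConfig(length=3000, n_planted=3, seed=5)
promoter, _ = hs.plant_sites(
    hs.generate_background(cfg), hs.illustrative_matrix(), cfg
)

motifs = [
    hs.IUPACMotif("hre_core", "RCGTG"),     # the canonical HIF1 core
    hs.IUPACMotif("ebox", "CACGTG"),        # generic example patterns
    hs.IUPACMotif("gc_box", "GGGCGG"),
]
hits = hs.scan_iupac(promoter, motifs, "both")
for name in sorted({h.motif for h in hits} | {m.name for m in motifs}):
    n = sum(h.motif == name for h in hits)
    print(f"motif {name:<9} occurrences: {n}")

promoter_tfs = [
    "SP1", "HDAC1", "SIN3A", "MAX", "MYC", "EGR1", "E2F1", "GATA1",
    "GATA2", "NFYA", "NFYB", "STAT3", "STAT5A", "JUN", "FOS", "CREB1",
    "ATF2", "ELK1", "ETS1", "KLF4", "KLF5", "NRF1", "YY1", "TBP", "CTCF",
    "REST", "ZNF143", "USF1", "USF2", "TFAP2A", "RELA",
]
interactors = ["SP1", "HDAC1", "SIN3A", "MAX", "MYC", "EP300", "ARNT", "VHL"]
table = hs.TFTable.from_symbols(promoter_tfs, interactors)
overlap = hs.cofactor_overlap(table)
print(f"\n{len(promoter_tfs)} promoter-binding TFs x {len(interactors)} "
      f"validated interactors -> {len(overlap)} candidate co-factors:")
print("  " + ", ".join(overlap))
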