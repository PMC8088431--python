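"""Build a frequency matrix from training windows and score variants.

Estimates a PSFM from a small alignment of 33-bp HRE windows, then shows
how the normalized probability score decays as bases are mutated away
from the consensus — the basis of the confidence filter.
"""

import hrescan as hs
from hrescan.matrix import ILLUSTRATIVE_CONSENSUS

# a toy training alignment: the consensus plus single-base variants
train = [
    ILLUSTRATIVE_CONSENSUS,
    ILLUSTRATIVE_CONSENSUS,
    "A" + ILLUSTRATIVE_CONSENSUS[1:],
    ILLUSTRATIVE_CONSENSUS[:32] + "G",
]
m = hs.build_psfm(train, pseudocount=0.5)
print(f"matrix width {m.width}, consensus {m.consensus()}")

window = m.consensus()
for n_mut in range(4):
    mutated = window
    for i in range(n_mut):          # mutate leading flank positions
        mutated = mutated[:i] + ("C" if mutated[i] != "C" else "G") + mutated[i + 1:]
    s = hs.score_window(m, mutated)
    print(f"{n_mut} flank mutation(s): raw {s.raw:.3e}  normalized {s.norm:.4f}")

print("\nA window containing N is unscorable:",
      hs.score_window(m, "N" + window[1:]))
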