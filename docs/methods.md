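# Methods

## The scanning model

An HRE candidate is an occurrence of the HIF1 core motif [A/G]CGTG. The
scanner reports every occurrence on the forward strand and, by default, on
the reverse strand as well (the core consensus RCGTG is conventionally
treated as strand-symmetric; forward-only mode is available for comparing
against single-strand counts). Overlapping occurrences are all reported —
the preliminary screen counts raw positive hits, with no greedy masking.

Each hit seeds a 33-bp window: 8 bases 5′ of the core, the 5-bp core, and
20 bases 3′, read on the hit strand. Hits whose window would run past
either sequence end are dropped and counted (`n_boundary_dropped`), so
`n_core_hits = n_windows + n_boundary_dropped` always holds. Windows
containing N are kept but flagged unscorable and never counted confident.

The window score is the product over positions of the PSFM frequency of
the observed base. Two scales are reported: the raw probability, and the
raw probability divided by the maximum attainable product (the consensus
window), so that normalized score 1.0 means "consensus" for any matrix and
confidence thresholds transfer between matrices. A flank-only mode scores
just the 28 flank positions, for matrices whose core is constrained by
construction. Ties at the threshold pass (closed threshold ≥).

## Parameters

| parameter | default | meaning |
|---|---|---|
| window geometry | −8 / +20 | flank extents around the 5-bp core (bp); fixed by the 33-bp window definition |
| `threshold` | 0.05 | normalized-score cutoff for a confident HRE |
| `pseudocount` | 0.5 | additive smoothing when building a PSFM from counts |
| `background` | uniform 0.25 | background base model carried with the matrix |
| `strand_mode` | both | scan forward strand only, or both |
| `match/mismatch/gap` | +1 / −1 / −2 | global-alignment scores, linear gap |
| `min_identity` | 0.7 | alignment identity floor for a conserved pair |

No published numeric cutoff exists for the "significant probability
score", so the default τ = 0.05 is a package decision, always echoed into
report headers, and every run is reconstructable from any output file
(CLI flag > config file > default, with provenance recorded per
parameter).

## The normalized score is log-steep: thresholds for diverged sequences

Every base that departs from the consensus multiplies the normalized score
by fᵢ(base)/fᵢ(consensus). For the illustrative matrix (flank consensus
probability 0.7, others 0.1) that factor is ≈ 0.143 per substitution:
one flank mismatch scores 0.143, two score 0.020, three 0.003. The default
τ = 0.05 therefore accepts at most one flank substitution and suits scans
for near-consensus sites in a single genome.

Windows that are genuine HREs but drawn from the motif distribution itself
(≈ 30% mismatch per flank position), or additionally diverged between
species (10% per base), sit orders of magnitude lower. For such studies the
package provides `divergence_threshold(matrix, k)`: the score of a window
carrying `k` worst-case flank substitutions (the less-favoured core purine
is also admitted). The cross-species analyses here use `k = 16`, the mean
expected mismatch count of a matrix-drawn, 10%-diverged window
(28 × (0.3 + 0.1·0.7) ≈ 10.4) plus ~2.5 standard deviations — low enough to
retain essentially all true sites while random background windows
(≈ 21 expected mismatches, normalized score ~10⁻¹⁸) remain separated by
several orders of magnitude. The derivation is analytic, from the
generator's divergence model, not a fitted constant.

## The bundled illustrative matrix

The published matrix behind the original promoter study is not available,
so the package bundles an explicitly synthetic stand-in built from the
generator's own settings: a fixed 33-bp consensus
(`TCTAGCATACGTGCTCAAGTCTCATGGTAGTCA`, chosen to contain no secondary
RCGTG match on either strand), flank positions at consensus probability
0.7, core positions near-deterministic with the purine split 0.58/0.39
between A and G. It demonstrates and calibrates the mechanism; any real
analysis should supply a trained matrix (`build-matrix` derives one from a
FASTA of equal-length validated windows with the pseudocount formula
(count + p)/(n + 4p)).

## Conservation calling

At 33-bp scale an exact global aligner is simpler and stricter than a
heuristic local search, so confident windows (not whole promoters) are
aligned with Needleman–Wunsch under a linear gap penalty. Traceback ties
break deterministically (diagonal, then up, then left), making outputs
byte-reproducible. Identity is matches over aligned columns excluding
terminal gaps; N matches nothing. A conserved pair needs identity ≥
`min_identity` and byte-identical cores after strand orientation; windows
are matched one-to-one greedily by identity (then score, then coordinates),
which prevents a single window from claiming several partners and yields
discrete region pairs.

## The synthetic generator

Backgrounds are order-0 i.i.d. draws from a configurable base composition
(a first-order Markov background would be a natural extension; promoter
architecture such as CpG islands or TATA positioning is explicitly out of
scope). Planted windows are drawn position-wise from the matrix with the
core forced legal (first base from the renormalized A/G frequencies, then
CGTG), written **over** the background at uniformly chosen positions at
least `min_spacing` apart — overwriting keeps all other coordinates
stable. Planting is forward-strand by default; random-strand mode
exercises both-strand scanning. In the two-species mode, backgrounds are
independent, a `shared_fraction` of sites receives the same drawn window
in both species — the species-B copy with flank bases substituted at
`flank_divergence` per base (core preserved, matching the strong
constraint on the core in real HREs) — and the remaining sites are private
to alternating species. Ground truth records every placement, and the
closed form

E[background hits] = (L − 4) · (p_A + p_G) p_C p_G p_T p_G  (per forward strand,
plus the reverse-complement motif term for both-strand scans)

provides an analytic calibration target for the scanner.

All randomness flows through a single NumPy PCG64 generator seeded from
`SimulationConfig.seed`, so every simulation is reproducible cross-platform.

Default study conditions: 5,500-bp sequences (a −5000/+500 promoter
window), uniform composition, 10 planted sites ≥ 50 bp apart, 10% flank
divergence, half the sites shared.

## What the simulations do and do not show

Passing the planted-recovery and conservation tests shows the pipeline is
correct and calibrated under its own generative model: i.i.d. background,
independently diverging flank bases, perfectly conserved cores, and a
scoring matrix matched to the planting distribution. Real promoters
violate all of these to some degree (composition heterogeneity, repeats,
indels within windows, core turnover, and a motif model that never matches
the true binding preferences exactly), so sensitivity/specificity measured
here are upper bounds, not estimates for genomic data. Reproducing
published hit counts for real loci additionally requires the user to
supply the same genomic interval and an equivalent trained matrix; the
report exposes forward-only and both-strand counts, pre- and post-boundary
filtering, so either counting convention can be compared.

## Numerical and edge-case choices

- Scores are products of ≤ 33 frequencies; double precision underflows
  only below ~10⁻³⁰⁸, far beyond any useful threshold, so no log-space
  arithmetic is needed.
- Matrix rows must sum to 1 within 1e−9; TSV round-trips preserve
  frequencies to ~1e−12 (`%.12g`).
- Consensus ties break in A,C,G,T order; matrices read from files accept
  counts (normalized with the configured pseudocount) or ready frequencies.
- Lowercase (soft-masked) input is uppercased and scanned; U is normalized
  to T; any other character is a hard error rather than a silent N.
- Coordinates: 1-based inclusive internally and in reports (Ensembl
  style); BED output is 0-based half-open with the normalized score
  rescaled to 0–1000.
- Infeasible planting configurations (sites cannot fit at the requested
  spacing) fail fast at configuration time.

## Problem sizes used in validation

The validation suite uses 1,000 × 1-kb sequences for scanner/enumeration
agreement, 500 × 2-kb backgrounds for rate calibration (4σ band on the
mean), 10 planted sites in 5.5 kb for recovery, exhaustive
alignment-space search on words ≤ 6 bp under three scoring schemes, and
5-site species pairs for conservation recovery — sizes at which the
independent oracles (enumeration, closed forms, exhaustive search) are
exact and fast.
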