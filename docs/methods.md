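# Methods

`agoblocks` re-implements, at desk scale, a primary-sequence analysis of the
plant ARGONAUTE (AGO) protein family: the discovery of short conserved
amino-acid *blocks* (8–50 residues) shared across family members, the
per-protein linear *architecture* of those blocks, and a set-theoretic
consensus calculus over the four plant AGO clades (AGO1/10, AGO2/3/7,
AGO4/6/8/9, AGO5). This note records the models, the parameters that
matter, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Block models and scanning

A block is a position probability matrix (PPM) over the 20 standard
residues, with a uniform background by default. The packaged block table
carries the 50 plant-AGO consensus strings with their domain components
(PIWI, PAZ, DUF1785); a PPM is rebuilt from each consensus by placing a
configurable match probability *m* (default 0.9) on the consensus residue
of every column and spreading the remainder uniformly — the printed
consensus is all the sequence-level information the table preserves, and
this reconstruction makes that assumption explicit rather than hiding it.

Scanning is MAST-style: every window of every protein is scored with the
log₂ odds `Σ_j log2(p_j(a_j)/b(a_j))`. Scores are discretized to a lattice
of 1/100 bit per column, and the exact null distribution of the lattice
score under the background is computed by dynamic-programming convolution;
a hit's p-value is the tail mass at its score. Windows with p ≤ 1e-4
(configurable) become candidates; candidates are accepted greedily by
ascending p-value (ties: smaller start, then smaller block id), discarding
any candidate overlapping an accepted hit. Greedy selection rather than
optimal interval scheduling is deliberate: it is deterministic, near-optimal
for sparse hits, and oracle-tested against exhaustive subset search on toy
cases. The masked residue `X` scores 0 everywhere (it contributes background
probability), which keeps likelihoods well defined without inventing residue
frequencies. Multiple non-overlapping copies of one block are allowed, which
is how N-terminal glycine/arginine repeat runs are counted.

The N-terminal G/R repeat block (block 43) is low-complexity — 13 of its 15
consensus positions are glycine — so when its model is scanned in isolation,
glycine-rich stretches of unrelated blocks reach the generic 1e-4 threshold
by composition alone. Repeat counting therefore defaults to the stringent
end of the scanning settings, p ≤ 1e-6 (`GR_P_THRESHOLD`); true copies sit
many orders of magnitude below this, so the stricter cut costs no
sensitivity. The "N-terminal region" is the first 25% of the protein by
default; the fraction is a parameter because the term has no standard
quantitative definition.

## Block discovery (ZOOPS EM)

Discovery fits one motif at a time under the ZOOPS model — each sequence
carries zero or one occurrence, with prior site probability γ shared across
sequences — and repeats up to `max_motifs` (default 50) rounds over a width
grid within [8, 50]. Per round:

1. **Seeding** (deterministic): candidate substrings are ranked by the
   number of substrings across the family within Hamming distance ⌈w/4⌉.
   The candidate pool is primed with windows that occur *identically* more
   than once (at realistic conservation, block instances collide exactly;
   background windows essentially never do), capped at half the pool so one
   repeat-rich region cannot crowd out everything else, and topped up with
   a seeded random sample. The five best-ranked, pairwise-dissimilar
   (Hamming > ⌈w/4⌉) substrings seed EM at match probability 0.7.
2. **EM**: the E-step computes each sequence's posterior over
   {no site} ∪ {offsets}; the M-step re-estimates columns with pseudocount
   0.01 and updates γ. The observed-data log-likelihood (reported relative
   to the background-only model, so it is exactly 0 at γ→0) is
   non-decreasing; iteration stops at relative change < 1e-4 or 100
   iterations.
3. **Phase refinement**: EM converges to shifted local optima when a seed
   straddles a block boundary, so the best candidate is hill-climbed over
   column phase (re-seeding from its ML-site windows shifted ±1..3 and
   refitting, keeping improvements).
4. **Core trimming**: columns are trimmed to the best contiguous run with
   information content above 1.0 nat, weighted by the non-X coverage at the
   ML sites (columns fitted over mostly-masked positions carry few real
   counts and would otherwise look informative). This shrinks off-grid-width
   fits to the true block span and splits fusions of adjacent blocks across
   variable spacers. The trimmed model is refit once at its new width.
5. **Stop rule and masking**: a motif is accepted while its significance
   `-(LLR − 0.5·(19w)·ln n)` is negative, with *n* the number of sequences —
   the independent units of the ZOOPS model (one zero-or-one site decision
   each). Using the window count for *n* instead would overstate the sample
   size by ~3 orders of magnitude and push real blocks confined to one small
   clade below the detection floor. On i.i.d. background data the rule
   accepts nothing across seeded runs. An accepted motif's ML site is masked
   with `X` in every contributing sequence (site posterior > 0.5), so no
   (sequence, offset) site is ever claimed twice. Because seeding is
   re-randomized per round, a barren round can reflect unlucky seeding
   rather than exhausted signal; the search tolerates 3 consecutive barren
   rounds before stopping.

This replaces the E-value machinery of production motif finders with a
deterministic, testable criterion; it is not an implementation of MEME's
objective function.

## Consensus calculus

Presence is boolean per (protein, block) — copies collapse. A clade's
*block consensus sequence* is the set of blocks present in at least 90% of
members, with "at least" read literally as ≥ on the exact fraction (9/10
qualifies at 0.90). The consensus is linearized by the median rank of each
block's first occurrence among the member architectures containing it, with
ties broken by mean start position, then block id — the source material
never states how member architectures were merged into one ordered
consensus, so this ordering is this package's construction, validated
against planted orders. *Clade-specific blocks* use raw presence (at least
one member of exactly one clade), not the 90% consensus. The *group
consensus* ("Viridiplantae consensus" construction) keeps blocks present in
at least k of the supplied clade consensuses (default k = 2 of 4). Ordered
consensuses are segmented into maximal runs of one domain class
(A, B, DUF1785, PAZ, PIWI; class map configurable) and matched against the
packaged series catalog by exact ordered identity, falling back to
"<class>-new".

## Domain preprocessing

Proteins lacking a PAZ or a PIWI annotation are discarded (DUF1785 is not
required). For kept proteins, amino-acid interval [s, e] (1-based,
inclusive — the Pfam batch convention; internal code is 0-based half-open
and converts at the boundary) maps to nucleotide interval [3s−2, 3e].
Overlapping or bookended annotations of the requested domains are merged
(union) before extraction — taking the union rather than the best-scoring
hit is conservative and deterministic — and segments are concatenated in
coordinate order, preserving the protein's linear layout for downstream
architecture analysis.

## Functional-motif annotation

The prolyl-hydroxylation signature is matched literally as x-P-G and
reported at the proline. Its association with block 8 is a proximity filter
(within 5 residues of a block-8 occurrence by default) rather than a
containment requirement, because the printed block-8 consensus ends just
before the glycine. The catalytic-triad check reads the residues at
configurable within-block offsets of blocks 5, 3 and 2 (defaults: first D,
first D, first H of the packaged consensuses — the table's typography
marking the exact residues does not survive into machine-readable form, so
the offsets ship as configuration) and classifies the triple as DDH, DDD,
other, or incomplete.

## Synthetic benchmark

The generator emulates the study frame: four clades of 44, 55, 28 and 58
members (185 proteins; the published phylogeny had 206 genes of which 21 —
bryophyte, gymnosperm and incomplete sequences — were excluded before block
analysis). Each clade's true architecture is its packaged consensus series
expanded to a block list; the rarely present clade-specific blocks (45/48
for AGO2/3/7; 37/42/46/50 for AGO4/6/8/9) are inserted at plausible
positions with presence 0.30, block 38 at 0.5 near the AGO4/6/8/9
C-terminus, and block 43 is prepended in Uniform{0..8} consecutive copies
in the three clades that carry it. Defaults: presence 0.95 per consensus
block (just above the 90% rule), within-block conservation 0.95,
uniform-background spacers of 5–15 residues between blocks (uniform
background keeps the analytic p-value checks exact; Robinson–Robinson-style
frequencies are configurable). Presence is sampled independently per block;
there is no rearrangement noise, no indels inside blocks, and no
phylogenetic correlation between members. Coding sequences are uniform
random synonymous codons; domain annotations span first-to-last planted
block of each tag, and a corruption rate deletes PAZ or PIWI annotations to
exercise the canonical-domain filter.

All randomness flows from one seed through per-stage substreams, so every
stage is reproducible in isolation and identical seeds give byte-identical
outputs (the pipeline report contains no timestamps for the same reason).

**What passing tests show — and do not.** Recovery oracles are *realized*
truth: because presence is sampled, a planted block can legitimately fall
below the 90% consensus for a given seed, so the reference consensus is the
planted architecture restricted to blocks whose realized presence reaches
the threshold (deduplicated at first occurrence, since presence-based
consensus cannot represent the duplicate appearances of blocks 12 and 3 in
two catalog series). A discovered motif recovers a planted block when the
shorter consensus aligns ungapped inside the longer with at most ⌈len/10⌉
mismatches and covers ≥ 60% of the planted width; the repeat block is
excluded from discovery targets (its tandem copies make every rotation of
the pattern equally conserved, and it is recovered by scanning instead).
None of this demonstrates performance on real proteomes, where blocks drift
in width, spacers are compositionally biased, and domain annotations carry
their own errors.

**Problem sizes.** The acceptance checks run discovery on the full
185-protein family: at half scale the shortest single-clade blocks
(width 8–11, present in ~20 sequences) fall below the BIC detection floor
for statistical rather than implementation reasons. A full discovery run is
minutes-scale on one CPU; scanning, consensus and annotation are seconds.

## Known limitations

- The ZOOPS model finds one copy per sequence per round; tandem repeats are
  handled downstream by the scanner, and a long repeat run absorbs several
  discovery rounds as rotated duplicates (the 50-motif cap makes this
  benign on the default family, but a repeat-dominated input could exhaust
  it).
- Scanning has no composition-adjusted or gapped scoring; the uniform
  background overstates significance for biased real sequences.
- The 90% threshold comparison uses floating-point division; the documented
  boundary case (9/10) is exact in binary and tested, but thresholds that
  are not exactly representable could in principle flip a boundary block.
- Group labels are inputs (two-column table, or nearest labeled exemplar by
  patristic distance on a user tree); the package does not build
  phylogenies.
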