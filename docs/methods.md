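# Methods

## The problem and the model

A permuted non-coding RNA gene is genomically contiguous, but the mature
transcript's 5′/3′ termini are relocated relative to the canonical
architecture of its RNA family; end-to-end ligation of one genomic block
[A, D) produces a mature circle that restores the canonical motif order.
`permacirc` models the three lines of computational evidence for such a gene:

1. **Sequence/structure**: the family's few invariant motifs (a GNAR
   tetraloop, a helix-8b element) co-occur in a window with high folding
   potential.
2. **Junction reads**: RNA-Seq reads that cross the ligation point align
   with a soft clip whose sequence matches the distant terminus, defining
   the acceptor/donor pair (A, D) exactly.
3. **Processing**: the precursor's leader and trailer can pair into a
   bulge-helix-bulge (BHB), the substrate of the archaeal tRNA splicing
   endonuclease; the cuts it would place inside the two bulges must coincide
   with A and D, since the ligated junctions observed in such genes are
   identical across reads.

## Coordinates and conventions

All internal coordinates are 0-based half-open; GFF3 (1-based closed) and
BED (0-based half-open) conversions happen only in the writers. Sequences
are held in DNA alphabet (U→T on input). The acceptor A is the mature 5′
terminus; the donor D is one past the mature 3′ terminus; circle length is
D − A.

## Read processing

* **Quality trimming** interprets the "limit 0.05" parameter as Mott-style
  max-sum trimming: each Phred score becomes an error probability
  p = 10^(−Q/10) and the retained read is the contiguous stretch maximizing
  Σ(0.05 − p_i), empty when no positive-sum stretch exists. Ties prefer the
  longer, then leftmost stretch. Reads with more than 2 ambiguous bases
  after trimming are discarded; applying the ambiguity cap *after* trimming
  is a deliberate choice (the alternative ordering is not documented
  anywhere authoritative).
* **Adapter trimming** removes the longest read suffix matching an adapter
  prefix with overlap ≥ 3 and mismatch fraction ≤ 0.1.
* **Length filter**: ≥ 15 nt.
* **Alignment** is seed-and-extend: exact 12-mer seeds from a genome hash
  index select candidate windows (merged seed diagonals padded by two seed
  lengths), and each window is resolved by an exact local affine-gap (Gotoh)
  alignment using Biopython's `PairwiseAligner` — match +1, mismatch −4, and
  a gap of length k costing 6 + k (the "mismatch cost 4" setting of the
  original mapping; gap costs are our configurable choice, since only the
  mismatch cost is documented). The best alignment and all co-optimal
  placements are reported; unaligned read ends are soft clips. Because the
  extension is exact within its window, the reported score equals full
  Smith-Waterman whenever a seed exists — the oracle-equivalence test
  checks this against an independent pure-Python DP.

## Junction calling

Only reads with a *unique* best placement vote (repeat-driven co-optimal
placements are excluded). For a 3′-side clip of length ≥ 8 on an alignment
ending at D, the clip is matched against the genome within 1,000 nt
upstream; a unique best-matching start A with ≤ 1 mismatch casts a vote for
(A, D). 5′-side clips are handled symmetrically (clip must end at D while
the alignment starts at A). Identical votes accumulate; votes for
non-identical pairs are reported separately and never merged — coordinate
discordance is biologically meaningful for a ligation mechanism that
requires precisely defined termini. A junction needs ≥ 2 identical votes by
default.

**TSS**: argmax of strand-aware 5′-read-start counts over the 60 nt upstream
of A, reported only if the peak is unique and holds ≥ 50% of the window's 5′
starts. **TATA**: best exact match of the promoter pattern (default TTAATA)
fully inside the 40 nt upstream of the TSS, nearest match winning ties. The
"n nt upstream" anchor is ambiguous in prose, so the report emits both
conventions (from the motif's 3′ base and from its 5′ base); the primary
offset is TSS − motif_end.

## BHB detection

Windows of ±18 nt around A (leader side, strand1) and D (trailer side,
strand2) are exhaustively scanned for the geometry
outer1(≥2 bp) · bulge1(3 nt) · central(4 bp) · bulge2(3 nt) · outer2(≥2 bp),
paired antiparallel with G-U wobble allowed; each strand carries its bulge
immediately 5′ of its central-helix segment, which makes the enumeration
symmetric under swapping the strands. Outer helices are maximal runs. All
configurations are emitted, ranked by total paired bases, ties by distance
of predicted cleavage from the observed termini.

**Cleavage convention**: the endonuclease cut falls after the
`cut_offset`-th bulge nucleotide (5′→3′ on its own strand); published
figures place the cut within the 3-nt bulge but do not fix the position
textually, so `cut_offset ∈ {1, 2}` is configurable (default 2) and is a
single shared constant between the detector and the synthetic generator.

**Detection vs enumeration.** The raw enumeration is deliberately
permissive: on dinucleotide-shuffled 36-nt flank pairs some BHB-shaped
configuration exists ~20% of the time (with ~37.5% per-base pairability,
≈0.2 expected configurations per null pair). The pipeline's *detection
event* — what the report and the null test score — is a configuration whose
predicted cleavage sites equal the observed junction termini
(`validate_junction_vs_bhb`), whose null probability is ~4 × 10⁻⁴. This
mirrors the biological claim: not "some helices exist near the junction" but
"endonuclease processing of this motif would produce exactly the observed
circle".

## Folding machinery

Folding potential is maximum base pairing (Nussinov DP, numba-compiled
fill, deterministic outermost-first traceback preferring the closing pair on
ties), not thermodynamics: it is parameter-free and exhaustively verifiable
on short sequences, and an energy-model backend could replace it behind the
same contract. The hairpin constraint is ≥ 3 unpaired loop bases, which
makes a tetraloop representable. G-U pairs are allowed by default everywhere
(structure-preserving G-C→G-U substitutions are characteristic of this RNA
family) but configurable per call. Note one asymmetry: maximum pairing is
invariant under reverse complementation only for Watson-Crick rules (a G-U
pair maps to an unpairable A-C), so the symmetry property is tested with
wobble disabled.

`pairing_fraction` = 2·pairs/length of a window; random RNA folds densely
under maximum pairing (typical fractions 0.7–0.8), so the scan threshold
(default 0.5) is a weak gate and specificity comes from requiring both
family motifs on one strand. The tetraloop context check (loop unpaired, ≥ 2
closing pairs) is meaningful on compact hairpin-sized windows; in large
windows maximum pairing recruits loop bases into long-range pairs.

## The synthetic generator

`build_locus` assembles
flank · TATA · spacer(= tata_offset) · leader(L) · circle(C) · trailer ·
spacer · C/D-box-like gene · flank, with i.i.d. background at configurable
GC. The leader's 3′ region and trailer's 5′ region carry a planted BHB whose
bulges are positioned so the shared cleavage convention maps the cuts
exactly onto A and D; a 5-bp hairpin with a GNAR loop and a realization of
the configured helix-8b pattern are planted inside the circle. The helix-8b
default (`RGGNGCAGGC`) is a synthetic placeholder — the real consensus is
not a published string — and the generator plants whatever pattern the
configuration specifies, keeping generator and detector symmetric.

Boundary bases around every planted helix are constrained (by construction
plus targeted resampling) so that no helix can extend by chance and the
junction is "sharp": the genome bases immediately outside A and D differ
from the corresponding circle-internal bases for two positions. The former
keeps the planted BHB the unique maximal configuration at its coordinates;
the latter prevents local alignments of junction-spanning reads from
extending across the ligation point by coincidental matches, which would
systematically shift every vote by the same amount. Sharp termini are part
of what the generator emulates — a locus whose observed junctions are
identical — not a convenience; diffuse-boundary loci are outside its scope.

Precursor reads are substrings of [TSS, trailer end); a configurable
fraction (default 0.5) starts exactly at the TSS, modelling intact
primary-transcript 5′ ends in small RNA libraries (5′-monophosphate-
dependent adapter ligation), and the rest start uniformly. A purely uniform
start model cannot support TSS calling from 5′-start pileups — the upstream
profile would be flat — so the anchored fraction is what makes the
generator's TSS recoverable, and its value trades off realism of
fragmentation against promoter signal strength. Circular reads are
substrings of the doubled circle string with start uniform in [0, C);
read_len < C keeps every read single-crossing. Substitution errors are
i.i.d.; qualities are constant Phred (default Q40) or a linear ramp. With a
minimum anchor m per junction side, the junction-spanning fraction of
circular reads is (R − 2m + 1)/C in expectation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: indels and quality-dependent error spectra, PCR
duplicates, strand bias, transcription start heterogeneity, partially
processed intermediates, expression of the C/D box locus (it is annotated
but silent, so its read count is 0 in synthetic runs), and multi-locus or
trans-chimeric junctions.

## Problem sizes and defaults

The standard geometry is a 309-nt circle, 23-nt leader, TATA offset 26,
TTAATA box — the scale of the motivating gene family. The recovery suites
run 20 random seeds with C ∈ [80, 400] and L ∈ [5, 40] at 30× depth and
75-nt reads (C ∈ [150, 400] for the 1%-error suite, where very small circles
leave few clean junction anchors); the whole suite and the acceptance script
each complete in well under a minute per stage on one CPU. Generator
feasibility bounds: L ≥ cut_offset + outer_helix + 1 (the leader must host
one BHB arm plus one background base) and C large enough for both BHB arms
plus the planted motifs (~45 nt minimum at default settings).

## Design choices where the design was open

* Alignment gap costs (6 + k per k-gap) and the seed length (12) are
  configurable; 12-mers are effectively unique at synthetic-genome scale.
* Candidate windows: 400/50 window/step sized to a ~300-nt gene;
  `combined_score` adds a flat 0.25 bonus per required motif class present.
* Feature read counts use the alignment-midpoint rule — the simplest
  unambiguous assignment for short reads over compact loci.
* Maximal-helix semantics in `enumerate_duplex_helices` are strictly
  per-register (a helix is maximal iff not extendable); fully complementary
  strands therefore also yield shorter shifted-register helices, and the
  brute-force oracle uses the same definition.
* `quality_trim` tie-breaking (longest, then leftmost) is shared exactly
  with its oracle via identical prefix-sum arithmetic.

## Known limitations

* The aligner is exact only within seeded windows: a read with no exact
  12-mer on either strand is unmapped (lower `seed_len` for noisier data).
* `find_bhb` assumes the junction is already known; it does not scan
  genome-wide for BHBs.
* The scan's folding gate uses maximum pairing, which saturates on random
  sequence; it separates structured from unstructured windows only weakly
  and is not a substitute for covariance-model homology search.
* Only intra-locus circles are called (clip search radius 1,000 nt);
  trans-chimeras are out of scope, as is quantifying circular vs linear
  abundance.
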