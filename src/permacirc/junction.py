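"""Circularization-junction calling, TSS/TATA inference, and BHB detection.

A permuted non-coding RNA gene is genomically contiguous but its mature
transcript is circularized end-to-end: reads crossing the ligation point align
with one end soft-clipped, and the clip matches the distant terminus. Each
such read votes for an (acceptor A, donor D) coordinate pair; identical votes
accumulate into a junction call. The precursor's transcription start site is
the dominant 5'-read-start position upstream of A, the TATA box is matched
upstream of the TSS, and the leader/trailer flanks of the junction are scanned
for a bulge-helix-bulge (BHB) motif: a central 4-bp helix flanked by 3-nt
unpaired bulges within outer helices of >= 2 bp, the substrate geometry of the
archaeal tRNA splicing endonuclease. Predicted endonuclease cleavage sites
within the bulges are cross-validated against the observed mature termini.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats import SeqRecord, revcomp
from .motif_scan import MotifHit
from .read_processing import AlignmentRecord
from .structure import can_pair

#: BHB geometry constants shared by the detector and the synthetic generator
CENTRAL_HELIX_LEN = 4
BULGE_LEN = 3
MIN_OUTER_HELIX = 2
#: cut after the cut_offset-th bulge nucleotide, read 5'->3' on its own strand
DEFAULT_CUT_OFFSET = 2


@dataclass
class CircularJunction:
    """Ligated acceptor/donor pair: mature RNA occupies [A, D) on the genome."""

    seq_id: str
    acceptor: int  # A: mature 5' terminus
    donor: int     # D: one past mature 3' terminus
    strand: str
    support: int
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.acceptor < self.donor:
            raise ValueError("junction requires acceptor < donor")


def circle_length(junction: CircularJunction) -> int:
    """Length of the mature circular RNA."""
    return junction.donor - junction.acceptor


@dataclass
class TSSCall:
    tss: int
    leader_len: int
    support: int


@dataclass
class BHBMotif:
    """Bulge-helix-bulge geometry between a leader-side and a trailer-side strand.

    All coordinates are genomic, 0-based half-open. Helices are pairs of
    (strand1 interval, strand2 interval) paired antiparallel; each strand
    carries one 3-nt bulge immediately 5' of its central-helix segment.
    """

    seq_id: str
    strand1: tuple[int, int]
    strand2: tuple[int, int]
    outer1: tuple[tuple[int, int], tuple[int, int]]
    central: tuple[tuple[int, int], tuple[int, int]]
    outer2: tuple[tuple[int, int], tuple[int, int]]
    bulge1: tuple[int, int]
    bulge2: tuple[int, int]
    cleavage1: int
    cleavage2: int
    score: int

    def __post_init__(self) -> None:
        (c1s, c1e), (c2s, c2e) = self.central
        if c1e - c1s != CENTRAL_HELIX_LEN or c2e - c2s != CENTRAL_HELIX_LEN:
            raise ValueError(f"central helix must be {CENTRAL_HELIX_LEN} bp")
        for b in (self.bulge1, self.bulge2):
            if b[1] - b[0] != BULGE_LEN:
                raise ValueError(f"bulge must be {BULGE_LEN} nt")
        for (h1s, h1e), _ in (self.outer1, self.outer2):
            if h1e - h1s < MIN_OUTER_HELIX:
                raise ValueError(f"outer helices must be >= {MIN_OUTER_HELIX} bp")
        if not (self.bulge1[0] <= self.cleavage1 < self.bulge1[1] + 1):
            raise ValueError("cleavage1 outside bulge1")
        if not (self.bulge2[0] <= self.cleavage2 < self.bulge2[1] + 1):
            raise ValueError("cleavage2 outside bulge2")


def predict_cleavage(bhb: BHBMotif, cut_offset: int = DEFAULT_CUT_OFFSET) -> tuple[int, int]:
    """Cut coordinates: after the cut_offset-th nucleotide of each bulge.

    The returned coordinate is the first position of the downstream cleavage
    product, e.g. bulge [50, 53) with cut_offset=2 cleaves between 51 and 52,
    reported as 52.
    """
    if cut_offset not in (1, 2):
        raise ValueError("cut_offset must be 1 or 2 (within a 3-nt bulge)")
    return (bhb.bulge1[0] + cut_offset, bhb.bulge2[0] + cut_offset)


def validate_junction_vs_bhb(
    junction: CircularJunction,
    bhb: Optional[BHBMotif],
    cut_offset: int = DEFAULT_CUT_OFFSET,
) -> bool:
    """True iff predicted cleavage sites equal the observed junction termini."""
    if bhb is None:
        return False
    return predict_cleavage(bhb, cut_offset) == (junction.acceptor, junction.donor)


# ---------------------------------------------------------------------------
# junction calling from soft-clipped alignments
# ---------------------------------------------------------------------------


def _best_clip_matches(
    genome_arr: np.ndarray, clip: str, lo: int, hi: int
) -> tuple[list[int], int]:
    """Start positions in [lo, hi) minimizing mismatches of clip vs genome,
    together with that minimal mismatch count."""
    m = len(clip)
    lo = max(0, lo)
    hi = min(hi, len(genome_arr) - m + 1)
    if hi <= lo:
        return [], m
    clip_arr = np.frombuffer(clip.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(genome_arr[lo : hi + m - 1], m)
    mism = (windows != clip_arr).sum(axis=1)
    best = int(mism.min())
    return [lo + int(i) for i in np.nonzero(mism == best)[0]], best


def junction_votes(
    alignments: Sequence[AlignmentRecord],
    reads: Sequence[SeqRecord],
    genome: SeqRecord,
    min_clip: int = 8,
    max_clip_mismatch: int = 1,
    search_radius: int = 1000,
) -> dict[tuple[int, int, str], list[str]]:
    """Per-read junction votes: (A, D, strand) -> supporting read ids.

    Only reads with a unique best placement contribute (co-optimal placements
    are discarded to avoid repeat-driven false junctions). A 3'-side clip of an
    alignment ending at D votes for (A, D) when the clip matches the genome
    starting at a unique best A < D within `search_radius`; 5'-side clips are
    handled symmetrically.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        by_read.setdefault(a.read_id, []).append(a)
    read_map = {r.id: r for r in reads}
    garr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)

    votes: dict[tuple[int, int, str], list[str]] = {}
    for read_id, alns in by_read.items():
        if len({a.placement() for a in alns}) != 1:
            continue  # ambiguous placement
        aln = alns[0]
        read = read_map.get(read_id)
        if read is None:
            continue
        oriented = read.seq if aln.strand == "+" else revcomp(read.seq)

        pairs: list[tuple[int, int]] = []
        clip3 = oriented[aln.read_aln_end :]
        if len(clip3) >= min_clip:
            D = aln.ref_end
            cand, mism = _best_clip_matches(garr, clip3, D - search_radius, D)
            cand = [A for A in cand if A < D]
            if len(cand) == 1 and mism <= max_clip_mismatch:
                pairs.append((cand[0], D))
        clip5 = oriented[: aln.read_aln_start]
        if len(clip5) >= min_clip:
            A = aln.ref_start
            m = len(clip5)
            # the clip's end D = start + m must satisfy A < D <= A + radius
            cand, mism = _best_clip_matches(garr, clip5, A - m + 1, A + search_radius - m + 1)
            if len(cand) == 1 and mism <= max_clip_mismatch:
                pairs.append((A, cand[0] + m))
        for A, D in pairs:
            votes.setdefault((A, D, aln.strand), []).append(read_id)
    return votes


def detect_circular_junctions(
    alignments: Sequence[AlignmentRecord],
    reads: Sequence[SeqRecord],
    genome: SeqRecord,
    min_clip: int = 8,
    min_support: int = 2,
    max_clip_mismatch: int = 1,
    search_radius: int = 1000,
) -> list[CircularJunction]:
    """Call circularization junctions from soft-clipped read alignments.

    Votes for non-identical coordinate pairs are never merged: each distinct
    (A, D) pair with >= min_support identical votes becomes its own junction.
    See junction_votes for the voting rules.
    """
    votes = junction_votes(
        alignments, reads, genome,
        min_clip=min_clip, max_clip_mismatch=max_clip_mismatch,
        search_radius=search_radius,
    )
    junctions = [
        CircularJunction(genome.id, A, D, strand, len(ids), sorted(ids))
        for (A, D, strand), ids in votes.items()
        if len(ids) >= min_support
    ]
    junctions.sort(key=lambda j: (-j.support, j.acceptor, j.donor))
    return junctions


def call_tss(
    starts5: np.ndarray,
    junction: CircularJunction,
    search_window: int = 60,
    min_frac: float = 0.5,
) -> Optional[TSSCall]:
    """TSS = argmax of 5'-start counts in [A - search_window, A).

    Reported only when the peak is unique and holds >= min_frac of all
    5' starts in the window; otherwise None (no-call).
    """
    A = junction.acceptor
    lo = max(0, A - search_window)
    window = np.asarray(starts5[lo:A])
    total = int(window.sum())
    if total == 0:
        return None
    peak = int(window.max())
    argmaxes = np.nonzero(window == peak)[0]
    if len(argmaxes) != 1:
        return None  # ambiguous
    if peak < min_frac * total:
        return None
    tss = lo + int(argmaxes[0])
    return TSSCall(tss=tss, leader_len=A - tss, support=peak)


def find_tata(
    genome: SeqRecord,
    tss: int,
    pattern: str = "TTAATA",
    search_window: int = 40,
    max_mismatch: int = 0,
) -> Optional[tuple[MotifHit, int]]:
    """Best promoter-pattern match fully inside [tss - search_window, tss).

    Returns (hit, offset) with offset = tss - hit.end (distance from the
    motif's 3' base to the TSS); the match nearest the TSS wins ties.
    """
    m = len(pattern)
    lo = max(0, tss - search_window)
    best: Optional[tuple[int, int]] = None  # (mismatches, start)
    for p in range(lo, tss - m + 1):
        mism = sum(1 for a, b in zip(genome.seq[p : p + m], pattern) if a != b)
        if mism <= max_mismatch and (best is None or mism < best[0] or
                                     (mism == best[0] and p > best[1])):
            best = (mism, p)
    if best is None:
        return None
    p = best[1]
    hit = MotifHit("tata_box", genome.id, p, p + m, "+", genome.seq[p : p + m])
    return hit, tss - (p + m)


# ---------------------------------------------------------------------------
# BHB enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BHBConfig:
    """A BHB configuration in local coordinates of two strands.

    i1/c2 are the central-helix start on strand1/strand2; a and b the outer
    helix lengths. Each strand carries its 3-nt bulge immediately 5' of its
    central segment, so the layout along strand1 is
    outer1(a) - bulge1(3) - central(4) - outer2(b), and along strand2
    outer2'(b) - bulge2(3) - central'(4) - outer1'(a).
    """

    i1: int
    c2: int
    a: int
    b: int

    @property
    def score(self) -> int:
        return CENTRAL_HELIX_LEN + self.a + self.b


def enumerate_bhb_configs(
    s1: str,
    s2: str,
    min_outer: int = MIN_OUTER_HELIX,
    allow_gu: bool = True,
) -> list[BHBConfig]:
    """Exhaustively enumerate BHB configurations between two strands.

    Pairing is antiparallel: central pairs s1[i1+k] with s2[c2+3-k]; outer1
    pairs s1[i1-4-k] with s2[c2+4+k]; outer2 pairs s1[i1+4+k] with s2[c2-4-k].
    Outer helices are maximal runs (>= min_outer). Swapping s1 and s2 yields
    the mirrored configuration set with identical scores.
    """
    n1, n2 = len(s1), len(s2)
    out: list[BHBConfig] = []
    CL, BL = CENTRAL_HELIX_LEN, BULGE_LEN
    for i1 in range(BL + min_outer, n1 - CL - min_outer + 1):
        for c2 in range(BL + min_outer, n2 - CL - min_outer + 1):
            if not all(can_pair(s1[i1 + k], s2[c2 + CL - 1 - k], allow_gu) for k in range(CL)):
                continue
            # outer helix 1: s1 upstream of bulge1 vs s2 downstream of central'
            a = 0
            while (
                i1 - CL - a >= 0
                and c2 + CL + a < n2
                and can_pair(s1[i1 - CL - a], s2[c2 + CL + a], allow_gu)
            ):
                a += 1
            # outer helix 2: s1 downstream of central vs s2 upstream of bulge2
            b = 0
            while (
                i1 + CL + b < n1
                and c2 - CL - b >= 0
                and can_pair(s1[i1 + CL + b], s2[c2 - CL - b], allow_gu)
            ):
                b += 1
            if a >= min_outer and b >= min_outer:
                out.append(BHBConfig(i1=i1, c2=c2, a=a, b=b))
    return out


def _config_to_motif(
    cfg: BHBConfig, seq_id: str, off1: int, off2: int, cut_offset: int
) -> BHBMotif:
    CL, BL = CENTRAL_HELIX_LEN, BULGE_LEN
    i1, c2, a, b = cfg.i1, cfg.c2, cfg.a, cfg.b
    bulge1 = (off1 + i1 - BL, off1 + i1)
    bulge2 = (off2 + c2 - BL, off2 + c2)
    return BHBMotif(
        seq_id=seq_id,
        strand1=(off1 + i1 - BL - a, off1 + i1 + CL + b),
        strand2=(off2 + c2 - BL - b, off2 + c2 + CL + a),
        outer1=((off1 + i1 - BL - a, off1 + i1 - BL), (off2 + c2 + CL, off2 + c2 + CL + a)),
        central=((off1 + i1, off1 + i1 + CL), (off2 + c2, off2 + c2 + CL)),
        outer2=((off1 + i1 + CL, off1 + i1 + CL + b), (off2 + c2 - BL - b, off2 + c2 - BL)),
        bulge1=bulge1,
        bulge2=bulge2,
        cleavage1=bulge1[0] + cut_offset,
        cleavage2=bulge2[0] + cut_offset,
        score=cfg.score,
    )


def find_bhb(
    genome: SeqRecord,
    junction: CircularJunction,
    tss: Optional[int] = None,
    flank: int = 18,
    min_outer: int = MIN_OUTER_HELIX,
    allow_gu: bool = True,
    cut_offset: int = DEFAULT_CUT_OFFSET,
) -> list[BHBMotif]:
    """Enumerate BHB motifs between the junction's leader- and trailer-side flanks.

    strand1 = genome[A - flank, A + flank), strand2 = genome[D - flank, D + flank).
    All configurations (outer >= min_outer bp, 3-nt bulges, central 4 bp) are
    emitted, ranked by score (total paired bases) descending, ties by distance
    of predicted cleavage sites from the observed termini, ascending. The tss
    argument is informational (the leader-side window is junction-anchored).
    """
    if flank < 10:
        raise ValueError("flank must be >= 10 to host the motif geometry")
    del tss
    A, D = junction.acceptor, junction.donor
    off1, off2 = max(0, A - flank), max(0, D - flank)
    s1 = genome.seq[off1 : A + flank]
    s2 = genome.seq[off2 : min(len(genome.seq), D + flank)]
    configs = enumerate_bhb_configs(s1, s2, min_outer=min_outer, allow_gu=allow_gu)
    motifs = [_config_to_motif(c, genome.id, off1, off2, cut_offset) for c in configs]

    def _key(m: BHBMotif):
        c1, c2 = predict_cleavage(m, cut_offset)
        return (-m.score, abs(c1 - A) + abs(c2 - D), m.bulge1[0], m.bulge2[0])

    motifs.sort(key=_key)
    return motifs
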