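"""Candidate-locus discovery: degenerate motif matching + folding potential.

The signal recognition particle RNA carries only two short, nearly invariant
sequence features on top of a strongly paired secondary structure: the GNAR
tetraloop (G, any, A, purine) closing helix 6 and a conserved SRP54-binding
motif in helix 8b. A genomic window is a candidate locus when both motifs
co-occur on one strand and the window's maximum-pairing fraction clears a
threshold. The helix-8b consensus is not a published string; the pattern is a
required configuration item and DEFAULT_H8B_PATTERN below is a synthetic
placeholder used by the generator/detector pair, not a biological claim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .formats import SeqRecord, revcomp
from .structure import nussinov_fold, pairing_fraction

IUPAC_CLASSES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

GNAR_PATTERN = "GNAR"
#: synthetic placeholder for the (unpublished) helix-8b consensus
DEFAULT_H8B_PATTERN = "RGGNGCAGGC"


@dataclass
class MotifHit:
    pattern_name: str
    seq_id: str
    start: int
    end: int
    strand: str
    matched: str


@dataclass
class CandidateLocus:
    seq_id: str
    start: int
    end: int
    strand: str
    motif_hits: list[MotifHit]
    fold_score: float
    combined_score: float


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for sym in pattern.upper():
        cls = IUPAC_CLASSES.get(sym)
        if cls is None:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in pattern {pattern!r}")
        parts.append(sym if len(cls) == 1 else f"[{cls}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def iupac_scan(
    seq, pattern: str, both_strands: bool = True, pattern_name: Optional[str] = None
) -> list[MotifHit]:
    """All matches of an IUPAC-degenerate pattern; minus-strand hits are
    reported in plus-strand coordinates with strand '-'."""
    if isinstance(seq, str):
        seq = SeqRecord("seq", seq.upper())
    name = pattern_name or pattern
    rx = _iupac_regex(pattern)
    m = len(pattern)
    n = len(seq.seq)
    hits = [
        MotifHit(name, seq.id, mt.start(), mt.start() + m, "+", mt.group(1))
        for mt in rx.finditer(seq.seq)
    ]
    if both_strands:
        rc = revcomp(seq.seq)
        for mt in rx.finditer(rc):
            start = n - (mt.start() + m)
            hits.append(MotifHit(name, seq.id, start, start + m, "-", mt.group(1)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def tetraloop_context_check(genome_window: str, hit: MotifHit) -> bool:
    """True iff, in the maximum-pairing fold of the window, the 4 hit bases
    are an unpaired hairpin loop closed by at least 2 stacked pairs.

    hit coordinates are local to the window. Meaningful on compact windows
    (a hairpin and modest flanks); in a large window the maximum-pairing
    criterion will recruit loop bases into long-range pairs.
    """
    s, e = hit.start, hit.end
    if not (0 <= s < e <= len(genome_window)):
        raise ValueError("hit must lie inside the window")
    fold = nussinov_fold(genome_window)
    paired = {i for p in fold.pairs for i in p}
    if any(i in paired for i in range(s, e)):
        return False
    pairset = set(fold.pairs)
    return (s - 1, e) in pairset and (s - 2, e + 1) in pairset


def scan_candidate_loci(
    genome: SeqRecord,
    gnar: str = GNAR_PATTERN,
    h8b_pattern: str = DEFAULT_H8B_PATTERN,
    window: int = 400,
    step: int = 50,
    min_fold: float = 0.5,
    motif_bonus: float = 0.25,
    allow_gu: bool = True,
) -> list[CandidateLocus]:
    """Slide windows over the genome; a window qualifies when >= 1 GNAR hit
    and >= 1 helix-8b hit co-occur on the same strand and the window's
    pairing fraction reaches min_fold. Overlapping qualifying windows are
    merged (scores recomputed on the merged interval); candidates are ranked
    by combined_score = fold_score + motif_bonus per required motif,
    descending, ties by leftmost start.
    """
    if window < max(len(gnar), len(h8b_pattern)):
        raise ValueError("window shorter than the longest pattern")
    n = len(genome.seq)

    def _evaluate(lo: int, hi: int) -> Optional[CandidateLocus]:
        sub = genome.seq[lo:hi]
        gnar_hits = iupac_scan(sub, gnar, pattern_name="gnar_tetraloop")
        h8b_hits = iupac_scan(sub, h8b_pattern, pattern_name="h8b")
        strands = {h.strand for h in gnar_hits} & {h.strand for h in h8b_hits}
        if not strands:
            return None
        fold = pairing_fraction(sub, allow_gu=allow_gu)
        if fold < min_fold:
            return None
        strand = "+" if "+" in strands else "-"
        hits = [
            MotifHit(h.pattern_name, genome.id, lo + h.start, lo + h.end, h.strand, h.matched)
            for h in gnar_hits + h8b_hits
            if h.strand == strand
        ]
        hits.sort(key=lambda h: h.start)
        return CandidateLocus(
            seq_id=genome.id,
            start=lo,
            end=hi,
            strand=strand,
            motif_hits=hits,
            fold_score=fold,
            combined_score=fold + 2 * motif_bonus,
        )

    qualifying: list[tuple[int, int]] = []
    starts = list(range(0, max(1, n - window + 1), step))
    if starts and starts[-1] + window < n:
        starts.append(n - window)
    for lo in starts:
        hi = min(n, lo + window)
        if _evaluate(lo, hi) is not None:
            if qualifying and lo <= qualifying[-1][1]:
                qualifying[-1] = (qualifying[-1][0], max(qualifying[-1][1], hi))
            else:
                qualifying.append((lo, hi))

    candidates = []
    for lo, hi in qualifying:
        cand = _evaluate(lo, hi)
        if cand is not None:
            candidates.append(cand)
    candidates.sort(key=lambda c: (-c.combined_score, c.start))
    return candidates
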