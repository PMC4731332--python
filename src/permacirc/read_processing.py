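"""Read cleanup and local alignment with soft-clip bookkeeping.

The trimming stages reproduce, as explicit algorithms, the standard small
RNA-Seq preprocessing chain: error-probability ("Mott") quality trimming with
a limit of 0.05 and at most 2 ambiguous bases, adapter trimming by suffix/
prefix overlap, and a 15-nt length cutoff. Alignment is seed-and-extend: exact
k-mer seeds from a genome index select candidate windows, and each window is
resolved by an exact local affine-gap (Gotoh) alignment, scored match +1,
mismatch -4, gap open -6, gap extend -1 (a gap of length k costs 6 + k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .formats import SeqRecord, revcomp


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring; costs are stored positive, applied as penalties."""

    match: int = 1
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1


@dataclass
class AlignmentRecord:
    """A local alignment of a read against a reference, 0-based half-open.

    read_aln_start/read_aln_end are coordinates on the reference-oriented
    read (for strand '-' they index into revcomp(read)); the soft clips are
    [0, read_aln_start) and [read_aln_end, read_len).
    """

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    read_aln_start: int
    read_aln_end: int
    read_len: int
    score: float
    n_mismatch: int = 0
    n_gap: int = 0

    @property
    def clip5(self) -> int:
        return self.read_aln_start

    @property
    def clip3(self) -> int:
        return self.read_len - self.read_aln_end

    def placement(self) -> tuple:
        return (self.ref_start, self.ref_end, self.strand, self.read_aln_start, self.read_aln_end)


def phred_to_prob(q: int) -> float:
    return 10.0 ** (-q / 10.0)


def quality_trim(read: SeqRecord, limit: float = 0.05, max_ambiguities: int = 2) -> SeqRecord:
    """Error-probability trimming: keep the contiguous stretch maximizing
    sum(limit - p_i) over per-base error probabilities p_i (empty if no
    positive-sum stretch exists). Ties prefer the longer, then leftmost,
    stretch. Reads retaining more than `max_ambiguities` N bases are
    discarded (empty result).
    """
    if read.qual is None:
        raise ValueError(f"read {read.id!r} has no qualities")
    n = len(read.seq)
    gains = [limit - phred_to_prob(q) for q in read.qual]
    # prefix-sum scan for the max-sum substring, longest/leftmost on ties
    best_sum = 0.0
    best = (0, 0)  # empty
    prefix = 0.0
    min_prefix, min_idx = 0.0, 0
    for j in range(1, n + 1):
        prefix += gains[j - 1]
        cand = prefix - min_prefix
        if cand > best_sum or (
            cand == best_sum and best_sum > 0 and (j - min_idx) > (best[1] - best[0])
        ):
            best_sum = cand
            best = (min_idx, j)
        if prefix < min_prefix:
            min_prefix, min_idx = prefix, j
    if best_sum <= 0:
        return read.slice(0, 0)
    trimmed = read.slice(*best)
    if trimmed.seq.count("N") > max_ambiguities:
        return read.slice(0, 0)
    return trimmed


def trim_adapter(
    read: SeqRecord,
    adapter: str,
    min_overlap: int = 3,
    max_mismatch_frac: float = 0.1,
) -> SeqRecord:
    """Remove the longest read suffix matching a prefix of the adapter.

    An overlap starting at read position p compares read[p:] to the adapter
    prefix of the same length and is admissible when its length is at least
    min_overlap and its mismatch count is at most
    floor(max_mismatch_frac * overlap). The smallest admissible p wins
    (longest suffix removed).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = adapter.upper()
    n = len(read.seq)
    for p in range(0, n - min_overlap + 1):
        overlap = min(n - p, len(adapter))
        if overlap < min_overlap:
            break
        mism = sum(
            1 for a, b in zip(read.seq[p : p + overlap], adapter[:overlap]) if a != b
        )
        if mism <= int(max_mismatch_frac * overlap):
            return read.slice(0, p)
    return read


def length_filter(reads: Sequence[SeqRecord], min_len: int = 15) -> list[SeqRecord]:
    """Keep reads with length >= min_len, preserving order."""
    return [r for r in reads if len(r.seq) >= min_len]


class GenomeIndex:
    """Exact k-mer index of one reference sequence for seeding alignments."""

    def __init__(self, genome: SeqRecord, seed_len: int = 12):
        if len(genome.seq) < seed_len:
            raise ValueError("genome shorter than seed length")
        self.genome = genome
        self.seed_len = seed_len
        self._index: dict[str, list[int]] = {}
        seq = genome.seq
        for i in range(len(seq) - seed_len + 1):
            kmer = seq[i : i + seed_len]
            self._index.setdefault(kmer, []).append(i)

    def seed_hits(self, query: str) -> list[tuple[int, int]]:
        """(query_offset, genome_position) pairs of exact seed matches."""
        k = self.seed_len
        hits = []
        for o in range(0, len(query) - k + 1):
            for pos in self._index.get(query[o : o + k], ()):
                hits.append((o, pos))
        return hits


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.match_score = scoring.match
    aln.mismatch_score = -scoring.mismatch
    # biopython charges open on the first gap base; our convention is
    # cost(k-gap) = open + k*extend
    aln.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aln.extend_gap_score = -scoring.gap_extend
    return aln


def _candidate_windows(hits, qlen: int, glen: int, pad: int) -> list[tuple[int, int]]:
    """Merge seed diagonals into genome windows guaranteed to contain any
    local alignment anchored on those seeds."""
    diags = sorted({pos - o for o, pos in hits})
    windows: list[tuple[int, int]] = []
    for d in diags:
        lo = max(0, d - pad)
        hi = min(glen, d + qlen + pad)
        if windows and lo <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], hi))
        else:
            windows.append((lo, hi))
    return windows


def _alignment_stats(target: str, query: str, alignment) -> tuple[int, int, int, int, int, int, int]:
    tb, qb = alignment.aligned
    t_start, t_end = int(tb[0][0]), int(tb[-1][1])
    q_start, q_end = int(qb[0][0]), int(qb[-1][1])
    n_mism = 0
    for (ts, te), (qs, qe) in zip(tb, qb):
        n_mism += sum(1 for a, b in zip(target[ts:te], query[qs:qe]) if a != b)
    n_gap = int((t_end - t_start) + (q_end - q_start) - 2 * sum(te - ts for ts, te in tb))
    return t_start, t_end, q_start, q_end, n_mism, n_gap, len(tb)


def align_read(
    read: SeqRecord,
    genome,
    scoring: Scoring = Scoring(),
    seed_len: int = 12,
    max_co_optimal: int = 16,
) -> list[AlignmentRecord]:
    """Seed-and-extend local alignment of one read on both strands.

    Returns the best-scoring alignment together with any co-optimal ones
    (distinct placements at the same score). No seed on either strand, or no
    positive-scoring alignment, yields an empty list.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, seed_len)
    gseq = index.genome.seq
    aligner = _make_aligner(scoring)
    pad = 2 * index.seed_len + 8

    results: list[AlignmentRecord] = []
    best_score = 0.0
    for strand in ("+", "-"):
        q = read.seq if strand == "+" else revcomp(read.seq)
        hits = index.seed_hits(q)
        if not hits:
            continue
        for lo, hi in _candidate_windows(hits, len(q), len(gseq), pad):
            window = gseq[lo:hi]
            alns = aligner.align(window, q)
            try:
                score = alns.score
            except (AttributeError, IndexError):
                continue
            if score <= 0 or score < best_score:
                continue
            seen = set()
            for idx, a in enumerate(alns):
                if idx >= max_co_optimal:
                    break
                t0, t1, q0, q1, nm, ng, _ = _alignment_stats(window, q, a)
                rec = AlignmentRecord(
                    read_id=read.id,
                    ref_id=index.genome.id,
                    ref_start=lo + t0,
                    ref_end=lo + t1,
                    strand=strand,
                    read_aln_start=q0,
                    read_aln_end=q1,
                    read_len=len(q),
                    score=float(score),
                    n_mismatch=nm,
                    n_gap=ng,
                )
                if rec.placement() in seen:
                    continue
                seen.add(rec.placement())
                if score > best_score:
                    best_score = score
                    results = [rec]
                elif score == best_score:
                    results.append(rec)

    # dedupe identical placements discovered through overlapping windows
    uniq: dict[tuple, AlignmentRecord] = {}
    for rec in results:
        if rec.score == best_score:
            uniq.setdefault(rec.placement(), rec)
    return list(uniq.values())


_TSV_FIELDS = [
    "read_id", "ref_id", "ref_start", "ref_end", "strand",
    "read_aln_start", "read_aln_end", "read_len", "score", "n_mismatch", "n_gap",
]


def write_alignments_tsv(alignments: Sequence[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_FIELDS) + "\n")
        for a in alignments:
            fh.write("\t".join(str(getattr(a, f)) for f in _TSV_FIELDS) + "\n")


def read_alignments_tsv(path) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_FIELDS:
            raise ValueError(f"unexpected alignment TSV header in {path}")
        for line in fh:
            vals = dict(zip(_TSV_FIELDS, line.rstrip("\n").split("\t")))
            out.append(
                AlignmentRecord(
                    read_id=vals["read_id"],
                    ref_id=vals["ref_id"],
                    ref_start=int(vals["ref_start"]),
                    ref_end=int(vals["ref_end"]),
                    strand=vals["strand"],
                    read_aln_start=int(vals["read_aln_start"]),
                    read_aln_end=int(vals["read_aln_end"]),
                    read_len=int(vals["read_len"]),
                    score=float(vals["score"]),
                    n_mismatch=int(vals["n_mismatch"]),
                    n_gap=int(vals["n_gap"]),
                )
            )
    return out


@dataclass
class CoverageProfiles:
    """Per-base depth and strand-aware 5'-start counts over one reference."""

    depth: dict = field(default_factory=dict)    # strand -> np.ndarray
    starts5: dict = field(default_factory=dict)  # strand -> np.ndarray

    def total_depth(self) -> np.ndarray:
        return self.depth["+"] + self.depth["-"]


def coverage_profiles(alignments: Sequence[AlignmentRecord], genome: SeqRecord) -> CoverageProfiles:
    """depth[i] = alignments covering i; starts5[i] = alignments whose
    biological 5' end maps to i (ref_start on '+', ref_end - 1 on '-')."""
    n = len(genome.seq)
    prof = CoverageProfiles(
        depth={"+": np.zeros(n, dtype=np.int64), "-": np.zeros(n, dtype=np.int64)},
        starts5={"+": np.zeros(n, dtype=np.int64), "-": np.zeros(n, dtype=np.int64)},
    )
    for a in alignments:
        if a.ref_id != genome.id:
            raise ValueError(f"alignment {a.read_id!r} references {a.ref_id!r}, not {genome.id!r}")
        prof.depth[a.strand][a.ref_start : a.ref_end] += 1
        five = a.ref_start if a.strand == "+" else a.ref_end - 1
        prof.starts5[a.strand][five] += 1
    return prof
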