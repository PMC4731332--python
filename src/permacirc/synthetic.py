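"""Synthetic locus and small RNA-Seq read generator with ground truth.

The generator emulates the genomic architecture the analysis assumes: an
archaeal TATA box (default 5'-TTAATA-3') a fixed distance upstream of the
transcription start site, a short leader, a permuted non-coding RNA gene
whose contiguous genomic block [A, D) is circularized end-to-end in the
mature RNA, trailer sequence, and an adjacent C/D box sRNA-like gene. The
leader's 3' region and the trailer's 5' region are constructed so that,
paired antiparallel, they form the bulge-helix-bulge processing motif
(outer helix >= 2 bp, 3-nt bulge, central 4-bp helix, 3-nt bulge, outer
helix >= 2 bp) whose predicted cleavage points fall exactly on A and D under
the cut-offset convention shared with the detector. A GNAR tetraloop is
planted as the loop of a constructed 5-bp hairpin, and a realization of the
configured helix-8b pattern is planted nearby, both inside the circle.

Reads are simulated from the linear precursor and from the circular mature
RNA (via the doubled circle string, so reads may cross the A/D junction),
with i.i.d. substitution errors. A configurable fraction of precursor reads
is 5'-anchored at the TSS, reflecting intact primary-transcript 5' ends in
small RNA libraries; the remainder are uniform fragments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .formats import Feature, SeqRecord, revcomp
from .junction import (
    BHBConfig,
    BHBMotif,
    BULGE_LEN,
    CENTRAL_HELIX_LEN,
    DEFAULT_CUT_OFFSET,
    MIN_OUTER_HELIX,
    _config_to_motif,
)
from .motif_scan import DEFAULT_H8B_PATTERN, IUPAC_CLASSES, MotifHit, tetraloop_context_check
from .structure import can_pair

BASES = "ACGT"


class ParameterError(ValueError):
    """Inconsistent or infeasible generator parameters."""


@dataclass
class LocusParams:
    """Geometry of the synthetic locus. Distances in nucleotides.

    tata_offset is measured from the TATA box's 3' base to the TSS (the
    find_tata convention). gnar_pos / h8b_pos are circle coordinates (None =
    automatic placement); gnar_pos addresses the first loop base of the
    planted 5-bp hairpin. outer_helix_len caps the planted BHB outer helices
    (reduced automatically when the leader is short).
    """

    circle_len: int = 309
    leader_len: int = 23
    trailer_len: int = 30
    tata_offset: int = 26
    tata_seq: str = "TTAATA"
    gnar_pos: Optional[int] = None
    h8b_pos: Optional[int] = None
    h8b_pattern: str = DEFAULT_H8B_PATTERN
    outer_helix_len: int = 4
    cdbox: bool = True
    cdbox_len: int = 55
    cdbox_spacing: int = 20
    flank_len: int = 150
    gc: float = 0.5
    cut_offset: int = DEFAULT_CUT_OFFSET
    seed: int = 0


@dataclass
class ReadSimParams:
    n_precursor: int = 60
    n_circular: int = 120
    read_len: int = 75
    err: float = 0.0
    qual_model: str = "constant"  # or "ramp"
    qual_const: int = 40
    qual_ramp: tuple[int, int] = (40, 20)
    adapter: Optional[str] = None
    frac_tss_anchored: float = 0.5
    min_anchor: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 15:
            raise ParameterError("read_len must be >= 15")
        if not (0 <= self.err < 0.25):
            raise ParameterError("err must be in [0, 0.25)")


@dataclass
class ReadLabel:
    origin: str  # "precursor" | "circular"
    junction_spanning: bool
    start: int   # genome coord (precursor) or circle coord (circular)


@dataclass
class TruthSet:
    """Generator ground truth used by the recovery suite."""

    seq_id: str
    circle_start: int            # A
    circle_end: int              # D
    tss: int
    leader_len: int
    tata_interval: tuple[int, int]
    tata_offset: int
    precursor_interval: tuple[int, int]
    gnar_interval: tuple[int, int]     # the loop itself, genome coords
    h8b_interval: tuple[int, int]
    cdbox_interval: Optional[tuple[int, int]]
    bhb: BHBMotif
    cleavage_sites: tuple[int, int]
    cut_offset: int
    read_labels: dict[str, ReadLabel] = field(default_factory=dict)

    @property
    def circle_len(self) -> int:
        return self.circle_end - self.circle_start

    def validate(self) -> None:
        assert self.tss == self.circle_start - self.leader_len
        assert self.cleavage_sites == (self.circle_start, self.circle_end)
        for cut, bulge in zip(self.cleavage_sites, (self.bhb.bulge1, self.bhb.bulge2)):
            assert bulge[0] <= cut <= bulge[1], "cleavage site outside its bulge"

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 1000) -> str:
    """Shuffle preserving dinucleotide counts (random Eulerian walk on the
    transition multigraph; retried until the walk consumes every edge)."""
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for x, y in zip(seq, seq[1:]):
            edges.setdefault(x, []).append(y)
        for lst in edges.values():
            rng.shuffle(lst)
        walk = [seq[0]]
        cur = seq[0]
        while edges.get(cur):
            cur = edges[cur].pop()
            walk.append(cur)
        if len(walk) == len(seq):
            return "".join(walk)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list(BASES), size=n, p=p)) if n else []


def _choose(rng: np.random.Generator, allowed: str) -> str:
    return allowed[int(rng.integers(len(allowed)))]


def _not_pairing(partner: str, exclude: str = "") -> str:
    opts = [b for b in BASES if not can_pair(b, partner) and b not in exclude]
    return "".join(opts)


def _realize_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(_choose(rng, IUPAC_CLASSES[s]) for s in pattern.upper())


def build_locus(params: LocusParams) -> tuple[SeqRecord, TruthSet, list[Feature]]:
    """Assemble the synthetic genome, its ground truth, and feature annotations.

    Deterministic for a fixed seed. Raises ParameterError when planted
    elements do not fit or overlap.
    """
    rng = np.random.default_rng(params.seed)
    C, L = params.circle_len, params.leader_len
    delta = params.cut_offset
    if delta not in (1, 2):
        raise ParameterError("cut_offset must be 1 or 2")
    a = min(params.outer_helix_len, L - delta - 1)
    b = params.outer_helix_len
    if a < MIN_OUTER_HELIX:
        raise ParameterError(
            f"leader_len={L} too short: needs >= outer({MIN_OUTER_HELIX}) + "
            f"cut_offset({delta}) + 1 background nt"
        )
    if params.trailer_len < (BULGE_LEN - delta) + CENTRAL_HELIX_LEN + a + 1:
        raise ParameterError("trailer_len too short to host the BHB trailer arm")

    # reserved circle prefix/suffix for the BHB arms
    prefix = (BULGE_LEN - delta) + CENTRAL_HELIX_LEN + b   # circle[0 : prefix]
    suffix = delta + b                                      # circle[C-suffix : C]
    interior_lo, interior_hi = prefix + 1, C - suffix - 1   # margins for motifs

    # --- planted motif placement inside the circle ---------------------------
    hairpin_stem = 5
    hairpin_len = 2 * hairpin_stem + 4
    gnar_pos = params.gnar_pos if params.gnar_pos is not None else interior_lo + 3 + hairpin_stem
    hp_start = gnar_pos - hairpin_stem
    hp_end = hp_start + hairpin_len
    h8b_len = len(params.h8b_pattern)
    h8b_pos = params.h8b_pos if params.h8b_pos is not None else hp_end + 6
    if hp_start < interior_lo or h8b_pos + h8b_len > interior_hi:
        raise ParameterError(
            f"circle_len={C} too small to host the BHB arms and planted motifs"
        )
    if not (h8b_pos >= hp_end or h8b_pos + h8b_len <= hp_start):
        raise ParameterError("planted GNAR hairpin and h8b motif overlap")

    # --- BHB letters with non-extension / junction-sharpness constraints -----
    # central helix c[0..3]; genome carries c at circle[3-delta+ : ] and its
    # reverse complement just after D.
    c = [_choose(rng, BASES), _choose(rng, BASES)]
    c.append(_choose(rng, "".join(x for x in BASES if x != revcomp(c[1]))) if delta == 2
             else _choose(rng, BASES))
    c.append(_choose(rng, "".join(x for x in BASES if x != revcomp(c[0]))))
    o1 = [_choose(rng, BASES) for _ in range(a)]
    o2 = [_choose(rng, BASES) for _ in range(b)]
    b1 = [
        _choose(rng, _not_pairing(revcomp(c[0]))),
        _choose(rng, BASES),
        _choose(rng, _not_pairing(revcomp(o1[-1]))),
    ]
    b2 = [
        _choose(rng, _not_pairing(c[3], exclude=b1[0])),
        _choose(rng, "".join(x for x in BASES if x != b1[1])),
        _choose(rng, _not_pairing(o2[0], exclude=b1[2])),
    ]

    # --- GNAR hairpin (5-bp stem + GNAR loop), validated fold ----------------
    for _ in range(64):
        stem5 = [_choose(rng, BASES) for _ in range(hairpin_stem)]
        loop = list(_realize_iupac(rng, "GNAR"))
        hairpin = "".join(stem5 + loop) + revcomp("".join(stem5))
        hit = MotifHit("gnar_tetraloop", "hp", hairpin_stem, hairpin_stem + 4, "+", "".join(loop))
        if tetraloop_context_check(hairpin, hit):
            break
    else:  # pragma: no cover - sampling failure is astronomically unlikely
        raise ParameterError("could not construct a foldable GNAR hairpin")

    h8b_realized = _realize_iupac(rng, params.h8b_pattern)

    # --- assemble the circle --------------------------------------------------
    circle = (
        b1[delta:]
        + c
        + o2
        + _random_seq(rng, C - prefix - suffix, params.gc)
        + [revcomp(base) for base in reversed(o2)]
        + b2[:delta]
    )
    assert len(circle) == C
    circle[hp_start:hp_end] = list(hairpin)
    circle[h8b_pos : h8b_pos + h8b_len] = list(h8b_realized)

    # --- leader / trailer / flanks -------------------------------------------
    leader = _random_seq(rng, L - a - delta, params.gc) + o1 + b1[:delta]
    trailer = (
        b2[delta:]
        + [revcomp(base) for base in reversed(c)]
        + [revcomp(base) for base in reversed(o1)]
        + _random_seq(rng, params.trailer_len - (BULGE_LEN - delta) - CENTRAL_HELIX_LEN - a,
                      params.gc)
    )
    left_flank = _random_seq(rng, params.flank_len, params.gc)
    spacer = _random_seq(rng, params.tata_offset, params.gc)
    spacer2 = _random_seq(rng, params.cdbox_spacing, params.gc)
    if params.cdbox:
        if params.cdbox_len < 12:
            raise ParameterError("cdbox_len must be >= 12")
        cdbox_seq = (
            list("ATGATGA")
            + _random_seq(rng, params.cdbox_len - 11, params.gc)
            + list("CTGA")
        )
    else:
        cdbox_seq = []
    right_flank = _random_seq(rng, params.flank_len, params.gc)

    segs = [left_flank, list(params.tata_seq.upper()), spacer, leader, circle,
            trailer, spacer2, cdbox_seq, right_flank]
    genome = [base for seg in segs for base in seg]

    tata_start = params.flank_len
    tata_end = tata_start + len(params.tata_seq)
    tss = tata_end + params.tata_offset
    A = tss + L
    D = A + C
    trailer_end = D + params.trailer_len
    cd_start = trailer_end + params.cdbox_spacing
    cd_interval = (cd_start, cd_start + params.cdbox_len) if params.cdbox else None

    # --- background-coupled non-extension fixes -------------------------------
    # outer helix 1 must not extend into background:
    p_leader, p_trailer = A - delta - a - 1, D + (BULGE_LEN - delta) + CENTRAL_HELIX_LEN + a
    while can_pair(genome[p_leader], genome[p_trailer]):
        genome[p_trailer] = _choose(rng, BASES)
    # outer helix 2 must not extend into the circle interior:
    p_in1, p_in2 = A + prefix, D - suffix - 1
    while can_pair(genome[p_in1], genome[p_in2]):
        genome[p_in2] = _choose(rng, BASES)
    circle = genome[A:D]  # refresh after fixes

    # --- keep the planted TATA the only match near the TSS ---------------------
    tata = params.tata_seq.upper()
    m = len(tata)
    win_lo = max(0, tss - 40)
    for _ in range(200):
        extra = [
            p
            for p in range(win_lo, tss - m + 1)
            if p != tata_start and "".join(genome[p : p + m]) == tata
        ]
        if not extra:
            break
        for p in extra:
            for q in range(p, p + m):
                if not (tata_start <= q < tata_end):
                    genome[q] = _choose(rng, BASES)
    else:  # pragma: no cover
        raise ParameterError("could not make the planted TATA box unique")

    genome_seq = "".join(genome)
    genome_rec = SeqRecord("synthetic_locus", genome_seq)

    # --- truth BHB via the shared local-configuration convention ----------------
    flank = 18
    cfg = BHBConfig(i1=flank + BULGE_LEN - delta, c2=flank + BULGE_LEN - delta, a=a, b=b)
    bhb = _config_to_motif(cfg, genome_rec.id, A - flank, D - flank, delta)
    truth = TruthSet(
        seq_id=genome_rec.id,
        circle_start=A,
        circle_end=D,
        tss=tss,
        leader_len=L,
        tata_interval=(tata_start, tata_end),
        tata_offset=params.tata_offset,
        precursor_interval=(tss, trailer_end),
        gnar_interval=(A + gnar_pos, A + gnar_pos + 4),
        h8b_interval=(A + h8b_pos, A + h8b_pos + h8b_len),
        cdbox_interval=cd_interval,
        bhb=bhb,
        cleavage_sites=(bhb.cleavage1, bhb.cleavage2),
        cut_offset=delta,
    )
    truth.validate()
    assert truth.cleavage_sites == (A, D)

    features = [
        Feature(genome_rec.id, tata_start, tata_end, "+", "tata_box"),
        Feature(genome_rec.id, tss, A, "+", "leader", {"tss": tss}),
        Feature(genome_rec.id, A, D, "+", "circle", {"name": "permuted_ncRNA"}),
        Feature(genome_rec.id, *truth.gnar_interval, "+", "gnar_tetraloop"),
        Feature(genome_rec.id, *truth.h8b_interval, "+", "h8b"),
        Feature(genome_rec.id, bhb.strand1[0], bhb.strand1[1], "+", "bhb", {"side": "leader"}),
        Feature(genome_rec.id, bhb.strand2[0], bhb.strand2[1], "+", "bhb", {"side": "trailer"}),
    ]
    if cd_interval is not None:
        features.append(Feature(genome_rec.id, *cd_interval, "+", "cdbox_srna"))
    return genome_rec, truth, features


def _qualities(rng: np.random.Generator, n: int, params: ReadSimParams) -> list[int]:
    if params.qual_model == "constant":
        return [params.qual_const] * n
    if params.qual_model == "ramp":
        hi, lo = params.qual_ramp
        return [int(round(hi + (lo - hi) * i / max(1, n - 1))) for i in range(n)]
    raise ParameterError(f"unknown qual_model {params.qual_model!r}")


def _mutate(rng: np.random.Generator, seq: str, err: float) -> str:
    if err <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < err)[0]
    for i in hits:
        out[i] = _choose(rng, "".join(x for x in BASES if x != out[i]))
    return "".join(out)


def simulate_reads(
    genome: SeqRecord, truth: TruthSet, simparams: ReadSimParams
) -> list[SeqRecord]:
    """Simulate precursor and circular-RNA reads; labels land in truth.read_labels.

    Precursor reads are substrings of [tss, trailer_end): a fraction
    frac_tss_anchored starts exactly at the TSS, the rest start uniformly.
    Circular reads are read_len-substrings of the doubled circle string with
    start uniform in [0, C), so a read may cross the A/D junction exactly
    once (read_len < C excludes double wrapping). Substitution errors are
    i.i.d. at rate err. An optional 3' adapter is appended to inserts that
    run off the precursor's end, then the read is truncated to read_len.
    """
    rng = np.random.default_rng(simparams.seed)
    A, D = truth.circle_start, truth.circle_end
    C = D - A
    R = simparams.read_len
    if R >= C:
        raise ParameterError("read_len must be < circle_len")

    reads: list[SeqRecord] = []
    truth.read_labels.clear()

    t_end = truth.precursor_interval[1]
    span = t_end - truth.tss
    if span < R:
        raise ParameterError("precursor shorter than read_len")

    for i in range(simparams.n_precursor):
        if rng.random() < simparams.frac_tss_anchored:
            start = truth.tss
        else:
            start = int(rng.integers(truth.tss, t_end))
        insert = genome.seq[start : min(start + R, t_end)]
        if simparams.adapter and len(insert) < R:
            insert = (insert + simparams.adapter.upper())[:R]
        seq = _mutate(rng, insert, simparams.err)
        rid = f"pre_{i:05d}"
        reads.append(SeqRecord(rid, seq, _qualities(rng, len(seq), simparams)))
        truth.read_labels[rid] = ReadLabel("precursor", False, start)

    doubled = genome.seq[A:D] * 2
    m = simparams.min_anchor
    for i in range(simparams.n_circular):
        u = int(rng.integers(0, C))
        insert = doubled[u : u + R]
        spanning = (C - u >= m) and (u + R - C >= m)
        seq = _mutate(rng, insert, simparams.err)
        rid = f"circ_{i:05d}"
        reads.append(SeqRecord(rid, seq, _qualities(rng, len(seq), simparams)))
        truth.read_labels[rid] = ReadLabel("circular", bool(spanning), u)
    return reads
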