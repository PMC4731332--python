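"""Pipeline orchestration: simulate -> process -> scan -> call.

Every stage is independently invokable with files as the only interface (see
the CLI), and `run_pipeline` composes them in memory for synthetic runs. The
configuration is a nested dataclass tree that round-trips losslessly through
YAML; unknown keys are rejected. A fixed (config, seed) pair yields a
byte-identical report (no timestamps enter the report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .formats import Feature, SeqRecord, write_bed, write_fasta, write_fastq, write_gff
from .junction import (
    call_tss,
    detect_circular_junctions,
    find_bhb,
    find_tata,
    junction_votes,
    predict_cleavage,
    validate_junction_vs_bhb,
)
from .motif_scan import DEFAULT_H8B_PATTERN, GNAR_PATTERN, scan_candidate_loci
from .read_processing import (
    AlignmentRecord,
    GenomeIndex,
    Scoring,
    align_read,
    coverage_profiles,
    length_filter,
    quality_trim,
    trim_adapter,
    write_alignments_tsv,
)
from .synthetic import LocusParams, ReadSimParams, TruthSet, build_locus, simulate_reads

log = logging.getLogger("permacirc")


@dataclass
class ProcessConfig:
    quality_limit: float = 0.05
    max_ambiguities: int = 2
    min_len: int = 15
    adapter: Optional[str] = None
    match: int = 1
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1
    seed_len: int = 12


@dataclass
class ScanConfig:
    gnar: str = GNAR_PATTERN
    h8b_pattern: str = DEFAULT_H8B_PATTERN
    window: int = 400
    step: int = 50
    min_fold: float = 0.5
    motif_bonus: float = 0.25


@dataclass
class CallConfig:
    min_clip: int = 8
    min_support: int = 2
    max_clip_mismatch: int = 1
    search_radius: int = 1000
    tss_search_window: int = 60
    tss_min_frac: float = 0.5
    tata_pattern: str = "TTAATA"
    tata_search_window: int = 40
    tata_max_mismatch: int = 0
    bhb_flank: int = 18
    cut_offset: int = 2


@dataclass
class PipelineConfig:
    """Global seed plus one namespaced section per stage.

    The stage-local seeds in `locus` and `reads` are derived from the global
    seed at run time (seed and seed + 10007), so one integer controls the
    whole pipeline.
    """

    locus: LocusParams = field(default_factory=LocusParams)
    reads: ReadSimParams = field(default_factory=ReadSimParams)
    process: ProcessConfig = field(default_factory=ProcessConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    call: CallConfig = field(default_factory=CallConfig)
    seed: int = 0
    verbosity: int = 1


_SECTIONS = {
    "locus": LocusParams,
    "reads": ReadSimParams,
    "process": ProcessConfig,
    "scan": ScanConfig,
    "call": CallConfig,
}


def _dataclass_from_dict(cls, data: dict, context: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        default = names[key].default
        if isinstance(default, tuple) and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _dataclass_from_dict(cls, data.pop(name) or {}, name)
    top = {f.name for f in dataclasses.fields(PipelineConfig)} - set(_SECTIONS)
    unknown = set(data) - top
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs.update(data)
    return PipelineConfig(**kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["reads"]["qual_ramp"] = list(d["reads"]["qual_ramp"])
    return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage functions
# ---------------------------------------------------------------------------


def process_reads(
    reads: Sequence[SeqRecord], genome: SeqRecord, cfg: ProcessConfig
) -> tuple[list[SeqRecord], list[AlignmentRecord], dict]:
    """Trim, filter, and align reads; returns (kept reads, alignments, counts)."""
    n_in = len(reads)
    trimmed = [quality_trim(r, cfg.quality_limit, cfg.max_ambiguities) for r in reads]
    if cfg.adapter:
        trimmed = [trim_adapter(r, cfg.adapter) for r in trimmed]
    kept = length_filter([r for r in trimmed if len(r)], cfg.min_len)
    scoring = Scoring(cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend)
    index = GenomeIndex(genome, cfg.seed_len)
    alignments: list[AlignmentRecord] = []
    n_aligned = n_unique = 0
    for read in kept:
        recs = align_read(read, index, scoring, cfg.seed_len)
        if recs:
            n_aligned += 1
            n_unique += len(recs) == 1
        alignments.extend(recs)
    counts = {
        "n_input": n_in,
        "n_after_trim_filter": len(kept),
        "n_aligned": n_aligned,
        "n_unique_placement": n_unique,
    }
    return kept, alignments, counts


def count_feature_reads(
    alignments: Sequence[AlignmentRecord], features: Sequence[Feature]
) -> dict[str, int]:
    """Reads per feature by the alignment-midpoint rule, strand-aware."""
    counts: dict[str, int] = {}
    for f in features:
        label = f.attrs.get("name", f"{f.kind}:{f.start}-{f.end}")
        n = sum(
            1
            for a in alignments
            if a.strand == f.strand and f.start <= (a.ref_start + a.ref_end) // 2 < f.end
        )
        counts[label] = counts.get(label, 0) + n
    return counts


def _bhb_dotbracket(motif) -> dict[str, str]:
    """Per-strand bracket strings over the motif extents (strand1 '(' / strand2 ')')."""
    out = {}
    for name, (lo, hi), open_char in (
        ("strand1", motif.strand1, "("),
        ("strand2", motif.strand2, ")"),
    ):
        chars = ["."] * (hi - lo)
        segs = [motif.outer1, motif.central, motif.outer2]
        idx = 0 if name == "strand1" else 1
        for seg in segs:
            s, e = seg[idx]
            for i in range(s, e):
                chars[i - lo] = open_char
        out[name] = "".join(chars)
    return out


def _motif_dict(m) -> dict:
    return {
        "seq_id": m.seq_id,
        "strand1": list(m.strand1),
        "strand2": list(m.strand2),
        "outer1": [list(m.outer1[0]), list(m.outer1[1])],
        "central": [list(m.central[0]), list(m.central[1])],
        "outer2": [list(m.outer2[0]), list(m.outer2[1])],
        "bulge1": list(m.bulge1),
        "bulge2": list(m.bulge2),
        "cleavage": [m.cleavage1, m.cleavage2],
        "score": m.score,
        "dotbracket": _bhb_dotbracket(m),
    }


def call_stage(
    alignments: Sequence[AlignmentRecord],
    reads: Sequence[SeqRecord],
    genome: SeqRecord,
    cfg: CallConfig,
    features: Sequence[Feature] = (),
) -> dict:
    """Junction, TSS, TATA, and BHB calls as a JSON-ready dictionary."""
    votes = junction_votes(
        alignments, reads, genome,
        min_clip=cfg.min_clip, max_clip_mismatch=cfg.max_clip_mismatch,
        search_radius=cfg.search_radius,
    )
    junctions = detect_circular_junctions(
        alignments, reads, genome,
        min_clip=cfg.min_clip, min_support=cfg.min_support,
        max_clip_mismatch=cfg.max_clip_mismatch, search_radius=cfg.search_radius,
    )
    result: dict = {
        "junctions": [
            {
                "seq_id": j.seq_id,
                "acceptor": j.acceptor,
                "donor": j.donor,
                "strand": j.strand,
                "circle_len": j.donor - j.acceptor,
                "support": j.support,
            }
            for j in junctions
        ],
        "discordant_votes": len(votes) > 1,
        "all_votes": [
            {"acceptor": A, "donor": D, "strand": s, "support": len(ids)}
            for (A, D, s), ids in sorted(votes.items())
        ],
        "flags": [],
    }
    if not junctions:
        result["flags"].append("no junction evidence")
        result.update({"tss": None, "tata": None, "bhb": None})
        return result

    top = junctions[0]
    prof = coverage_profiles([a for a in alignments if a.ref_id == genome.id], genome)
    tss_call = call_tss(prof.starts5[top.strand], top, cfg.tss_search_window, cfg.tss_min_frac)
    if tss_call is None:
        result["tss"] = None
        result["flags"].append("no TSS call")
        result["tata"] = None
    else:
        result["tss"] = {
            "tss": tss_call.tss,
            "leader_len": tss_call.leader_len,
            "support": tss_call.support,
        }
        tata = find_tata(
            genome, tss_call.tss, cfg.tata_pattern,
            cfg.tata_search_window, cfg.tata_max_mismatch,
        )
        if tata is None:
            result["tata"] = None
            result["flags"].append("no TATA match")
        else:
            hit, offset = tata
            result["tata"] = {
                "start": hit.start,
                "end": hit.end,
                "matched": hit.matched,
                # both anchoring conventions for "n nt upstream of the TSS"
                "offset_from_3prime": offset,
                "offset_from_5prime": tss_call.tss - hit.start,
            }

    motifs = find_bhb(
        genome, top, tss=result["tss"]["tss"] if result["tss"] else None,
        flank=cfg.bhb_flank, cut_offset=cfg.cut_offset,
    )
    if not motifs:
        result["bhb"] = None
        result["flags"].append("no BHB configuration")
    else:
        best = motifs[0]
        cleavage = predict_cleavage(best, cfg.cut_offset)
        result["bhb"] = {
            "top": _motif_dict(best),
            "n_configurations": len(motifs),
            "predicted_cleavage": list(cleavage),
            "validated_against_junction": validate_junction_vs_bhb(top, best, cfg.cut_offset),
        }
    if features:
        uniq = _unique_placement(alignments)
        result["feature_read_counts"] = count_feature_reads(uniq, features)
    return result


def _unique_placement(alignments: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    by_read: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        by_read.setdefault(a.read_id, []).append(a)
    return [alns[0] for alns in by_read.values() if len(alns) == 1]


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute simulate -> process -> scan -> call; returns the report dict.

    Identical (config, seed) produce identical reports. When outdir is given,
    all stage artifacts (FASTA/FASTQ/GFF3/BED/TSV/JSON) are written there.
    """
    logging.basicConfig(level=logging.INFO if config.verbosity else logging.WARNING,
                        format="%(name)s %(levelname)s %(message)s")
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    locus = dataclasses.replace(config.locus, seed=config.seed)
    simparams = dataclasses.replace(config.reads, seed=config.seed + 10007)

    try:
        genome, truth, features = build_locus(locus)
        reads = simulate_reads(genome, truth, simparams)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    log.info("simulate: genome %d nt, %d reads", len(genome.seq), len(reads))
    if out is not None:
        write_fasta([genome], out / "genome.fasta")
        write_fastq(reads, out / "reads.fastq")
        write_gff(features, out / "features.gff3")
        truth.to_json(out / "truth.json")

    try:
        kept, alignments, counts = process_reads(reads, genome, config.process)
    except Exception as exc:
        raise RuntimeError(f"stage 'process' failed: {exc}") from exc
    log.info("process: %s", counts)
    if out is not None:
        write_alignments_tsv(alignments, out / "aln.tsv")

    try:
        candidates = scan_candidate_loci(
            genome,
            gnar=config.scan.gnar,
            h8b_pattern=config.scan.h8b_pattern,
            window=config.scan.window,
            step=config.scan.step,
            min_fold=config.scan.min_fold,
            motif_bonus=config.scan.motif_bonus,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'scan' failed: {exc}") from exc
    log.info("scan: %d candidate locus/loci", len(candidates))

    try:
        calls = call_stage(alignments, kept, genome, config.call, features)
    except Exception as exc:
        raise RuntimeError(f"stage 'call' failed: {exc}") from exc

    report = {
        "provenance": {
            "tool": "permacirc",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": config_hash(config),
        },
        "genome": {"id": genome.id, "length": len(genome.seq)},
        "read_processing": counts,
        "candidates": [
            {
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "fold_score": round(c.fold_score, 6),
                "combined_score": round(c.combined_score, 6),
                "n_motif_hits": len(c.motif_hits),
            }
            for c in candidates
        ],
        **calls,
    }
    if out is not None:
        junction_feats = [
            Feature(genome.id, j["acceptor"], j["donor"], j["strand"], "circle",
                    {"name": "called_junction", "support": j["support"]})
            for j in report["junctions"]
        ]
        if junction_feats:
            write_bed(junction_feats, out / "junction.bed")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report
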