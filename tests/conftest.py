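import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from permacirc.junction import call_tss, detect_circular_junctions, find_tata
from permacirc.read_processing import (
    GenomeIndex,
    align_read,
    coverage_profiles,
    length_filter,
    quality_trim,
)
from permacirc.synthetic import LocusParams, ReadSimParams, build_locus, simulate_reads

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def run_junction_pipeline(seed, circle_len=None, leader_len=None, err=0.0,
                          depth=30, read_len=75, **locus_kw):
    """Simulate a locus at the given coverage depth and run trim/align/call.

    Geometry defaults to the standard locus; circle_len/leader_len may be
    randomized by the caller. Returns a dict with all intermediate products.
    """
    lp_kw = dict(seed=seed, **locus_kw)
    if circle_len is not None:
        lp_kw["circle_len"] = circle_len
    if leader_len is not None:
        lp_kw["leader_len"] = leader_len
    params = LocusParams(**lp_kw)
    genome, truth, features = build_locus(params)
    C = truth.circle_len
    n = max(2, round(depth * C / read_len))
    rp = ReadSimParams(n_precursor=n, n_circular=n, read_len=read_len, err=err,
                       seed=seed + 1000)
    reads = length_filter([quality_trim(r) for r in simulate_reads(genome, truth, rp)])
    index = GenomeIndex(genome)
    alignments = [a for r in reads for a in align_read(r, index)]
    junctions = detect_circular_junctions(alignments, reads, genome)
    result = {
        "genome": genome, "truth": truth, "features": features, "reads": reads,
        "alignments": alignments, "junctions": junctions,
        "tss": None, "tata": None,
    }
    if junctions:
        top = junctions[0]
        prof = coverage_profiles(alignments, genome)
        tss = call_tss(prof.starts5[top.strand], top)
        result["tss"] = tss
        if tss is not None:
            result["tata"] = find_tata(genome, tss.tss)
    return result


def random_geometry(seed):
    """The randomized study geometry used by the recovery suite."""
    rng = np.random.default_rng(seed)
    return int(rng.integers(80, 401)), int(rng.integers(5, 41))


@pytest.fixture(scope="session")
def default_locus():
    """Standard synthetic locus (309-nt circle, 23-nt leader, TATA at -26)."""
    return build_locus(LocusParams(seed=1))


@pytest.fixture(scope="session")
def default_run():
    """One full junction-calling run on the standard locus."""
    return run_junction_pipeline(seed=1)
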