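"""Simulate reads and call the circularization junction from soft clips.

Reads crossing the ligated termini align with one end soft-clipped; the clip
matches the distant terminus and votes for an (acceptor, donor) pair. The
TSS is the dominant 5'-read-start upstream of the acceptor, and the TATA box
is matched upstream of the TSS.
"""

from permacirc import (
    GenomeIndex,
    LocusParams,
    ReadSimParams,
    align_read,
    build_locus,
    call_tss,
    coverage_profiles,
    detect_circular_junctions,
    find_tata,
    length_filter,
    quality_trim,
    simulate_reads,
)

genome, truth, _ = build_locus(LocusParams(seed=1))
reads = simulate_reads(genome, truth, ReadSimParams(n_precursor=60, n_circular=120, seed=2))

reads = length_filter([quality_trim(r) for r in reads])
index = GenomeIndex(genome)
alignments = [a for r in reads for a in align_read(r, index)]

junctions = detect_circular_junctions(alignments, reads, genome)
j = junctions[0]
print(f"junction: acceptor {j.acceptor}, donor {j.donor} "
      f"({j.donor - j.acceptor} nt circle), {j.support} supporting reads")

profiles = coverage_profiles(alignments, genome)
tss = call_tss(profiles.starts5[j.strand], j)
print(f"TSS {tss.tss} -> leader {tss.leader_len} nt ({tss.support} 5' starts)")

hit, offset = find_tata(genome, tss.tss)
print(f"TATA {hit.matched} at [{hit.start}, {hit.end}), {offset} nt upstream of the TSS")

# with error-free reads these equal the generator's truth exactly
assert (j.acceptor, j.donor) == (truth.circle_start, truth.circle_end)
assert tss.leader_len == truth.leader_len and offset == truth.tata_offset
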