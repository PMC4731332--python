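"""Scan a genome for candidate permuted-SRP-RNA loci.

A window qualifies when a GNAR tetraloop hit and a helix-8b hit co-occur on
one strand and the window's maximum-base-pairing fraction (Nussinov) clears
the folding threshold; qualifying windows are merged and ranked.
"""

from permacirc import LocusParams, build_locus, nussinov_fold, scan_candidate_loci

genome, truth, _ = build_locus(LocusParams(seed=3))
candidates = scan_candidate_loci(genome)

print(f"{len(candidates)} candidate locus/loci on a {len(genome.seq)} nt genome")
for c in candidates:
    print(f"  [{c.start}, {c.end}) {c.strand}  fold {c.fold_score:.3f} "
          f"combined {c.combined_score:.3f}  motif hits: "
          f"{sorted({h.pattern_name for h in c.motif_hits})}")

top = candidates[0]
print(f"\ntrue circle [{truth.circle_start}, {truth.circle_end}) "
      f"is inside the top candidate: "
      f"{top.start <= truth.circle_start and top.end >= truth.circle_end}")

# the planted GNAR hairpin folds as a genuine tetraloop
loop = genome.seq[truth.gnar_interval[0] - 5 : truth.gnar_interval[1] + 5]
print(f"planted hairpin fold: {loop} -> {nussinov_fold(loop).dotbracket}")
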