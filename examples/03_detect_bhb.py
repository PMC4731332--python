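"""Detect the bulge-helix-bulge motif at the junction flanks and validate it.

The BHB (outer helix >= 2 bp, 3-nt bulge, central 4-bp helix, 3-nt bulge,
outer helix >= 2 bp) is the substrate of the archaeal tRNA splicing
endonuclease; its predicted cleavage points must coincide with the observed
mature termini for the circularization model to hold.
"""

from permacirc import (
    CircularJunction,
    LocusParams,
    build_locus,
    find_bhb,
    predict_cleavage,
    validate_junction_vs_bhb,
)

genome, truth, _ = build_locus(LocusParams(seed=1))
junction = CircularJunction(
    genome.id, truth.circle_start, truth.circle_end, "+", support=28
)

motifs = find_bhb(genome, junction)
top = motifs[0]
print(f"{len(motifs)} BHB configuration(s); top score {top.score} paired bases")
print(f"  leader-side strand  {top.strand1}, trailer-side strand {top.strand2}")
print(f"  central helix {top.central}")
print(f"  bulges {top.bulge1} / {top.bulge2}")

c1, c2 = predict_cleavage(top, cut_offset=2)
print(f"predicted cleavage: {c1}, {c2}  observed termini: "
      f"{junction.acceptor}, {junction.donor}")
print("validated:", validate_junction_vs_bhb(junction, top))
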