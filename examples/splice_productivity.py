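"""Alternative splicing, TE overlap, and transcript productivity.

Constructs a gene whose second intron contains a TE carrying an in-frame
stop codon. The clean isoform is productive; the intron-retaining isoform
gains a premature termination codon whose position is located relative to
the TE's projection into transcript coordinates.
"""

import numpy as np

from telocus import (
    TELocus,
    annotate_te_overlap,
    classify_productivity,
    detect_as_features,
    locate_stop_vs_te,
    make_isoform,
)

rng = np.random.default_rng(0)
filler = "".join(np.array(list("AC"))[rng.integers(0, 2, 120)])
exon1 = "ATG" + filler[: (len(filler) // 3) * 3]
te_seq = "TAA" + "".join(np.array(list("AC"))[rng.integers(0, 2, 117)])  # stop + body
intron = "C" * ((3 - len(exon1) % 3) % 3) + te_seq + "CAC" * 40
exon2 = "CACCAC" * 30 + "TAA"
genome = {"chr1": exon1 + intron + exon2}

b1 = (0, len(exon1))
b2 = (len(exon1) + len(intron), len(genome["chr1"]))
reference = make_isoform("ref", "g1", "chr1", "+", [b1, b2], genome)
retained = make_isoform("ir", "g1", "chr1", "+",
                        [(0, b2[0] + 60), (b2[0] + 120, b2[1])], genome)

te = TELocus(id="TE1", chrom="chr1", start=len(exon1), end=len(exon1) + len(te_seq),
             strand="+", family="hAT-X", superfamily="hAT", canonical_length=1500)

features = annotate_te_overlap(detect_as_features(retained, reference), [te])
for f in features:
    print(f"{f.type} at [{f.start},{f.end}), TE overlaps: {f.te_overlaps}")

for iso in (reference, retained):
    call = classify_productivity(iso)
    print(f"{iso.id}: {call.klass}")
    if call.klass == "PTC":
        ir = next(f for f in features if f.type == "IR")
        call = locate_stop_vs_te(call, iso, ir, te)
        where = call.stop_vs_te
        gap = ("" if call.distance_bp is None
               else f", {call.distance_bp} bp away in transcript coordinates")
        print(f"   premature stop {where} the TE{gap}")
# PRO = productive; PTC = stop >= 50 nt upstream of the last junction (NMD
# convention); the retained TE intron introduces the premature stop.
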