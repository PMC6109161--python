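"""IS-element detection between two related prophage genomes.

Compares a prophage against a relative carrying a 1,399 bp IS30-like
insertion (50 bp terminal inverted repeats, 3 bp target-site
duplication) plus a small motif-bounded inversion, and reads off both
signatures from unique-anchor collinear blocks.
"""

import numpy as np

from pforge import compare
from pforge._seq import revcomp

rng = np.random.default_rng(5)
b = "".join(rng.choice(list("ACGT"), 8000))

# plant an IS30-like element with TIRs and a TSD
arm = "".join(rng.choice(list("ACGT"), 50))
core = "".join(rng.choice(list("ACGT"), 1299))
element = arm + core + revcomp(arm)
tsd = b[2997:3000]
a = b[:3000] + element + tsd + b[3000:]

# plant a motif-bounded ~500 bp inversion further downstream
motif = "CAGGGTTA"
a = a[:6000] + motif + a[6000:6500] + motif + a[6500:]
start = 6000 + len(motif)
b2 = a[:start] + revcomp(a[start : start + 500]) + a[start + 500 :]

blocks = compare.anchor_blocks(b2, a, k=15)
print(f"collinear blocks: {len(blocks)} "
      f"({sum(bl.strand == '-' for bl in blocks)} inverted)")

insertions = compare.find_insertions(compare.anchor_blocks(a, b, k=15), a, b,
                                     min_len=1000)
for rec in insertions:
    tir, tsd_len = compare.is_element_signature(
        element, a[:3000][-20:], tsd + a[4399 + 3 : 4399 + 20], max_mismatch=0
    )
    print(f"insertion at {rec.position_in_a}: {rec.length} bp "
          f"(element + duplicated target); TIR {tir} bp, TSD {tsd_len} bp")

for hit in compare.detect_simple_inversion(b2, a, junction_motif=motif):
    print(f"inverted block {hit.block.a_start}-{hit.block.a_end} "
          f"({hit.block.a_len} bp), junction motif {motif} matched: "
          f"{hit.motif_matched}")
print("TIR+TSD marks a transposon hop; the motif-bounded flip mirrors a "
      "trans-acting phase-variation locus.")
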