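"""Attachment-site analysis of the published prophage core sequences.

Aligns attL against attR for each prophage, infers the conserved
strand-exchange (crossover) window across all dnaJ2-locus sites, and
derives the theoretical pre-integration attB and phage attP sites.
"""

from pforge import attsite, catalog

print("attL/attR alignment per prophage (core, mismatches, indels):")
for locus, entries in catalog.ATT_SITES.items():
    for name, sites in entries.items():
        pair = attsite.align_att_pair(sites["attL"], sites["attR"])
        print(f"  {locus:9s} {name:22s} core={pair.core_length:2d} bp  "
              f"mm={pair.mismatches}  indels={pair.indels}")

# conserved windows across all 14 dnaJ2-locus attL/attR sequences
windows = attsite.infer_crossover(catalog.dnaj2_sites())
print("\nConserved windows across all dnaJ2 att sites (len desc):")
for w in windows[:3]:
    print(f"  column {w.start:2d}, {w.length} bp: {w.sequence}")
print("The 7 bp run is the candidate strand-exchange (crossover) window.")

# derive attB/attP for one prophage using that window
sites = catalog.ATT_SITES["dnaJ2"]["Bb48phi1"]
pair = attsite.align_att_pair(sites["attL"], sites["attR"])
seven = next(w for w in windows if w.sequence == "GCAAGTT")
att_set = attsite.derive_attB_attP(pair, seven)
print(f"\nBb48phi1 derived attB: {att_set.attB}")
print(f"Bb48phi1 derived attP: {att_set.attP}")
print("attB carries the host flanks, attP the phage flanks, each with one "
      "copy of the crossover.")
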