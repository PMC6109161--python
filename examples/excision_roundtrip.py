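"""In-silico prophage excision and reintegration on a synthetic lysogen.

Builds a lysogen whose prophage splits a marker gene at the attachment
core, excises the prophage as a circular virion genome, verifies the
marker open reading frame is restored, and reintegrates to recover the
original chromosome byte-for-byte.
"""

from pforge import attsite, synthetic
from pforge._seq import translate

genome, truth = synthetic.make_lysogen(seed=1)
e = truth.expected
print(f"lysogen: {len(genome)} bp; attL at {e['attL_interval']}, "
      f"attR at {e['attR_interval']}")

res = attsite.excise(
    genome, e["attL_interval"], e["attR_interval"],
    (e["crossover_offset"], e["crossover_len"]),
)
print(f"excised: host {len(res.host)} bp + virion circle {len(res.virion)} bp "
      f"(total conserved: {len(res.host) + len(res.virion) == len(genome)})")

lo, hi = e["marker_interval"]
restored = translate(res.host[lo - 1 : hi]) == e["marker_protein"]
print(f"marker gene restored intact by excision: {restored}")

back = attsite.integrate(
    res.host, res.attB_interval, res.virion, res.attP_interval,
    (res.crossover_in_attB[0], res.crossover_in_attP[0], e["crossover_len"]),
)
print(f"re-integration reproduces the lysogen exactly: {back == genome}")
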