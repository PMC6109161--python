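"""Integration-dependent immunity: virion vs prophage repressor forms.

Reconstructs the immunity repressor from a synthetic lysogen whose attP
lies inside the repressor gene near its 3' end: the virion-encoded form
carries extra C-terminal residues with an ssrA-like degradation tag that
integration removes.
"""

from pforge import immunity, synthetic

lysogen, truth = synthetic.make_immunity_locus(seed=7, extension_residues=18)
e = truth.expected
forms = immunity.reconstruct_repressor_forms(
    lysogen, e["attL_interval"], e["attR_interval"],
    tuple(e["crossover"]), e["repressor_start"],
)
print(f"prophage-encoded repressor: {len(forms.prophage_protein)} aa")
print(f"virion-encoded repressor:   {len(forms.virion_protein)} aa")
print(f"virion-only C-terminal extension: {len(forms.extension)} aa "
      f"({forms.extension})")
print(f"integration-dependent architecture: {forms.integration_dependent}")
print(f"ssrA-like tag match in the virion form: {forms.tag_hit}")
print("Integration truncates the gene at attR, removing the degradation "
      "tag and stabilizing the prophage repressor.")
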