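# Signature residue rules per gene (model_column is 1-based on the profile's
# match columns).  The carnitine oxygenase family carries a conserved
# "bridging" glutamate at the position homologous to E205 of the reference
# enzyme, distinguishing it from aspartate-bearing non-TMA Rieske oxygenases.
# The choline TMA-lyase rule set is left for the user to fill in for their
# seed alignment (signature positions depend on the model's column indexing).
gene	model_column	allowed_residues	label
cntA	205	E	bridging_glutamate_E205
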