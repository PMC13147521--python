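# dm6-like chromosome 2 geometry. Arm lengths follow the dm6 assembly;
# euchromatin/heterochromatin boundaries approximate the somatic H3K9me3
# domains and are config constants, not inferred from data. The gap is the
# unassembled centromeric satellite between the 2L and 2R assemblies.
name: "2"
shape: metacentric
gap_length: 4000000
arms:
  - name: 2L
    length: 23513712
    orientation: telomere_to_centromere
    het_boundary: 22000000
  - name: 2R
    length: 25286936
    orientation: centromere_to_telomere
    het_boundary: 5900000
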