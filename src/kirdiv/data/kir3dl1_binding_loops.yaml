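# Binding-loop residue positions, numbered on the mature KIR3DL1 protein.
#
# The eight ligand-contact loops characterised crystallographically for
# KIR3DL1 bound to HLA-B, totalling 45 positions.  This file is an editable
# convention: the loop membership shipped here places the anchor residues
# discussed for KIR3DL3 (33-34, 141, 167, 283) inside their loops; adjust
# against a structural reference before cross-gene comparisons.
loops:
  D0-A: [31, 32, 33, 34, 35, 36]
  D0-B: [49, 50, 51, 52, 53]
  D1-A: [104, 105, 106, 107, 108]
  D1-B: [138, 139, 140, 141, 142, 143]
  D1-C: [163, 164, 165, 166, 167, 168]
  D2-A: [200, 201, 202, 203, 204]
  D2-B: [226, 227, 228, 229, 230, 231, 232]
  D2-C: [279, 280, 281, 282, 283]
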