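# Default domain map for the KIR3DL3*00101 CDS (1-based inclusive codon
# coordinates over the full CDS, terminal stop codon included in TM/Cyt).
#
# This is an editable convention, not a database fact: the leader is 21
# codons (exons 1-2), so mature residue r sits at CDS codon r + 21, placing
# mature residue 147 at CDS nucleotides 502-504 within D1.  The Ig-domain
# boundaries follow the standard ~100-codon exon organisation of three-domain
# KIR (exons 3-5 encode D0, D1, D2); adjust per gene as needed.
leader_length_codons: 21
segments:
  - {label: Leader, start_codon: 1, end_codon: 21}
  - {label: D0, start_codon: 22, end_codon: 121}
  - {label: D1, start_codon: 122, end_codon: 221}
  - {label: D2, start_codon: 222, end_codon: 313}
  - {label: TM/Cyt, start_codon: 314, end_codon: 400}
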