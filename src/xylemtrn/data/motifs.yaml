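# Default cis-element consensus definitions (degenerate notation; see
# xylemtrn.motifs.parse_consensus).  Every entry can be overridden by
# pointing the pipeline at a user config with the same structure.
#
# SNBE: 19-bp secondary wall NAC-binding element consensus.
# SMRE: 7-bp secondary wall MYB-responsive element.
# WBOX: canonical WRKY transcription-factor binding element.
# TGTG: ATAF-class NAC core element found upstream of PCD genes.
SNBE: "(T/A)NN(C/T)(T/C/G)TNNNNNNNA(A/C)GN(A/C/T)(A/C/T)"
SMRE: "ACC(A/T)A(A/C)(T/C)"
WBOX: "TTGAC(C/T)"
TGTG: "TGTG[T/G/C]"
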