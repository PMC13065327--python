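# Default kinase consensus-motif definitions.
#
# Each motif maps a relative position (0 = the phospho-acceptor) to the
# allowed residues at that position, written as a string of one-letter
# codes. Position 0 defaults to "ST" when omitted. Only Polo_stringent
# ([DEN]x[ST]F) is a published, stage-specific Polo consensus; the others
# are common literature definitions and are meant to be overridden where a
# study defines its own panel. Result tables always echo the definitions
# used.
minimal_Cdk:
  1: P
strict_Cdk:
  1: P
  3: KR
Polo_stringent:
  -2: DEN
  1: F
minimal_Polo:
  -2: DE
Ipl1_Aurora:
  -2: RK
DDK:
  1: DE
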