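code_prefix,group,laterality_char_position
M75,A,4
M2551,C,5
M2561,B,5
S41,D,5
S43,D,5
S46,D,5
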