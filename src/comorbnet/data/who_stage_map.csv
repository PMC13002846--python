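category,stage
B02,2
A09,3
A15,3
A16,3
B37,3
B49,3
A17,4
A18,4
A81,4
B25,4
B45,4
B48,4
B58,4
B59,4
C46,4
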