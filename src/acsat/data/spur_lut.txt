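0000000000000000100101110111111100000000000000000111111111111111
0000000000000000011111111111111100000000000000001111111111111111
0000000000000000011111111111111100000000000000001111111111111111
0000000000000000111111111111111100000000000000001111111111111111
0000000000000000011111111111111100000000000000001111111111111111
0000000000000000111111111111111100000000000000001111111111111111
0000000000000000111111111111111100000000000000001111111111111111
0000000000000000111111111111111100000000000000001111111111111111
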