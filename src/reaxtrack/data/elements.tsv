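# atom type -> element symbol
1 C
2 H
3 O
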