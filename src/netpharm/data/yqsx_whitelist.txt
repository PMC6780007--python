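MOL000676
MOL000360
MOL011782
MOL002143
MOL002111
MOL000748
MOL001436
MOL002819
MOL000067
MOL007579
MOL000061
MOL000050
MOL000071
MOL000054
MOL003971
MOL003969
MOL000052
MOL000042
MOL005449
MOL005448
MOL000068
MOL000056
MOL000041
MOL000065
MOL001780
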