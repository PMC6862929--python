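# LASTZ-style score file: default nucleotide substitution scores (HOXD70)
# and the default affine gap penalties.  A gap of length g costs O + g*E.
O = 400
E = 30
      A     C     G     T
A    91  -114   -31  -123
C  -114   100  -125   -31
G   -31  -125   100  -114
T  -123   -31  -114    91
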