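# schedule: loose
# Piecewise-linear gap cost schedule ("loose" linear-gap table used for
# chaining distantly related genomes).  single_cost applies when the gap is
# on one genome only (evaluated at that gap's size); both_cost applies when
# both genomes have unaligned bases (evaluated at dt+dq).  Costs are linearly
# interpolated between sizes and extrapolated with the last slope beyond the
# final row.
# size	single_cost	both_cost
0	0	0
1	325	625
2	360	660
3	400	700
11	450	750
2981	600	900
6167	1100	1400
20000	3600	4000
23548	7600	8000
200000	15600	16000
3000000	31600	32000
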