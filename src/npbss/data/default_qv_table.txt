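# Default QV proportion table for CLR simulation.
# Synthetic stand-in distribution: discretized Gamma(shape=2, scale=3.2)
# over integer QV 0-40, chosen so the table-averaged empirical per-base
# error probability is ~0.15, typical of PacBio continuous long reads.
# It is NOT a measured instrument profile; replace via -qv <file>.
# columns: QV proportion
0	0.041599
1	0.091303
2	0.111331
3	0.114028
4	0.107264
5	0.095915
6	0.082932
7	0.070009
8	0.058049
9	0.047466
10	0.038382
11	0.030755
12	0.024458
13	0.019325
14	0.015186
15	0.011876
16	0.009250
17	0.007177
18	0.005551
19	0.004281
20	0.003292
21	0.002526
22	0.001934
23	0.001478
24	0.001127
25	0.000858
26	0.000653
27	0.000496
28	0.000376
29	0.000285
30	0.000215
31	0.000163
32	0.000123
33	0.000093
34	0.000070
35	0.000053
36	0.000039
37	0.000030
38	0.000022
39	0.000017
40	0.000013
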