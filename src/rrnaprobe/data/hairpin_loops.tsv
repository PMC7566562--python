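# Hairpin loop initiation penalties for DNA at 37 C (unified NN framework,
# SantaLucia & Hicks 2004). dG37 in kcal/mol by loop length (nt). Lengths
# between listed values are linearly interpolated; beyond the largest entry a
# Jacobson-Stockmayer ln-extrapolation (+1.75*R*T*ln(n/n_max)) is applied.
loop_len	dG37
3	3.5
4	3.5
5	3.3
6	4.0
7	4.2
8	4.3
9	4.5
10	4.4
12	4.7
14	5.0
16	5.1
18	5.2
20	5.3
25	5.6
30	5.9
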