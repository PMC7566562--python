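# Nearest-neighbor parameters for DNA/DNA duplexes (Allawi & SantaLucia 1997, unified).
# step: dinucleotide on one strand, 5'->3'; the table is complement-symmetric
# (dG37 of a step equals dG37 of its reverse complement), so all 16 steps are listed.
# dH in kcal/mol, dS in cal/(mol*K). 'init' row: flat duplex initiation (two ends).
step	dH	dS
init	0.2	-5.7
AA	-7.9	-22.2
AC	-8.4	-22.4
AG	-7.8	-21.0
AT	-7.2	-20.4
CA	-8.5	-22.7
CC	-8.0	-19.9
CG	-10.6	-27.2
CT	-7.8	-21.0
GA	-8.2	-22.2
GC	-9.8	-24.4
GG	-8.0	-19.9
GT	-8.4	-22.4
TA	-7.2	-21.3
TC	-8.2	-22.2
TG	-8.5	-22.7
TT	-7.9	-22.2
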