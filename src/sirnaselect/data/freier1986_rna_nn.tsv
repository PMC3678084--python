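# RNA/RNA nearest-neighbor thermodynamic parameters (Watson-Crick helices)
# Source: Freier, Kierzek, Jaeger, Sugimoto, Caruthers, Neilson & Turner (1986)
#         Proc Natl Acad Sci USA 83:9373-9377, measured in 1 M NaCl.
# stack: dinucleotide read 5'->3' on one strand of the duplex; the table is
#        duplex-symmetric, so each stack carries the same parameters as its
#        reverse complement read from the opposite strand.
# dH: enthalpy change, kcal/mol.  dS: entropy change, cal/(mol*K).
# The 'init' row holds the helix initiation terms.
stack	dH	dS
init	0.0	-10.8
AA	-6.6	-18.4
AC	-10.2	-26.2
AG	-7.6	-19.2
AU	-5.7	-15.5
CA	-10.5	-27.8
CC	-12.2	-29.7
CG	-8.0	-19.4
CU	-7.6	-19.2
GA	-13.3	-35.5
GC	-14.2	-34.9
GG	-12.2	-29.7
GU	-10.2	-26.2
UA	-8.1	-22.6
UC	-13.3	-35.5
UG	-10.5	-27.8
UU	-6.6	-18.4
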