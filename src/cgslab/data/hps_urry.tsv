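# Default per-bead parameters for the one-bead-per-residue hydropathy-scale
# model with the Urry hydropathy ranking (lambda normalized to [0, 1]) and for
# the two generic DNA bead roles of the two-bead-per-nucleotide duplex
# stand-in (DB = charged sugar-phosphate backbone bead, DN = neutral base
# bead; see cgslab.topology.build_dna_duplex for the geometry).
# mass in g/mol, charge in e, sigma in Angstrom, lambda unitless.
bead	mass	charge	sigma	lambda
A	71.08	0.0	5.04	0.602942
R	156.19	1.0	6.56	0.558824
N	114.10	0.0	5.68	0.588236
D	115.09	-1.0	5.58	0.294119
C	103.14	0.0	5.48	0.647060
Q	128.13	0.0	6.02	0.558824
E	129.12	-1.0	5.92	0.000000
G	57.05	0.0	4.50	0.573530
H	137.14	0.0	6.08	0.764707
I	113.16	0.0	6.18	0.705883
L	113.16	0.0	6.18	0.720589
K	128.17	1.0	6.36	0.382354
M	131.19	0.0	6.18	0.676471
F	147.18	0.0	6.36	0.823530
P	97.12	0.0	5.56	0.758824
S	87.08	0.0	5.18	0.588236
T	101.10	0.0	5.62	0.588236
W	186.21	0.0	6.78	1.000000
Y	163.18	0.0	6.46	0.897059
V	99.07	0.0	5.86	0.664707
DB	180.00	-1.0	6.00	0.100000
DN	130.90	0.0	5.50	0.700000
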