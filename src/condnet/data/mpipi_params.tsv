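# Residue-level bead parameters for the Mpipi-style potential used by condnet.
# SYNTHETIC, model-faithful table: the published residue-resolution model
# distributes its full per-pair table externally, so this packaged table is a
# representative reconstruction built from standard residue masses, HPS-style
# bead diameters, fractional side-chain charges (+-0.75 e, His +0.375 e), and
# per-residue Wang-Frenkel energy scales combined geometrically.  The tyrosine
# scale is anchored so that the Y-Y well depth is exactly 0.42 kcal/mol.
# Swap in a different table with forcefield.load_parameter_table(path).
#
# columns: residue  mass(amu)  charge(e)  sigma(A)  eps(kcal/mol)  mu
residue	mass	charge	sigma	eps	mu
A	71.08	0.0	5.04	0.23	2
R	156.19	0.75	6.56	0.30	2
N	114.10	0.0	5.68	0.22	2
D	115.09	-0.75	5.58	0.15	2
C	103.14	0.0	5.48	0.26	2
Q	128.13	0.0	6.02	0.22	2
E	129.12	-0.75	5.92	0.15	2
G	57.05	0.0	4.50	0.20	2
H	137.14	0.375	6.08	0.30	2
I	113.16	0.0	6.18	0.29	2
L	113.16	0.0	6.18	0.29	2
K	128.17	0.75	6.36	0.15	2
M	131.19	0.0	6.18	0.30	2
F	147.18	0.0	6.36	0.38	2
P	97.12	0.0	5.56	0.25	2
S	87.08	0.0	5.18	0.20	2
T	101.10	0.0	5.62	0.22	2
W	186.21	0.0	6.78	0.55	2
Y	163.18	0.0	6.46	0.42	2
V	99.07	0.0	5.86	0.26	2
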