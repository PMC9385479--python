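# Nearest-neighbour free energies for RNA/RNA Watson-Crick helices at 37 C
# (Xia et al. 1998 / Turner rules). Steps are keyed by the top-strand
# dinucleotide read 5'->3'; the bottom strand is its Watson-Crick complement.
# Values in kcal/mol.
step	dg37_kcal_mol
AA	-0.93
AC	-2.24
AG	-2.08
AU	-1.10
CA	-2.11
CC	-3.26
CG	-2.36
CU	-2.08
GA	-2.35
GC	-3.42
GG	-3.26
GU	-2.24
UA	-1.33
UC	-2.35
UG	-2.11
UU	-0.93
init	4.09
terminal_au	0.45
symmetry	0.43
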