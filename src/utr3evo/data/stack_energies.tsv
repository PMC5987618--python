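# Watson-Crick nearest-neighbor stacking free energies for RNA duplexes,
# delta-G at 37 C in kcal/mol (Turner 2004 parameter set).
# Key: the 5'->3' dinucleotide on the miRNA strand; the perfectly
# complementary antiparallel target dinucleotide is implied.
dinucleotide	delta_g
AA	-0.93
AU	-1.10
AC	-2.24
AG	-2.08
UA	-1.33
UU	-0.93
UC	-2.35
UG	-2.11
CA	-2.11
CU	-2.08
CC	-3.26
CG	-2.36
GA	-2.35
GU	-2.24
GC	-3.42
GG	-3.26
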