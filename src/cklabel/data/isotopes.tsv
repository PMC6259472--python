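# Pinned atomic isotope table (IUPAC standard atomic masses and
# representative natural abundances). One line per isotope:
# element<TAB>mass_Da<TAB>abundance_fraction
# "D" is the deuterium label atom: a distinct symbol with a single
# isotope at abundance 1.0, never subject to natural variation.
H	1.007825	0.999885
H	2.014102	0.000115
D	2.014102	1.0
C	12.000000	0.9893
C	13.003355	0.0107
N	14.003074	0.99636
N	15.000109	0.00364
O	15.994915	0.99757
O	16.999132	0.00038
O	17.999160	0.00205
P	30.973762	1.0
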