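# SYNTHETIC FIXTURE: plausible default building blocks for the combinatorial
# schemes; reagent identities are user-configurable, only the table sizes
# (22 rows) and formula arithmetic are load-bearing.
name	block_class	formula
Ala	amino_acid	C3H7NO2
Ser	amino_acid	C3H7NO3
Pro	amino_acid	C5H9NO2
Val	amino_acid	C5H11NO2
Thr	amino_acid	C4H9NO3
Cys	amino_acid	C3H7NO2S
Leu	amino_acid	C6H13NO2
Ile	amino_acid	C6H13NO2
Asn	amino_acid	C4H8N2O3
Asp	amino_acid	C4H7NO4
Gln	amino_acid	C5H10N2O3
Glu	amino_acid	C5H9NO4
Lys	amino_acid	C6H14N2O2
Met	amino_acid	C5H11NO2S
His	amino_acid	C6H9N3O2
Phe	amino_acid	C9H11NO2
Arg	amino_acid	C6H14N4O2
Tyr	amino_acid	C9H11NO3
Trp	amino_acid	C11H12N2O2
Cit	amino_acid	C6H13N3O3
Orn	amino_acid	C5H12N2O2
DOPA	amino_acid	C9H11NO4
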