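# SYNTHETIC FIXTURE: plausible default building blocks for the combinatorial
# schemes; reagent identities are user-configurable, only the table sizes
# (32 rows) and formula arithmetic are load-bearing.
name	block_class	formula
Gly	amine	C2H5NO2
Ala	amine	C3H7NO2
Ser	amine	C3H7NO3
Pro	amine	C5H9NO2
Val	amine	C5H11NO2
Thr	amine	C4H9NO3
Cys	amine	C3H7NO2S
Leu	amine	C6H13NO2
Ile	amine	C6H13NO2
Asn	amine	C4H8N2O3
Asp	amine	C4H7NO4
Gln	amine	C5H10N2O3
Glu	amine	C5H9NO4
Lys	amine	C6H14N2O2
Met	amine	C5H11NO2S
His	amine	C6H9N3O2
Phe	amine	C9H11NO2
Arg	amine	C6H14N4O2
Tyr	amine	C9H11NO3
Trp	amine	C11H12N2O2
ethanolamine	amine	C2H7NO
dopamine	amine	C8H11NO2
tyramine	amine	C8H11NO
phenethylamine	amine	C8H11N
tryptamine	amine	C10H12N2
serotonin	amine	C10H12N2O
histamine	amine	C5H9N3
putrescine	amine	C4H12N2
cadaverine	amine	C5H14N2
agmatine	amine	C5H14N4
GABA	amine	C4H9NO2
taurine	amine	C2H7NO3S
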