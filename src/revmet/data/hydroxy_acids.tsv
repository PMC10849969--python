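# SYNTHETIC FIXTURE: plausible default building blocks for the combinatorial
# schemes; reagent identities are user-configurable, only the table sizes
# (17 rows) and formula arithmetic are load-bearing.
name	block_class	formula
glycolic acid	hydroxy_acid	C2H4O3
lactic acid	hydroxy_acid	C3H6O3
3-hydroxybutyric acid	hydroxy_acid	C4H8O3
malic acid	hydroxy_acid	C4H6O5
2-hydroxyvaleric acid	hydroxy_acid	C5H10O3
3-hydroxyhexanoic acid	hydroxy_acid	C6H12O3
hydroxyoctanoic acid	hydroxy_acid	C8H16O3
hydroxydecanoic acid	hydroxy_acid	C10H20O3
hydroxylauric acid	hydroxy_acid	C12H24O3
hydroxymyristic acid	hydroxy_acid	C14H28O3
hydroxypalmitic acid	hydroxy_acid	C16H32O3
hydroxypalmitoleic acid	hydroxy_acid	C16H30O3
hydroxystearic acid	hydroxy_acid	C18H36O3
hydroxyoleic acid	hydroxy_acid	C18H34O3
hydroxyarachidic acid	hydroxy_acid	C20H40O3
hydroxybehenic acid	hydroxy_acid	C22H44O3
hydroxylignoceric acid	hydroxy_acid	C24H48O3
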