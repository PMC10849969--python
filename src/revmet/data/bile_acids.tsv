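# SYNTHETIC FIXTURE: plausible default building blocks for the combinatorial
# schemes; reagent identities are user-configurable, only the table sizes
# (8 rows) and formula arithmetic are load-bearing.
name	block_class	formula
CA	bile_acid	C24H40O5
aMCA	bile_acid	C24H40O5
bMCA	bile_acid	C24H40O5
wMCA	bile_acid	C24H40O5
CDCA	bile_acid	C24H40O4
DCA	bile_acid	C24H40O4
UDCA	bile_acid	C24H40O4
HDCA	bile_acid	C24H40O4
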