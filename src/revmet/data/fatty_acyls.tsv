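# SYNTHETIC FIXTURE: plausible default building blocks for the combinatorial
# schemes; reagent identities are user-configurable, only the table sizes
# (46 rows) and formula arithmetic are load-bearing.
name	block_class	formula
FA 2:0	fatty_acyl	C2H4O2
FA 3:0	fatty_acyl	C3H6O2
FA 4:0	fatty_acyl	C4H8O2
FA 5:0	fatty_acyl	C5H10O2
FA 6:0	fatty_acyl	C6H12O2
FA 7:0	fatty_acyl	C7H14O2
FA 8:0	fatty_acyl	C8H16O2
FA 9:0	fatty_acyl	C9H18O2
FA 10:0	fatty_acyl	C10H20O2
FA 11:0	fatty_acyl	C11H22O2
FA 12:0	fatty_acyl	C12H24O2
FA 13:0	fatty_acyl	C13H26O2
FA 14:0	fatty_acyl	C14H28O2
FA 15:0	fatty_acyl	C15H30O2
FA 16:0	fatty_acyl	C16H32O2
FA 17:0	fatty_acyl	C17H34O2
FA 18:0	fatty_acyl	C18H36O2
FA 19:0	fatty_acyl	C19H38O2
FA 20:0	fatty_acyl	C20H40O2
FA 21:0	fatty_acyl	C21H42O2
FA 22:0	fatty_acyl	C22H44O2
FA 23:0	fatty_acyl	C23H46O2
FA 24:0	fatty_acyl	C24H48O2
FA 25:0	fatty_acyl	C25H50O2
FA 26:0	fatty_acyl	C26H52O2
FA 28:0	fatty_acyl	C28H56O2
FA 30:0	fatty_acyl	C30H60O2
FA 10:1	fatty_acyl	C10H18O2
FA 12:1	fatty_acyl	C12H22O2
FA 14:1	fatty_acyl	C14H26O2
FA 15:1	fatty_acyl	C15H28O2
FA 16:1	fatty_acyl	C16H30O2
FA 17:1	fatty_acyl	C17H32O2
FA 18:1	fatty_acyl	C18H34O2
FA 20:1	fatty_acyl	C20H38O2
FA 22:1	fatty_acyl	C22H42O2
FA 24:1	fatty_acyl	C24H46O2
FA 18:2	fatty_acyl	C18H32O2
FA 18:3	fatty_acyl	C18H30O2
FA 20:2	fatty_acyl	C20H36O2
FA 20:3	fatty_acyl	C20H34O2
FA 20:4	fatty_acyl	C20H32O2
FA 20:5	fatty_acyl	C20H30O2
FA 22:4	fatty_acyl	C22H36O2
FA 22:5	fatty_acyl	C22H34O2
FA 22:6	fatty_acyl	C22H32O2
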