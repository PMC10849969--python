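"""Bundled element data: monoisotopic masses and isotope abundances.

Values are the IUPAC 2021 standard atomic masses / isotopic compositions
(CIAAW), truncated to the precision useful for small-molecule MS. Each
element maps to a list of ``(mass_Da, abundance)`` tuples sorted by mass;
the first entry is always the lightest isotope and the *most abundant*
isotope defines the monoisotopic mass used throughout.
"""

from __future__ import annotations

# (isotope mass in Da, relative abundance); abundances sum to 1 per element.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.0030740048, 0.99636), (15.0001088989, 0.00364)],
    "O": [(15.99491461956, 0.99757), (16.99913170, 0.00038), (17.99916040, 0.00205)],
    "P": [(30.97376163, 1.0)],
    "S": [(31.97207100, 0.9499), (32.97145876, 0.0075), (33.96786690, 0.0425), (35.96708076, 0.0001)],
    "Na": [(22.9897692809, 1.0)],
    "Cl": [(34.96885268, 0.7576), (36.96590259, 0.2424)],
}

#: Monoisotopic (most abundant isotope) mass per element, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    el: max(isos, key=lambda iso: iso[1])[0] for el, isos in ISOTOPES.items()
}

#: Mass of the proton, Da (CODATA). Used for [M+H]+/[M-H]- shifts so that
#: the electron gained or lost by the ion is accounted for exactly.
PROTON_MASS = 1.00727646

#: Electron rest mass, Da (CODATA).
ELECTRON_MASS = 0.00054858
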