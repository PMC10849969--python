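"""Molecular-formula arithmetic and combinatorial condensation libraries.

This module provides the mass calculus underneath a virtual combinatorial
library: Hill-notation formula parsing, monoisotopic masses, adduct m/z,
ppm errors, aggregated isotope envelopes, and enumeration of condensation
products (acyl amides, acyl esters, bile amidates) from building-block
tables. A condensation product is defined purely arithmetically::

    formula(product) = formula(left) + formula(right) - formula(loss)

with the loss defaulting to one water per bond formed. Regiochemistry and
stereochemistry are deliberately ignored: one (rule, left, right) triple is
one record, because MS/MS cannot distinguish regioisomers of these classes
in practice.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._elements import ELECTRON_MASS, ISOTOPES, MONOISOTOPIC_MASS, PROTON_MASS

__all__ = [
    "MolecularFormula",
    "BuildingBlock",
    "CondensationRule",
    "Adduct",
    "CompoundRecord",
    "IsotopeEnvelope",
    "FormulaParseError",
    "parse_formula",
    "monoisotopic_mass",
    "condense",
    "adduct_mz",
    "ppm_error",
    "isotope_envelope",
    "enumerate_library",
    "load_building_blocks",
    "library_to_frame",
    "write_library",
    "CONDENSATION_RULES",
    "ADDUCTS",
    "WATER",
]

#: Spacing between successive isotopologue peaks (13C - 12C), Da. Carbon
#: dominates the A+1/A+2 pattern of the compound classes handled here, so
#: aggregated envelopes place the A+k peak at mono + k * this spacing.
ISOTOPE_SPACING = ISOTOPES["C"][1][0] - ISOTOPES["C"][0][0]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaParseError(ValueError):
    """Raised when a formula string cannot be interpreted."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element composition as a mapping element symbol -> count.

    Immutable; supports ``+`` and ``-`` (subtraction raises if any count
    would go negative). Equality is count-wise; zero counts are dropped on
    construction so ``CH0O`` == ``CO``.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        cleaned = {}
        for el, n in self.element_counts.items():
            if el not in ISOTOPES:
                raise FormulaParseError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
            if n:
                cleaned[el] = int(n)
        object.__setattr__(self, "element_counts", cleaned)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula(counts)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"cannot subtract {other}: element {el} count would be {new}"
                )
            counts[el] = new
        return MolecularFormula(counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.element_counts) == dict(other.element_counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.element_counts.items())))

    @property
    def n_atoms(self) -> int:
        return sum(self.element_counts.values())

    def hill(self) -> str:
        """Canonical Hill-order serialization (C, H, then alphabetical)."""
        counts = self.element_counts
        if not counts:
            return ""
        order: list[str] = []
        if "C" in counts:
            order.append("C")
            if "H" in counts:
                order.append("H")
            order += sorted(el for el in counts if el not in ("C", "H"))
        else:
            order = sorted(counts)
        return "".join(f"{el}{counts[el] if counts[el] != 1 else ''}" for el in order)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string like ``"C24H40O5"``.

    An omitted count means 1. Round-trips through :meth:`MolecularFormula.hill`.
    """
    if not text or not text.strip():
        raise FormulaParseError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaParseError(
                f"unparseable formula {text!r} at position {pos}"
            )
        el, digits = match.groups()
        if el not in ISOTOPES:
            raise FormulaParseError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaParseError(f"unparseable formula {text!r} at position {pos}")
    return MolecularFormula(counts)


WATER = parse_formula("H2O")


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass in Da: sum of count x most-abundant-isotope mass."""
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in f.element_counts.items())


@dataclass(frozen=True)
class BuildingBlock:
    """One reagent in a combinatorial scheme, identified by name and formula."""

    name: str
    block_class: str
    formula: MolecularFormula

    _CLASSES = frozenset({"fatty_acyl", "amine", "hydroxy_acid", "bile_acid", "amino_acid"})

    def __post_init__(self) -> None:
        if self.block_class not in self._CLASSES:
            raise ValueError(f"unknown block class {self.block_class!r}")

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class CondensationRule:
    """A condensation reaction: left-class + right-class - loss."""

    name: str
    left_class: str
    right_class: str
    loss: MolecularFormula = field(default_factory=lambda: WATER)


#: The three condensation schemes of the combinatorial libraries.
CONDENSATION_RULES: dict[str, CondensationRule] = {
    "amide": CondensationRule("amide", "fatty_acyl", "amine"),
    "ester": CondensationRule("ester", "fatty_acyl", "hydroxy_acid"),
    "bile_amidate": CondensationRule("bile_amidate", "bile_acid", "amino_acid"),
}


@dataclass(frozen=True)
class Adduct:
    """Single-M ionization adduct: m/z = (M + mass_shift) / |charge|."""

    name: str
    mass_shift: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


#: Common electrospray adducts. Shifts use the proton mass so that the
#: electron gained/lost by the ion is accounted for.
ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", PROTON_MASS, +1),
    "[M-H]-": Adduct("[M-H]-", -PROTON_MASS, -1),
    "[M+Na]+": Adduct("[M+Na]+", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
    "[M+Cl]-": Adduct("[M+Cl]-", MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS, -1),
}


def get_adduct(name: str) -> Adduct:
    """Look up a bundled adduct; the Unicode minus sign is accepted."""
    key = name.replace("−", "-").strip()
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(f"unknown adduct {name!r}; known: {sorted(ADDUCTS)}") from None


def adduct_mz(mass: float, adduct: Adduct) -> float:
    """m/z of a single-M adduct ion for a neutral monoisotopic mass."""
    if mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {mass}")
    return (mass + adduct.mass_shift) / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def within_ppm(observed: float, theoretical: float, window: float) -> bool:
    """Inclusive ppm window test: |ppm error| <= window."""
    return abs(ppm_error(observed, theoretical)) <= window


@dataclass(frozen=True)
class CompoundRecord:
    """A virtual library product with its provenance and mass calculus."""

    compound_id: str
    rule: str
    left_block: str
    right_block: str
    formula: MolecularFormula
    monoisotopic_mass: float
    adduct_mzs: Mapping[str, float] = field(default_factory=dict)
    mass_degenerate_group: str | None = None


IsotopeEnvelope = list  # list of (mz, relative_abundance), base peak == 1


def isotope_envelope(f: MolecularFormula, n_peaks: int = 3) -> list[tuple[float, float]]:
    """Aggregated isotope envelope of a formula, by nominal-mass shift.

    Convolves per-element isotope distributions binned by integer neutron
    shift (A, A+1, A+2, ...), truncates to ``n_peaks`` starting at A, and
    normalizes so the base peak has abundance 1. Fine structure within a
    nominal-mass bin is summed, matching the unit-resolution treatment used
    by Skyline-style isotope-dot-product scoring.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    dist = np.ones(1)
    for el, n in f.element_counts.items():
        isos = ISOTOPES.get(el)
        if isos is None:
            raise ValueError(f"no isotope data for element {el}")
        base = isos[0][0]
        shifts = [int(round(m - base)) for m, _ in isos]
        per_atom = np.zeros(max(shifts) + 1)
        for shift, (_, abund) in zip(shifts, isos):
            per_atom[shift] += abund
        # per-element distribution = per-atom distribution convolved n times
        power = per_atom
        k = n
        acc = np.ones(1)
        while k:
            if k & 1:
                acc = np.convolve(acc, power)
            power = np.convolve(power, power)
            k >>= 1
        dist = np.convolve(dist, acc)
    dist = dist[:n_peaks]
    dist = dist / dist.max()
    mono = monoisotopic_mass(f)
    return [(mono + i * ISOTOPE_SPACING, a) for i, a in enumerate(dist) if a > 0]


def condense(
    left: BuildingBlock,
    right: BuildingBlock,
    rule: CondensationRule,
    adducts: Sequence[Adduct] = (),
) -> CompoundRecord:
    """Form the condensation product of two building blocks under a rule."""
    if left.block_class != rule.left_class or right.block_class != rule.right_class:
        raise ValueError(
            f"rule {rule.name!r} expects ({rule.left_class}, {rule.right_class}), "
            f"got ({left.block_class}, {right.block_class}) "
            f"for blocks ({left.name}, {right.name})"
        )
    product = (left.formula + right.formula) - rule.loss
    mass = monoisotopic_mass(product)
    return CompoundRecord(
        compound_id=f"{rule.name}:{left.name}+{right.name}",
        rule=rule.name,
        left_block=left.name,
        right_block=right.name,
        formula=product,
        monoisotopic_mass=mass,
        adduct_mzs={a.name: adduct_mz(mass, a) for a in adducts},
    )


def enumerate_library(
    left_blocks: Sequence[BuildingBlock],
    right_blocks: Sequence[BuildingBlock],
    rule: CondensationRule,
    adducts: Sequence[Adduct] = (),
) -> list[CompoundRecord]:
    """Enumerate all ordered (left, right) condensation products.

    Every pair yields exactly one record, so the library size is
    ``|left| x |right|``. Records whose product formulas coincide (e.g. Ile
    vs Leu conjugates) are kept distinct but share a ``mass_degenerate_group``
    label naming the common formula.
    """
    if not left_blocks or not right_blocks:
        raise ValueError("building-block tables must be non-empty")
    records = []
    errors = []
    for left, right in itertools.product(left_blocks, right_blocks):
        try:
            records.append(condense(left, right, rule, adducts))
        except ValueError as exc:
            errors.append(f"({left.name}, {right.name}): {exc}")
    if errors:
        raise ValueError("condensation failed for pairs:\n" + "\n".join(errors))
    by_formula: dict[MolecularFormula, list[int]] = {}
    for i, rec in enumerate(records):
        by_formula.setdefault(rec.formula, []).append(i)
    out: list[CompoundRecord] = list(records)
    for formula, idxs in by_formula.items():
        if len(idxs) > 1:
            label = f"{rule.name}:{formula.hill()}"
            for i in idxs:
                r = out[i]
                out[i] = CompoundRecord(
                    r.compound_id, r.rule, r.left_block, r.right_block,
                    r.formula, r.monoisotopic_mass, r.adduct_mzs, label,
                )
    return out


def load_building_blocks(path: str | Path) -> list[BuildingBlock]:
    """Read a building-block table (TSV/CSV: name, block_class, formula)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"name", "block_class", "formula"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"building-block table {path} lacks columns {sorted(missing)}")
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate building-block names in {path}: {dupes}")
    return [
        BuildingBlock(row["name"], row["block_class"], parse_formula(row["formula"]))
        for _, row in df.iterrows()
    ]


def library_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Tabulate compound records; one column per adduct m/z."""
    rows = []
    for r in records:
        row = {
            "compound_id": r.compound_id,
            "rule": r.rule,
            "left_block": r.left_block,
            "right_block": r.right_block,
            "formula": r.formula.hill(),
            "monoisotopic_mass": r.monoisotopic_mass,
            "mass_degenerate_group": r.mass_degenerate_group or "",
        }
        row.update({f"mz {name}": mz for name, mz in r.adduct_mzs.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_library(records: Iterable[CompoundRecord], path: str | Path) -> None:
    library_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6f")


#: Bundled fixture block tables (synthetic defaults; identities configurable).
BUNDLED_TABLES = ("fatty_acyls", "amines", "hydroxy_acids", "bile_acids", "amino_acids")


def bundled_blocks(table: str) -> list[BuildingBlock]:
    """Load one of the bundled building-block fixture tables by name."""
    if table not in BUNDLED_TABLES:
        raise KeyError(f"unknown bundled table {table!r}; known: {BUNDLED_TABLES}")
    path = Path(__file__).parent / "data" / f"{table}.tsv"
    return load_building_blocks(path)


def bundled_block_index() -> dict[str, BuildingBlock]:
    """Name -> block lookup across all bundled tables."""
    index: dict[str, BuildingBlock] = {}
    for table in BUNDLED_TABLES:
        for block in bundled_blocks(table):
            index[block.name] = block
    return index


def load_library(path: str | Path) -> list[CompoundRecord]:
    """Read back a library TSV written by :func:`write_library`."""
    df = pd.read_csv(path, sep="\t")
    mz_cols = [c for c in df.columns if c.startswith("mz ")]
    records = []
    for _, row in df.iterrows():
        group = row.get("mass_degenerate_group", "")
        records.append(CompoundRecord(
            compound_id=row["compound_id"],
            rule=row["rule"],
            left_block=row["left_block"],
            right_block=row["right_block"],
            formula=parse_formula(row["formula"]),
            monoisotopic_mass=float(row["monoisotopic_mass"]),
            adduct_mzs={c[3:]: float(row[c]) for c in mz_cols if pd.notna(row[c])},
            mass_degenerate_group=group if isinstance(group, str) and group else None,
        ))
    return records
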