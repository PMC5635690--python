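"""Elemental-formula arithmetic, monoisotopic masses and the precursor registry.

Two m/z conventions coexist in this package and are deliberately kept apart:

* molecular ions are reported as ``[M+H]+`` = neutral monoisotopic mass plus
  the proton mass (1.00727646 Da, electron accounted for);
* fragment ions (see :mod:`sideroforge.fragmenter`) are reported as the plain
  sum of the atomic monoisotopic masses of the charged fragment's formula,
  with no electron correction.

The second convention reproduces the reference fragment values (e.g. the
2,3-dihydroxybenzoyl acylium at 137.0239) which the first does not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping, Optional

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER",
    "WATER_MASS",
    "HYDROXYL",
    "Formula",
    "FormulaError",
    "UnknownElementError",
    "InfeasibleCondensationError",
    "BuildingBlock",
    "PrecursorAmine",
    "DHB",
    "SERINE",
    "THREONINE",
    "monoisotopic_mass",
    "protonated_mz",
    "condense",
    "load_registry",
    "default_registry",
    "round_display",
]

#: Monoisotopic element masses in Da (CODATA/IUPAC).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Mass of the proton in Da (includes the electron correction).
PROTON_MASS: float = 1.00727646

_HILL_TAIL = ("N", "O", "S")  # after C and H; extend alphabetically if needed

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or infeasible elemental-formula operation."""


class UnknownElementError(FormulaError):
    """Element symbol without a monoisotopic mass entry."""


class InfeasibleCondensationError(FormulaError):
    """A subtraction that would drive an element count negative."""


class Formula:
    """Immutable multiset of element counts with monoisotopic-mass semantics.

    Counts are non-negative integers; zero counts are dropped so equality is
    element-wise. Subtraction raises :class:`InfeasibleCondensationError`
    rather than producing a negative count.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for element, count in counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise UnknownElementError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int):
                raise FormulaError(f"count for {element} must be an integer, got {count!r}")
            if count < 0:
                raise FormulaError(f"negative count for {element}: {count}")
            if count:
                clean[element] = count
        self._counts = clean
        self._hash = hash(frozenset(clean.items()))

    # -- construction ----------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-notation formula string such as ``"C7H6O4"``."""
        if not isinstance(text, str) or not text.strip():
            raise FormulaError(f"empty or non-string formula: {text!r}")
        text = text.strip()
        pos = 0
        counts: dict[str, int] = {}
        while pos < len(text):
            match = _TOKEN.match(text, pos)
            if match is None or match.start() != pos or not match.group(1):
                raise FormulaError(
                    f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
                )
            element, digits = match.groups()
            if element not in MONOISOTOPIC_MASS:
                raise UnknownElementError(
                    f"malformed formula {text!r}: unknown element {element!r}"
                )
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        return cls(counts)

    # -- mapping-ish access ----------------------------------------------

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self._counts.items()))

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return self._hash

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        counts = dict(self._counts)
        for element, count in other._counts.items():
            counts[element] = counts.get(element, 0) + count
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        counts = dict(self._counts)
        for element, count in other._counts.items():
            remaining = counts.get(element, 0) - count
            if remaining < 0:
                raise InfeasibleCondensationError(
                    f"cannot remove {other} from {self}: {element} count would be negative"
                )
            counts[element] = remaining
        return Formula(counts)

    def __mul__(self, n: int) -> "Formula":
        if not isinstance(n, int):
            return NotImplemented
        if n < 0:
            raise FormulaError(f"cannot scale a formula by {n}")
        return Formula({e: c * n for e, c in self._counts.items()})

    __rmul__ = __mul__

    def contains(self, other: "Formula") -> bool:
        return all(self[e] >= c for e, c in other._counts.items())

    # -- presentation ----------------------------------------------------

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        parts = []
        for element in ("C", "H") + _HILL_TAIL:
            count = self[element]
            if count == 1:
                parts.append(element)
            elif count > 1:
                parts.append(f"{element}{count}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


WATER = Formula({"H": 2, "O": 1})
WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]
HYDROXYL = Formula({"O": 1, "H": 1})
AMMONIA = Formula({"N": 1, "H": 3})
CARBON_MONOXIDE = Formula({"C": 1, "O": 1})


def monoisotopic_mass(formula: Formula) -> float:
    """Sum of element monoisotopic masses, in Da."""
    return sum(MONOISOTOPIC_MASS[e] * c for e, c in formula.items())


def protonated_mz(neutral_mass: float) -> float:
    """m/z of the singly protonated molecular ion ``[M+H]+``."""
    if neutral_mass < 0:
        raise ValueError(f"neutral mass must be non-negative, got {neutral_mass}")
    return neutral_mass + PROTON_MASS


def condense(a: Formula, b: Formula, n_waters: int = 1) -> Formula:
    """Join two formulas, losing ``n_waters`` molecules of water.

    Raises :class:`InfeasibleCondensationError` when the combined formula
    cannot supply the water.
    """
    if n_waters < 0:
        raise FormulaError(f"n_waters must be >= 0, got {n_waters}")
    return (a + b) - WATER * n_waters


def round_display(value: float, ndigits: int = 4) -> float:
    """Round-half-even display rounding (4 decimals matches the references)."""
    return round(value, ndigits)


@dataclass(frozen=True)
class BuildingBlock:
    """A fixed pathway building block (aryl acid or amino acid)."""

    name: str
    formula: Formula
    role: str


DHB = BuildingBlock("2,3-dihydroxybenzoic acid", Formula.parse("C7H6O4"), "aryl-acid")
SERINE = BuildingBlock("L-serine", Formula.parse("C3H7NO3"), "amino-acid")
THREONINE = BuildingBlock("L-threonine", Formula.parse("C4H9NO3"), "amino-acid")

#: Acyl group of DHB after loss of the carboxyl OH (the acylium composition).
DHB_ACYL = DHB.formula - HYDROXYL


@dataclass(frozen=True)
class PrecursorAmine:
    """One feedable amine precursor from the shipped registry.

    ``backbone`` describes simple linear polyamines as the carbon counts of
    the methylene segments between amine nitrogens (e.g. spermidine is
    ``(3, 4)``); it drives backbone C-N fragment prediction and is ``None``
    for precursors without that linear topology.
    """

    ref_no: int
    name: str
    formula: Formula
    n_primary_amines: int
    n_secondary_amines: int
    backbone: Optional[tuple[int, ...]] = None
    working_concentration: str = ""
    mass_validated: bool = False

    def __post_init__(self) -> None:
        if self.n_primary_amines < 0 or self.n_secondary_amines < 0:
            raise ValueError("amine counts must be non-negative")
        if not 1 <= self.ref_no <= 25:
            raise ValueError(f"precursor reference number out of range: {self.ref_no}")

    def n_sites(self, allow_secondary: bool = True) -> int:
        """Number of acylation-competent amine sites."""
        return self.n_primary_amines + (self.n_secondary_amines if allow_secondary else 0)


_REGISTRY_COLUMNS = [
    "id",
    "name",
    "formula",
    "n_primary_amines",
    "n_secondary_amines",
    "backbone",
    "concentration",
    "mass_validated",
]


def load_registry(path=None) -> list[PrecursorAmine]:
    """Load a precursor registry from tab-separated text.

    With no argument the packaged registry (25 precursors mirroring the
    published feeding panel) is returned.
    """
    if path is None:
        source = resources.files("sideroforge.data") / "precursor_registry.tsv"
        text = source.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as handle:
            text = handle.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    if header != _REGISTRY_COLUMNS:
        raise ValueError(
            f"registry header mismatch: expected {_REGISTRY_COLUMNS}, got {header}"
        )
    registry = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(_REGISTRY_COLUMNS):
            raise ValueError(f"registry line {lineno}: expected {len(_REGISTRY_COLUMNS)} fields")
        row = dict(zip(_REGISTRY_COLUMNS, fields))
        try:
            backbone = (
                tuple(int(c) for c in row["backbone"].split(",")) if row["backbone"] else None
            )
            registry.append(
                PrecursorAmine(
                    ref_no=int(row["id"]),
                    name=row["name"],
                    formula=Formula.parse(row["formula"]),
                    n_primary_amines=int(row["n_primary_amines"]),
                    n_secondary_amines=int(row["n_secondary_amines"]),
                    backbone=backbone,
                    working_concentration=row["concentration"],
                    mass_validated=row["mass_validated"].lower() in ("yes", "true", "1"),
                )
            )
        except FormulaError as exc:
            raise ValueError(f"registry line {lineno}: {exc}") from exc
    return registry


def default_registry() -> list[PrecursorAmine]:
    """The packaged 25-precursor registry."""
    return load_registry()
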