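"""Enumeration of candidate products from the engineered pathway rules.

Three product families are produced:

* intermediates ``M{n}``: one amine precursor amide-condensed with DHB;
* capped full analogs ``M{n}{S|T}{c|o}``: an intermediate further acylated on
  a second amine site by a DHB-amino-acid cap, either cyclized to the
  methyl/oxazoline (``c``) or left open (``o``);
* the catecholate oligomer series (``Ent``-type): chains of DHB-Ser or
  DHB-Thr units joined by ester bonds, optionally macrocyclized at n = 3.

Each product carries a provenance of condensation steps and a list of
cleavable bonds with precomputed side formulas; the fragmenter works purely
from that bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .chemcore import (
    DHB,
    HYDROXYL,
    SERINE,
    THREONINE,
    WATER,
    BuildingBlock,
    Formula,
    PrecursorAmine,
    condense,
    monoisotopic_mass,
    protonated_mz,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AcylCap",
    "CAPS",
    "CAP_ORDER",
    "CondensationStep",
    "CleavableBond",
    "AssembledProduct",
    "EnumerationConfig",
    "NotASubstrateError",
    "make_intermediate",
    "make_full_analog",
    "ent_oligomer",
    "enumerate_ent_series",
    "enumerate_products",
]


class NotASubstrateError(ValueError):
    """Precursor lacks the amine site(s) required for the reaction."""


@dataclass(frozen=True)
class AcylCap:
    """A DHB-amino-acid acyl cap added to the second amine site.

    The composition added to the intermediate is DHB + amino acid minus three
    waters when cyclized (oxazoline ring) or two when open.
    """

    code: str
    amino_acid: BuildingBlock
    cyclized: bool

    @property
    def composition(self) -> Formula:
        n_waters = 3 if self.cyclized else 2
        return condense(DHB.formula, self.amino_acid.formula, n_waters)

    @property
    def acid(self) -> Formula:
        """The free cap acid before amide condensation (composition + H2O)."""
        return self.composition + WATER


CAPS: dict[str, AcylCap] = {
    "Sc": AcylCap("Sc", SERINE, cyclized=True),
    "So": AcylCap("So", SERINE, cyclized=False),
    "Tc": AcylCap("Tc", THREONINE, cyclized=True),
    "To": AcylCap("To", THREONINE, cyclized=False),
}

#: Deterministic cap application order.
CAP_ORDER: tuple[str, ...] = ("Sc", "So", "Tc", "To")


@dataclass(frozen=True)
class CondensationStep:
    """One condensation in a product's assembly history."""

    block: str
    bond: str  # "amide" | "ester"
    waters_lost: int


@dataclass(frozen=True)
class CleavableBond:
    """A provenance bond with the neutral side formulas it splits into.

    ``acid_side`` is the neutral acid fragment (carboxyl OH restored) and
    ``amine_side`` the neutral amine/alcohol fragment (N-H or O-H restored),
    so that ``acid_side + amine_side == parent + H2O``.
    """

    bond_type: str  # "amide" | "ester"
    acid_side: Formula
    amine_side: Formula
    label: str = ""


@dataclass(frozen=True)
class AssembledProduct:
    """An enumerated candidate molecule with full assembly provenance."""

    id: str
    formula: Formula
    kind: str  # "intermediate" | "analog" | "oligomer"
    provenance: tuple[CondensationStep, ...]
    bonds: tuple[CleavableBond, ...]
    precursor: Optional[PrecursorAmine] = None
    cap: Optional[AcylCap] = None
    residue: Optional[str] = None  # oligomer residue, "Ser" | "Thr"
    n_units: int = 0
    cyclic: bool = False
    multiplicity: int = 1

    @property
    def precursor_id(self) -> Optional[int]:
        return self.precursor.ref_no if self.precursor is not None else None

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def mz(self) -> float:
        """Calculated [M+H]+ m/z."""
        return protonated_mz(self.neutral_mass)

    @property
    def waters_lost(self) -> int:
        return sum(step.waters_lost for step in self.provenance)


@dataclass(frozen=True)
class EnumerationConfig:
    """Knobs for the candidate enumeration."""

    caps: tuple[str, ...] = CAP_ORDER
    allow_secondary: bool = True
    ent_max_n: int = 3
    allow_macrocyclization: bool = True
    ent_residues: tuple[str, ...] = ("Ser", "Thr")

    def __post_init__(self) -> None:
        unknown = set(self.caps) - set(CAPS)
        if unknown:
            raise ValueError(f"unknown cap codes: {sorted(unknown)}")
        if self.ent_max_n < 1:
            raise ValueError("ent_max_n must be >= 1")


def make_intermediate(
    precursor: PrecursorAmine, allow_secondary: bool = True
) -> AssembledProduct:
    """Condense one precursor amine with DHB (one amide bond, one water)."""
    sites = precursor.n_sites(allow_secondary)
    if sites < 1:
        raise NotASubstrateError(
            f"precursor {precursor.ref_no} ({precursor.name}) has no acylatable amine"
        )
    formula = condense(DHB.formula, precursor.formula, 1)
    return AssembledProduct(
        id=f"M{precursor.ref_no}",
        formula=formula,
        kind="intermediate",
        provenance=(
            CondensationStep(DHB.name, "root", 0),
            CondensationStep(precursor.name, "amide", 1),
        ),
        bonds=(CleavableBond("amide", DHB.formula, precursor.formula, "DHB amide"),),
        precursor=precursor,
        multiplicity=sites,
    )


def make_full_analog(intermediate: AssembledProduct, cap: AcylCap) -> AssembledProduct:
    """Acylate an intermediate's remaining amine site with a cap."""
    if intermediate.precursor is None or intermediate.kind != "intermediate":
        raise ValueError("full analogs are built from precursor intermediates")
    sites = intermediate.multiplicity
    if sites < 2:
        raise NotASubstrateError(
            f"{intermediate.id}: a second amine site is required for the {cap.code} cap"
        )
    precursor = intermediate.precursor
    formula = intermediate.formula + cap.composition
    bonds = (
        CleavableBond(
            "amide", DHB.formula, precursor.formula + cap.composition, "DHB amide"
        ),
        CleavableBond("amide", cap.acid, intermediate.formula, f"{cap.code} cap amide"),
    )
    return AssembledProduct(
        id=f"{intermediate.id}{cap.code}",
        formula=formula,
        kind="analog",
        provenance=intermediate.provenance
        + (CondensationStep(f"DHB-{cap.amino_acid.name} ({cap.code})", "amide", 1),),
        bonds=bonds,
        precursor=precursor,
        cap=cap,
        multiplicity=sites * (sites - 1),
    )


_RESIDUES = {"Ser": SERINE, "Thr": THREONINE}


def _oligomer_id(residue: str, n: int, cyclic: bool) -> str:
    prefix = "Ent" if residue == "Ser" else "Thr-Ent"
    if cyclic:
        return prefix
    suffix = {1: "monomer", 2: "dimer", 3: "trimer"}.get(n, f"{n}-mer")
    return f"{prefix} {suffix}"


def ent_unit(residue: str) -> Formula:
    """One DHB-amino-acid unit (amide condensation, one water lost)."""
    return condense(DHB.formula, _RESIDUES[residue].formula, 1)


def ent_oligomer(residue: str, n: int, cyclic: bool = False) -> AssembledProduct:
    """A homo-oligomer of DHB-Ser or DHB-Thr units joined by ester bonds.

    Linear chains of ``n`` units lose ``n - 1`` further waters; the
    macrocyclic trilactone loses one more. Only the trilactone (n = 3) is
    modeled as cyclic.
    """
    if residue not in _RESIDUES:
        raise ValueError(f"residue must be one of {sorted(_RESIDUES)}, got {residue!r}")
    if n < 1:
        raise ValueError("oligomer length must be >= 1")
    if cyclic and n != 3:
        raise ValueError("only the n=3 trilactone macrocycle is modeled")
    unit = ent_unit(residue)
    waters = (n - 1) + (1 if cyclic else 0)
    formula = unit * n - WATER * waters
    steps = [CondensationStep(DHB.name, "root", 0)]
    steps += [CondensationStep(_RESIDUES[residue].name, "amide", 1)] * n
    steps += [CondensationStep("unit ester", "ester", 1)] * (n - 1)
    if cyclic:
        steps.append(CondensationStep("macrolactone ester", "ester", 1))
    bonds: list[CleavableBond] = [
        CleavableBond("amide", DHB.formula, formula - DHB.formula + WATER, "DHB amide")
    ]
    if not cyclic:
        for k in range(1, n):
            acid_side = unit * k - WATER * (k - 1)
            alcohol_side = unit * (n - k) - WATER * (n - k - 1)
            bonds.append(
                CleavableBond("ester", acid_side, alcohol_side, f"ester after unit {k}")
            )
    return AssembledProduct(
        id=_oligomer_id(residue, n, cyclic),
        formula=formula,
        kind="oligomer",
        provenance=tuple(steps),
        bonds=tuple(bonds),
        residue=residue,
        n_units=n,
        cyclic=cyclic,
    )


def enumerate_ent_series(
    residues: Sequence[str] = ("Ser", "Thr"),
    max_n: int = 3,
    topologies: Sequence[str] = ("linear", "cyclic"),
) -> list[AssembledProduct]:
    """All homo-oligomer species up to ``max_n`` units per residue."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    products = []
    for residue in residues:
        for n in range(1, max_n + 1):
            if "linear" in topologies:
                products.append(ent_oligomer(residue, n, cyclic=False))
        if "cyclic" in topologies and max_n >= 3:
            products.append(ent_oligomer(residue, 3, cyclic=True))
    return products


def enumerate_products(
    registry: Iterable[PrecursorAmine],
    cfg: EnumerationConfig = EnumerationConfig(),
) -> list[AssembledProduct]:
    """Deterministic candidate enumeration over a precursor registry.

    For each precursor (ordered by reference number): one intermediate when
    at least one amine site is available, plus one capped analog per
    configured cap when a second site exists. Regio-isomeric placements are
    collapsed into a single product carrying a multiplicity annotation.
    Precursors with no site are skipped with a warning.
    """
    products: list[AssembledProduct] = []
    for precursor in sorted(registry, key=lambda p: p.ref_no):
        try:
            intermediate = make_intermediate(precursor, cfg.allow_secondary)
        except NotASubstrateError:
            logger.warning(
                "skipping precursor %d (%s): no acylatable amine site",
                precursor.ref_no,
                precursor.name,
            )
            continue
        products.append(intermediate)
        if intermediate.multiplicity >= 2:
            for code in sorted(cfg.caps):
                products.append(make_full_analog(intermediate, CAPS[code]))
    return products
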