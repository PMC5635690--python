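"""Rule-based MS/MS fragment prediction for assembled products.

All fragment m/z values use the plain formula-sum convention: the mass of a
charged fragment is the sum of the atomic monoisotopic masses of its formula,
with no electron subtraction and no extra proton term. The protonated parent
is represented as the neutral formula plus one H atom under the same
convention (and therefore sits ~0.5 mDa above the [M+H]+ value reported for
precursor ions).

Depth is limited to a single bond cleavage plus at most one neutral loss.
Rules:

* intact protonated species, and intact minus each configured neutral loss;
* for every provenance bond, the acid-side acylium (acid minus OH) and the
  protonated amine/alcohol side (plus H), each also minus each neutral loss
  (acylium species may additionally lose CO);
* backbone C-N cleavages of linear polyamine precursors, both acyl
  orientations, with as-drawn hydrogen bookkeeping;
* for macrocyclic oligomers, the sub-chain species that real ester bonds
  would provide in the linear topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .chemcore import (
    AMMONIA,
    CARBON_MONOXIDE,
    DHB_ACYL,
    HYDROXYL,
    WATER,
    Formula,
    InfeasibleCondensationError,
    monoisotopic_mass,
)
from .assembly import AssembledProduct, ent_unit

__all__ = [
    "PredictedFragment",
    "predict_fragments",
    "fragment_coverage",
    "NEUTRAL_LOSSES",
]

NEUTRAL_LOSSES: dict[str, Formula] = {"H2O": WATER, "NH3": AMMONIA}

_H = Formula({"H": 1})
_NH = Formula({"N": 1, "H": 1})
_NH2 = Formula({"N": 1, "H": 2})


@dataclass(frozen=True)
class PredictedFragment:
    """A charged sub-formula with its plain-sum m/z."""

    formula: Formula
    mz: float
    parent_id: str
    description: str


def _segment(carbons: int) -> Formula:
    return Formula({"C": carbons, "H": 2 * carbons})


class _Collector:
    """Deduplicates fragments by formula, preserving first description."""

    def __init__(self, parent: AssembledProduct):
        self.parent = parent
        self.seen: dict[Formula, PredictedFragment] = {}

    def add(self, formula: Formula, description: str) -> None:
        if not formula or formula["C"] == 0:
            return
        if formula in self.seen:
            return
        self.seen[formula] = PredictedFragment(
            formula=formula,
            mz=monoisotopic_mass(formula),
            parent_id=self.parent.id,
            description=description,
        )

    def add_with_losses(
        self,
        formula: Formula,
        description: str,
        losses: dict[str, Formula],
        allow_co: bool = False,
    ) -> None:
        self.add(formula, description)
        for name, loss in losses.items():
            try:
                self.add(formula - loss, f"{description}, loss of {name}")
            except InfeasibleCondensationError:
                pass
        if allow_co:
            try:
                self.add(formula - CARBON_MONOXIDE, f"{description}, loss of CO")
            except InfeasibleCondensationError:
                pass

    def fragments(self) -> list[PredictedFragment]:
        return sorted(self.seen.values(), key=lambda f: (-f.mz, f.formula.hill()))


def _backbone_pieces(product: AssembledProduct, collector: _Collector) -> None:
    """Backbone C-N cleavage fragments for linear polyamine precursors.

    The polyamine is N0-seg1-N1-seg2-...-Nm with the DHB acyl on one terminal
    nitrogen and, for capped analogs, the cap acyl on the other. Every C-N
    bond is cleaved; each side is emitted as an even-electron cation with
    as-drawn hydrogen counts (amide and internal N carry one H, free terminal
    N two).
    """
    precursor = product.precursor
    if precursor is None or precursor.backbone is None:
        return
    segments = [_segment(c) for c in precursor.backbone]
    m = len(segments)
    cap_acyl = product.cap.acid - HYDROXYL if product.cap is not None else None
    orientations = [(DHB_ACYL, cap_acyl)]
    if cap_acyl is not None:
        orientations.append((cap_acyl, DHB_ACYL))

    def nitrogen(index: int, left_acyl, right_acyl) -> Formula:
        acylated = (index == 0 and left_acyl is not None) or (
            index == m and right_acyl is not None
        )
        internal = 0 < index < m
        return _NH if (acylated or internal) else _NH2

    empty = Formula({})
    for left_acyl, right_acyl in orientations:
        # prefix[i] = atoms of acyl + N0..N(i-1) + seg1..seg(i-1)
        for i in range(1, m + 1):
            left = left_acyl if left_acyl is not None else empty
            for j in range(i):
                left = left + nitrogen(j, left_acyl, right_acyl)
                if j < i - 1:
                    left = left + segments[j]
            # bond between N(i-1) and seg i: seg i goes right
            right = empty
            for j in range(i - 1, m):
                right = right + segments[j]
                right = right + nitrogen(j + 1, left_acyl, right_acyl)
            if right_acyl is not None:
                right = right + right_acyl
            collector.add(left, "backbone C-N cleavage (acyl side)")
            collector.add(right, "backbone C-N cleavage (distal side)")
            # bond between seg i and N(i): seg i goes left
            left_with_seg = left + segments[i - 1]
            right_without_seg = right - segments[i - 1]
            collector.add(left_with_seg, "backbone C-N cleavage (acyl side)")
            collector.add(right_without_seg, "backbone C-N cleavage (distal side)")


def _oligomer_subchains(
    product: AssembledProduct, collector: _Collector, losses: dict[str, Formula]
) -> None:
    """Sub-chain ions of a macrocyclic oligomer (ring opening + unit loss)."""
    if product.kind != "oligomer" or not product.cyclic:
        return
    unit = ent_unit(product.residue)
    for k in range(1, product.n_units):
        chain_acid = unit * k - WATER * (k - 1)
        collector.add_with_losses(
            chain_acid - HYDROXYL,
            f"ring-opened {k}-unit acylium",
            losses,
            allow_co=True,
        )
        collector.add_with_losses(
            chain_acid + _H, f"ring-opened protonated {k}-unit chain", losses
        )


def predict_fragments(
    product: AssembledProduct,
    losses: Iterable[str] = ("H2O", "NH3"),
    max_cleavages: int = 1,
) -> list[PredictedFragment]:
    """Predict singly charged fragment ions for one product.

    ``losses`` selects the neutral losses applied to the intact species and
    to every cleavage product; ``max_cleavages`` must be 0 or 1.
    """
    if max_cleavages not in (0, 1):
        raise ValueError(f"unsupported cleavage depth: {max_cleavages}")
    unknown = set(losses) - set(NEUTRAL_LOSSES)
    if unknown:
        raise ValueError(f"unknown neutral losses: {sorted(unknown)}")
    loss_map = {name: NEUTRAL_LOSSES[name] for name in losses}

    collector = _Collector(product)
    protonated = product.formula + _H
    collector.add_with_losses(protonated, "protonated molecule", loss_map)

    if max_cleavages >= 1:
        for bond in product.bonds:
            collector.add_with_losses(
                bond.acid_side - HYDROXYL,
                f"{bond.bond_type} cleavage acylium ({bond.label})",
                loss_map,
                allow_co=True,
            )
            collector.add_with_losses(
                bond.amine_side + _H,
                f"{bond.bond_type} cleavage, protonated {bond.bond_type[:1]}-side"
                f" ({bond.label})",
                loss_map,
            )
        _backbone_pieces(product, collector)
        _oligomer_subchains(product, collector, loss_map)

    fragments = collector.fragments()
    ceiling = protonated.mass + 0.01
    return [f for f in fragments if f.mz <= ceiling]


def fragment_coverage(
    predicted: Sequence[PredictedFragment],
    observed: Sequence[float],
    tol_ppm: float = 10.0,
) -> tuple[float, list[tuple[float, PredictedFragment]]]:
    """Greedy one-to-one pairing of observed peaks with predictions.

    Pairs are taken in order of increasing |ppm error|; each observed peak
    and each prediction is used at most once. Returns the matched fraction
    of observed peaks (1.0 for an empty peak list) and the pairing.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if not observed:
        return 1.0, []
    candidates = []
    for obs_index, obs in enumerate(observed):
        for pred_index, frag in enumerate(predicted):
            ppm = (obs - frag.mz) / frag.mz * 1e6
            if abs(ppm) <= tol_ppm:
                candidates.append((abs(ppm), obs_index, pred_index))
    candidates.sort()
    used_obs: set[int] = set()
    used_pred: set[int] = set()
    pairs: list[tuple[float, PredictedFragment]] = []
    for _, obs_index, pred_index in candidates:
        if obs_index in used_obs or pred_index in used_pred:
            continue
        used_obs.add(obs_index)
        used_pred.add(pred_index)
        pairs.append((observed[obs_index], predicted[pred_index]))
    pairs.sort(key=lambda pair: -pair[0])
    return len(used_obs) / len(observed), pairs
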