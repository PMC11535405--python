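"""Chemical inventory for homogeneous water-radiolysis kinetics.

A :class:`ReactionNetwork` holds the species (with elemental composition and
charge, so every reaction can be audited for mass and charge balance) and the
reactions with their room-temperature rate constants.  Rate laws follow the
radiation-chemistry tabulation convention:

* the *kinetic order* of a reaction is set by the unit tag of its rate
  constant (``M-1s-1`` -> second order, ``s-1`` -> first order);
* dynamic (integrated) reactants fill the kinetic-order slots first; any
  remaining slot is filled by a constant-concentration reactant at its fixed
  molarity.  A reaction written ``HO2- + H2O -> H2O2 + OH-`` with a
  bimolecular constant therefore proceeds at ``k [HO2-] [H2O]_fixed``, while
  ``e_aq + e_aq + H2O + H2O -> H2 + OH- + OH-`` keeps the bimolecular law
  ``k [e_aq]^2`` with the solvent appearing only in the atom bookkeeping;
* identical dynamic reactants A + A react at ``r = k [A]^2`` and A is
  consumed at ``2 r`` (through its stoichiometric coefficient of -2).
"""

from __future__ import annotations

import importlib.resources
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "BalanceReport",
    "ReactionTableError",
    "parse_reaction_table",
    "validate_balance",
    "reaction_rate",
    "default_network",
    "default_table_text",
]


class ReactionTableError(ValueError):
    """Malformed reaction-table input."""


@dataclass(frozen=True)
class Species:
    """A chemical species tracked (or pinned) by the kinetics engine.

    Parameters
    ----------
    name
        Identifier used in reaction equations (``OH``, ``e_aq``, ``O2-`` ...).
    charge
        Net charge in elementary charges.
    composition
        Element -> atom-count map (H and O suffice for water radiolysis).
        The hydrated electron carries no atoms, only charge.
    constant_concentration
        If set (mol/L), the species is a reservoir: it enters rate laws at
        this fixed molarity and is never updated by the integrator.
    """

    name: str
    charge: int = 0
    composition: Mapping[str, int] = field(default_factory=dict)
    constant_concentration: float | None = None

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.composition.values()):
            raise ValueError(f"negative atom count in {self.name}")
        if self.constant_concentration is not None and self.constant_concentration < 0:
            raise ValueError(f"negative reservoir concentration for {self.name}")
        # freeze the mapping so the dataclass is hashable in practice
        object.__setattr__(self, "composition", dict(self.composition))

    @property
    def is_constant(self) -> bool:
        return self.constant_concentration is not None


@dataclass(frozen=True)
class Reaction:
    """An elementary reaction with its rate constant.

    ``unit`` is ``"M-1s-1"`` for bimolecular or ``"s-1"`` for unimolecular
    kinetics; it fixes the kinetic order (2 or 1) independently of how many
    solvent molecules appear in the written equation.
    """

    label: str
    reactants: tuple[Species, ...]
    products: tuple[Species, ...]
    k: float
    unit: str = "M-1s-1"
    note: str = ""

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"reaction {self.label}: non-positive rate constant")
        if self.unit not in ("M-1s-1", "s-1"):
            raise ValueError(f"reaction {self.label}: unknown unit tag {self.unit!r}")
        if not (1 <= len(self.reactants)):
            raise ValueError(f"reaction {self.label}: needs at least one reactant")
        order = self.kinetic_order
        n_dynamic = sum(1 for s in self.reactants if not s.is_constant)
        if n_dynamic > order:
            raise ValueError(
                f"reaction {self.label}: {n_dynamic} dynamic reactants exceed "
                f"kinetic order {order} implied by unit {self.unit!r}"
            )

    @property
    def kinetic_order(self) -> int:
        return 2 if self.unit == "M-1s-1" else 1

    def kinetic_reactants(self) -> tuple[Species, ...]:
        """Reactants that enter the rate law: dynamic first, then constants,
        truncated to the kinetic order."""
        dynamic = [s for s in self.reactants if not s.is_constant]
        constant = [s for s in self.reactants if s.is_constant]
        return tuple((dynamic + constant)[: self.kinetic_order])

    def net_coefficients(self) -> dict[str, int]:
        """Products-minus-reactants stoichiometry, keyed by species name."""
        net: Counter[str] = Counter(s.name for s in self.products)
        net.subtract(s.name for s in self.reactants)
        return {name: c for name, c in net.items() if c != 0}


class ReactionNetwork:
    """Species list + reaction list + stoichiometry matrix.

    Species order is declaration order, so the kinetics state vector layout
    is deterministic.  The stoichiometry matrix has one row per species and
    one column per reaction, holding net (products minus reactants)
    coefficients; reservoir species keep their true coefficients here and
    are masked only inside the kinetics right-hand side.
    """

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction]):
        self.species: list[Species] = list(species)
        self.reactions: list[Reaction] = list(reactions)
        self.species_index: dict[str, int] = {
            s.name: i for i, s in enumerate(self.species)
        }
        if len(self.species_index) != len(self.species):
            raise ValueError("duplicate species names")
        for rxn in self.reactions:
            for s in rxn.reactants + rxn.products:
                if s.name not in self.species_index:
                    raise ValueError(
                        f"reaction {rxn.label}: undeclared species {s.name!r}"
                    )
        self.stoichiometry = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for name, coeff in rxn.net_coefficients().items():
                self.stoichiometry[self.species_index[name], j] = coeff

    def __len__(self) -> int:
        return len(self.reactions)

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def get_species(self, name: str) -> Species:
        return self.species[self.species_index[name]]

    def get_reaction(self, label: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.label == label:
                return rxn
        raise KeyError(label)

    def with_pinned(self, pinned: Mapping[str, float]) -> "ReactionNetwork":
        """Return a copy where the named species are held at fixed molarity
        (buffered mode, e.g. pinning H3O+ and OH- at pH 7)."""
        new_species = {
            s.name: (
                Species(s.name, s.charge, s.composition, pinned[s.name])
                if s.name in pinned
                else s
            )
            for s in self.species
        }
        new_reactions = [
            Reaction(
                r.label,
                tuple(new_species[s.name] for s in r.reactants),
                tuple(new_species[s.name] for s in r.products),
                r.k,
                r.unit,
                r.note,
            )
            for r in self.reactions
        ]
        return ReactionNetwork(list(new_species.values()), new_reactions)


@dataclass
class BalanceReport:
    """Per-reaction atom-count and charge deltas (products minus reactants)."""

    entries: dict[str, dict[str, int]]

    @property
    def unbalanced(self) -> list[str]:
        return [
            label
            for label, deltas in self.entries.items()
            if any(v != 0 for v in deltas.values())
        ]

    @property
    def all_balanced(self) -> bool:
        return not self.unbalanced

    def pretty(self) -> str:
        lines = []
        for label, deltas in self.entries.items():
            ok = all(v == 0 for v in deltas.values())
            detail = ", ".join(f"{k}: {v:+d}" for k, v in deltas.items())
            lines.append(f"{label}: {'balanced' if ok else 'UNBALANCED'} ({detail})")
        return "\n".join(lines)


def validate_balance(network: ReactionNetwork) -> BalanceReport:
    """Audit every reaction for element and charge conservation.

    Water written explicitly on either side is included in the counts.
    """
    entries: dict[str, dict[str, int]] = {}
    for rxn in network.reactions:
        deltas: Counter[str] = Counter()
        for side, sign in ((rxn.reactants, -1), (rxn.products, +1)):
            for sp in side:
                for element, n in sp.composition.items():
                    deltas[element] += sign * n
                deltas["charge"] += sign * sp.charge
        entry = {el: deltas.get(el, 0) for el in ("H", "O", "charge")}
        for el, v in deltas.items():
            entry.setdefault(el, v)
        entries[rxn.label] = entry
    return BalanceReport(entries)


def reaction_rate(
    reaction: Reaction, state: Mapping[str, float]
) -> float:
    """Evaluate the rate law r (mol/L/s) at the given concentrations.

    Constant-concentration reactants use their fixed molarity; the state
    mapping is consulted only for dynamic species.  Negative concentrations
    violate the contract.
    """
    rate = reaction.k
    for sp in reaction.kinetic_reactants():
        if sp.is_constant:
            conc = float(sp.constant_concentration)  # type: ignore[arg-type]
        else:
            conc = float(state[sp.name])
            if conc < 0:
                raise ValueError(
                    f"negative concentration for {sp.name}: {conc}"
                )
        rate *= conc
    return rate


# ---------------------------------------------------------------------------
# Table parsing
# ---------------------------------------------------------------------------

#: Species known without an explicit declaration row, so a bare reaction list
#: like "OH + OH -> H2O2, 5.50e9, M-1s-1" parses out of the box.
BUILTIN_SPECIES: dict[str, Species] = {
    s.name: s
    for s in [
        Species("H2O", 0, {"H": 2, "O": 1}, 55.3),
        Species("e_aq", -1, {}),
        Species("OH", 0, {"H": 1, "O": 1}),
        Species("H", 0, {"H": 1}),
        Species("H2", 0, {"H": 2}),
        Species("H2O2", 0, {"H": 2, "O": 2}),
        Species("O2", 0, {"O": 2}),
        Species("O2-", -1, {"O": 2}),
        Species("HO2", 0, {"H": 1, "O": 2}),
        Species("HO2-", -1, {"H": 1, "O": 2}),
        Species("H3O+", 1, {"H": 3, "O": 1}),
        Species("OH-", -1, {"H": 1, "O": 1}),
    ]
}


def _parse_composition(text: str) -> dict[str, int]:
    comp: dict[str, int] = {}
    text = text.strip()
    if not text:
        return comp
    for part in text.split(","):
        element, _, count = part.partition(":")
        comp[element.strip()] = int(count) if count else 1
    return comp


def _parse_side(text: str, registry: Mapping[str, Species], row: int) -> tuple[Species, ...]:
    # split on whitespace-delimited '+' only: species names may end in +/-
    names = [tok.strip() for tok in re.split(r"(?:^|\s)\+(?:\s|$)", " " + text + " ")]
    names = [n for n in names if n]
    if not names:
        raise ReactionTableError(f"row {row}: empty reaction side")
    out = []
    for name in names:
        if not name:
            raise ReactionTableError(f"row {row}: empty species token")
        if name not in registry:
            raise ReactionTableError(f"row {row}: unknown species token {name!r}")
        out.append(registry[name])
    return tuple(out)


def parse_reaction_table(table_text: str) -> ReactionNetwork:
    """Parse a delimiter-separated reaction table into a network.

    Rows are tab-separated (``species`` / ``reaction`` records, see the
    packaged default table) or, for quick interactive use, comma-separated
    ``"A + B -> C, k, unit"`` triples resolved against the built-in water
    species.  Species order is declaration order: declared species first,
    then first-appearance order in the reactions.
    """
    registry: dict[str, Species] = dict(BUILTIN_SPECIES)
    declared: list[Species] = []
    reactions: list[Reaction] = []
    auto = 0
    for row, raw in enumerate(table_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else [f.strip() for f in line.split(",")]
        fields = [f.strip() for f in fields]
        try:
            if fields[0] == "species":
                name = fields[1]
                charge = int(fields[2]) if len(fields) > 2 and fields[2] else 0
                comp = _parse_composition(fields[3]) if len(fields) > 3 else {}
                const = (
                    float(fields[4])
                    if len(fields) > 4 and fields[4]
                    else None
                )
                sp = Species(name, charge, comp, const)
                registry[name] = sp
                declared.append(sp)
                continue
            if fields[0] == "reaction":
                fields = fields[1:]
            if "->" in fields[0]:
                auto += 1
                label, eq, rest = f"R{auto}", fields[0], fields[1:]
            else:
                label, eq, rest = fields[0], fields[1], fields[2:]
            if "->" not in eq:
                raise ReactionTableError(f"row {row}: missing '->' in {eq!r}")
            lhs, _, rhs = eq.partition("->")
            if len(rest) < 2:
                raise ReactionTableError(f"row {row}: expected rate constant and unit tag")
            k = float(rest[0])
            if k <= 0:
                raise ReactionTableError(f"row {row}: non-positive rate constant {k}")
            unit = rest[1]
            note = rest[2] if len(rest) > 2 else ""
            reactions.append(
                Reaction(
                    label,
                    _parse_side(lhs, registry, row),
                    _parse_side(rhs, registry, row),
                    k,
                    unit,
                    note,
                )
            )
        except ReactionTableError:
            raise
        except (ValueError, IndexError) as exc:
            raise ReactionTableError(f"row {row}: malformed row ({exc})") from exc

    # species order: declared first, then first appearance in reactions
    order: dict[str, Species] = {s.name: s for s in declared}
    for rxn in reactions:
        for sp in rxn.reactants + rxn.products:
            order.setdefault(sp.name, sp)
    return ReactionNetwork(list(order.values()), reactions)


def default_table_text() -> str:
    """Raw text of the packaged default reaction table."""
    return (
        importlib.resources.files("flashlysis.data")
        .joinpath("reactions_default.tsv")
        .read_text()
    )


def default_network() -> ReactionNetwork:
    """The packaged water-radiolysis network.

    Contains the six peroxide/superoxide reactions that govern the late
    H2O2 and O2- evolution (labels 1a, 1b, 2a-2d) with their published rate
    constants, plus a standard compilation set covering e_aq, H, OH, H2,
    H2O2, O2, HO2, O2-, H3O+ and OH- interconversions and the acid-base
    equilibria of water, HO2 and H2O2.  Every reaction is atom- and
    charge-balanced; provenance is tagged per row in the data file.
    """
    return parse_reaction_table(default_table_text())
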