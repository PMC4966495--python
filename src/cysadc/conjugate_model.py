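"""Conjugate structure model for cysteine-conjugated ADCs.

An IgG1 antibody carries four inter-chain disulfide bonds: one between each
light chain and its heavy chain, and two in the hinge between the heavy
chains.  Partial reduction opens a subset of those bonds; every opened bond
exposes two free cysteine thiols, each of which is capped with one
maleimide drug-linker.  Drug loads therefore occur in intervals of
0, 2, 4, 6 and 8, and within each load the *position* of the opened bonds
defines positional isomers.

This module enumerates those isomers as equivalence classes of reduction
states under the molecular symmetry, and predicts the covalent sub-units
(connected components over the remaining intact bonds) that each isomer
dissociates into under denaturing reversed-phase conditions, together with
their average masses.  Those dissociation signatures are what a
second-dimension RP-MS separation observes, and they identify isomers that
UV chromatography alone cannot distinguish.

Mass bookkeeping convention: chain base masses are given in the fully
reduced state (all inter-chain cysteines as free thiols, intra-chain
disulfides and constant modifications folded in); every intact inter-chain
disulfide then subtracts one H2-loss decrement (2.016 Da), and every
conjugated drug adds the full drug-linker average mass (Michael addition of
a thiol onto the maleimide — no leaving group).  This makes mass
conservation across dissociation exact by construction.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "STANDARD_ATOMIC_WEIGHTS",
    "DISULFIDE_MASS_DECREMENT",
    "ChemicalFormula",
    "DrugLinker",
    "ChainSpec",
    "DisulfideBond",
    "AssemblySpec",
    "ReductionState",
    "IsoformClass",
    "Subunit",
    "DissociationSignature",
    "average_mass",
    "enumerate_isoforms",
    "dissociate",
    "subunit_mass",
    "intact_mass",
]

#: IUPAC conventional standard atomic weights (abridged to elements that
#: occur in protein/linker chemistry).  Conventional single values, not
#: interval midpoints.
STANDARD_ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.904,
    "Na": 22.990,
    "K": 39.098,
    "Ca": 40.078,
    "Mg": 24.305,
    "Fe": 55.845,
    "Zn": 65.38,
    "Se": 78.971,
    "B": 10.81,
    "Si": 28.085,
}

#: Average mass lost per intact disulfide bond relative to the two free
#: thiols (loss of 2 H).
DISULFIDE_MASS_DECREMENT: float = 2.016

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")


class ConfigurationError(ValueError):
    """Raised when a conjugate configuration violates a structural invariant."""


@dataclass(frozen=True)
class ChemicalFormula:
    """Elemental composition as a map ``element symbol -> count``."""

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for symbol, count in self.element_counts.items():
            if count < 0:
                raise ValueError(f"negative count for element {symbol!r}")

    @classmethod
    def from_string(cls, formula: str) -> "ChemicalFormula":
        """Parse a Hill-style formula such as ``"C23H24N2O3"``."""
        counts: dict[str, int] = {}
        pos = 0
        stripped = formula.replace("_", "").strip()
        while pos < len(stripped):
            match = _FORMULA_TOKEN.match(stripped, pos)
            if match is None or match.end() == pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            symbol, digits = match.group(1), match.group(2)
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = match.end()
        return cls(counts)

    def average_mass(self) -> float:
        return average_mass(self)


def average_mass(formula: ChemicalFormula | str) -> float:
    """Average molecular mass (Da) from standard atomic weights.

    Raises
    ------
    ValueError
        If the formula contains an element symbol with no standard atomic
        weight entry; the message names the offending symbol.
    """
    if isinstance(formula, str):
        formula = ChemicalFormula.from_string(formula)
    total = 0.0
    for symbol, count in formula.element_counts.items():
        try:
            weight = STANDARD_ATOMIC_WEIGHTS[symbol]
        except KeyError:
            raise ValueError(f"unknown element symbol: {symbol!r}") from None
        total += count * weight
    return total


@dataclass(frozen=True)
class DrugLinker:
    """A maleimide drug-linker conjugated onto a reduced cysteine thiol.

    Thiol-maleimide conjugation is a Michael addition: the *full* drug
    average mass is added per occupied site, with no leaving group.
    """

    average_mass: float
    formula: ChemicalFormula | None = None
    attachment: str = "thiol-maleimide"

    def __post_init__(self) -> None:
        if self.average_mass <= 0:
            raise ValueError("drug-linker average mass must be positive")

    @classmethod
    def from_formula(cls, formula: str | ChemicalFormula) -> "DrugLinker":
        if isinstance(formula, str):
            formula = ChemicalFormula.from_string(formula)
        return cls(average_mass=average_mass(formula), formula=formula)


@dataclass(frozen=True)
class ChainSpec:
    """One antibody chain species.

    ``reduced_average_mass`` is the chain's average mass with every
    inter-chain cysteine as a free thiol.  ``glycoforms`` lists
    ``(name, mass_delta)`` pairs relative to that base mass and applies to
    heavy chains only (N-glycosylation on the Fc).
    """

    role: str  # "light" | "heavy"
    reduced_average_mass: float
    glycoforms: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("light", "heavy"):
            raise ValueError(f"chain role must be 'light' or 'heavy', got {self.role!r}")
        if self.reduced_average_mass <= 0:
            raise ValueError("chain mass must be positive")
        if self.role == "light" and self.glycoforms:
            raise ValueError("light chains carry no glycoforms")

    def glycoform_delta(self, name: str | None) -> float:
        if name is None:
            return 0.0
        for gname, delta in self.glycoforms:
            if gname == name:
                return delta
        raise ValueError(f"unknown glycoform {name!r} for {self.role} chain")


@dataclass(frozen=True)
class DisulfideBond:
    """An inter-chain disulfide; endpoints are ``(chain_instance, site_class)``.

    ``site_class`` is ``"LC-HC"`` for light–heavy bonds and ``"hinge"`` for
    heavy–heavy hinge bonds.  Reduction of one bond creates exactly two
    conjugation sites, one on each endpoint chain.
    """

    id: str
    endpoints: tuple[tuple[str, str], tuple[str, str]]

    def __post_init__(self) -> None:
        (c1, _), (c2, _) = self.endpoints
        if c1 == c2:
            raise ValueError(f"bond {self.id!r}: endpoints must be on different chain instances")

    @property
    def site_class(self) -> str:
        return self.endpoints[0][1]

    @property
    def chain_ids(self) -> tuple[str, str]:
        return (self.endpoints[0][0], self.endpoints[1][0])


@dataclass(frozen=True)
class AssemblySpec:
    """Chains, inter-chain disulfide topology and symmetry of a conjugate.

    ``symmetries`` holds generator permutations of bond ids (each an
    involution mapping the bond set onto itself).  For a standard IgG1 the
    generators are the two-fold molecular flip (L1,H1)<->(L2,H2) with
    hinge-1<->hinge-2, and the exchange of the two chemically equivalent
    adjacent hinge bonds; together they give the Klein four-group that
    collapses the 16 reduction states into the 9 observed isoform classes.
    """

    chains: Mapping[str, ChainSpec]
    bonds: tuple[DisulfideBond, ...]
    drug: DrugLinker
    symmetries: tuple[Mapping[str, str], ...] = ()
    disulfide_mass_decrement: float = DISULFIDE_MASS_DECREMENT

    def __post_init__(self) -> None:
        bond_ids = {b.id for b in self.bonds}
        if len(bond_ids) != len(self.bonds):
            raise ConfigurationError("duplicate bond ids")
        for bond in self.bonds:
            for chain_id, _ in bond.endpoints:
                if chain_id not in self.chains:
                    raise ConfigurationError(f"bond {bond.id!r} references unknown chain {chain_id!r}")
        for perm in self.symmetries:
            if set(perm) != bond_ids or set(perm.values()) != bond_ids:
                raise ConfigurationError("symmetry permutation must map the bond set onto itself")
            for a, b in perm.items():
                if perm[b] != a:
                    raise ConfigurationError(f"symmetry is not an involution at bond {a!r}")

    def bond(self, bond_id: str) -> DisulfideBond:
        for b in self.bonds:
            if b.id == bond_id:
                return b
        raise KeyError(bond_id)

    def symmetry_group(self) -> list[dict[str, str]]:
        """Closure of the generator permutations (including identity)."""
        ids = sorted(b.id for b in self.bonds)
        identity = {i: i for i in ids}
        group: list[dict[str, str]] = [identity]
        frontier = [identity]
        while frontier:
            new: list[dict[str, str]] = []
            for g in frontier:
                for gen in self.symmetries:
                    composed = {i: gen[g[i]] for i in ids}
                    if composed not in group and composed not in new:
                        new.append(composed)
            group.extend(new)
            frontier = new
        return group


@dataclass(frozen=True)
class ReductionState:
    """A concrete subset of reduced (opened) inter-chain bonds."""

    reduced_bonds: frozenset[str]

    @property
    def drug_count(self) -> int:
        # each opened bond exposes 2 thiols, each capped with one drug
        return 2 * len(self.reduced_bonds)


@dataclass(frozen=True)
class IsoformClass:
    """An equivalence class of reduction states under the assembly symmetry.

    ``label`` follows the field convention: bare load number when the load
    has a single class, else suffixes a, b, c ordered by the number of
    reduced light–heavy bonds (descending) — so 4a opens both LC-HC bonds,
    4b one LC-HC plus one hinge, 4c both hinge bonds.
    """

    label: str
    dar: int
    representative: ReductionState
    members: tuple[ReductionState, ...]


@dataclass(frozen=True)
class Subunit:
    """One covalent dissociation product of an isoform.

    mass = sum(chain reduced masses) + sum(glycoform deltas)
         + drug_count * drug mass - internal_intact_bonds * decrement
    """

    chain_ids: tuple[str, ...]
    drug_count: int
    internal_intact_bonds: int
    glycoform_assignment: tuple[tuple[str, str], ...]  # (heavy chain id, glycoform)
    mass: float

    def composition_label(self, chains: Mapping[str, ChainSpec]) -> str:
        n_light = sum(1 for c in self.chain_ids if chains[c].role == "light")
        n_heavy = sum(1 for c in self.chain_ids if chains[c].role == "heavy")
        parts = []
        if n_light:
            parts.append(f"{n_light}L" if n_light > 1 else "L")
        if n_heavy:
            parts.append(f"{n_heavy}H" if n_heavy > 1 else "H")
        label = "+".join(parts) if parts else "empty"
        return f"{label}+{self.drug_count}drug"


@dataclass(frozen=True)
class DissociationSignature:
    """The multiset of sub-units an isoform yields when denatured."""

    isoform_label: str
    subunits: tuple[Subunit, ...]
    unique_masses: tuple[float, ...]
    merge_tolerance: float = 0.5

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.subunits)


def _lc_hc_reduced_count(state: ReductionState, assembly: AssemblySpec) -> int:
    return sum(1 for bid in state.reduced_bonds if assembly.bond(bid).site_class == "LC-HC")


def enumerate_isoforms(assembly: AssemblySpec) -> list[IsoformClass]:
    """Enumerate all positional isomer classes of partial reduction.

    Every subset of the inter-chain bonds is a reduction state; states are
    collapsed into classes by the assembly symmetry group.  Classes are
    returned sorted by (drug load, label).
    """
    group = assembly.symmetry_group()
    bond_ids = sorted(b.id for b in assembly.bonds)
    seen: set[frozenset[str]] = set()
    raw_classes: list[tuple[int, int, tuple[frozenset[str], ...]]] = []
    for r in range(len(bond_ids) + 1):
        for combo in itertools.combinations(bond_ids, r):
            subset = frozenset(combo)
            if subset in seen:
                continue
            orbit = {frozenset(g[b] for b in subset) for g in group}
            seen |= orbit
            members = tuple(sorted(orbit, key=lambda s: tuple(sorted(s))))
            rep = members[0]
            n_lc_hc = _lc_hc_reduced_count(ReductionState(rep), assembly)
            raw_classes.append((2 * len(subset), n_lc_hc, members))

    classes: list[IsoformClass] = []
    raw_classes.sort(key=lambda t: (t[0], -t[1]))
    by_dar: dict[int, list[tuple[int, tuple[frozenset[str], ...]]]] = {}
    for dar, n_lc_hc, members in raw_classes:
        by_dar.setdefault(dar, []).append((n_lc_hc, members))
    for dar in sorted(by_dar):
        entries = by_dar[dar]
        for i, (_, members) in enumerate(entries):
            suffix = chr(ord("a") + i) if len(entries) > 1 else ""
            classes.append(
                IsoformClass(
                    label=f"{dar}{suffix}",
                    dar=dar,
                    representative=ReductionState(members[0]),
                    members=tuple(ReductionState(m) for m in members),
                )
            )
    return classes


def _merge_unique(masses: Sequence[float], tolerance: float) -> tuple[float, ...]:
    """Collapse masses closer than ``tolerance`` into single representatives."""
    if not masses:
        return ()
    ordered = sorted(masses)
    merged: list[list[float]] = [[ordered[0]]]
    for m in ordered[1:]:
        if m - merged[-1][-1] <= tolerance:
            merged[-1].append(m)
        else:
            merged.append([m])
    return tuple(sum(g) / len(g) for g in merged)


def _resolve_glycoforms(
    assembly: AssemblySpec, glycoform: str | Mapping[str, str] | None
) -> dict[str, str | None]:
    """Per-heavy-chain glycoform names from a single name or explicit map."""
    assignment: dict[str, str | None] = {}
    for chain_id, spec in assembly.chains.items():
        if spec.role != "heavy":
            continue
        if glycoform is None:
            assignment[chain_id] = None
        elif isinstance(glycoform, str):
            assignment[chain_id] = glycoform
        else:
            assignment[chain_id] = glycoform.get(chain_id)
    return assignment


def subunit_mass(
    chain_ids: Sequence[str],
    drug_count: int,
    internal_intact_bonds: int,
    assembly: AssemblySpec,
    glycoform: str | Mapping[str, str] | None = None,
) -> float:
    """Average mass of a covalent sub-unit per the additive mass model."""
    per_heavy = _resolve_glycoforms(assembly, glycoform)
    total = 0.0
    for chain_id in chain_ids:
        spec = assembly.chains[chain_id]
        total += spec.reduced_average_mass
        if spec.role == "heavy":
            total += spec.glycoform_delta(per_heavy.get(chain_id))
        elif isinstance(glycoform, Mapping) and chain_id in glycoform:
            raise ValueError(f"glycoform named for light chain {chain_id!r}")
    total += drug_count * assembly.drug.average_mass
    total -= internal_intact_bonds * assembly.disulfide_mass_decrement
    return total


def dissociate(
    isoform: IsoformClass,
    assembly: AssemblySpec,
    glycoform: str | Mapping[str, str] | None = None,
    merge_tolerance: float = 0.5,
) -> DissociationSignature:
    """Covalent sub-units an isoform dissociates into when denatured.

    Sub-units are connected components of the chain graph whose edges are
    the *intact* inter-chain bonds; each reduced bond contributes one drug
    to the component holding each of its two endpoint cysteines.
    """
    reduced = isoform.representative.reduced_bonds
    parent: dict[str, str] = {c: c for c in assembly.chains}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    intact = [b for b in assembly.bonds if b.id not in reduced]
    for bond in intact:
        c1, c2 = bond.chain_ids
        parent[find(c1)] = find(c2)

    components: dict[str, list[str]] = {}
    for chain_id in assembly.chains:
        components.setdefault(find(chain_id), []).append(chain_id)

    drug_per_component: dict[str, int] = {root: 0 for root in components}
    for bond_id in reduced:
        for chain_id, _site in assembly.bond(bond_id).endpoints:
            drug_per_component[find(chain_id)] += 1

    intact_per_component: dict[str, int] = {root: 0 for root in components}
    for bond in intact:
        intact_per_component[find(bond.chain_ids[0])] += 1

    per_heavy = _resolve_glycoforms(assembly, glycoform)
    subunits: list[Subunit] = []
    for root, chain_ids in components.items():
        chain_ids = tuple(sorted(chain_ids))
        glyco = tuple(
            (c, per_heavy[c])
            for c in chain_ids
            if assembly.chains[c].role == "heavy" and per_heavy.get(c) is not None
        )
        mass = subunit_mass(
            chain_ids,
            drug_per_component[root],
            intact_per_component[root],
            assembly,
            glycoform,
        )
        subunits.append(
            Subunit(
                chain_ids=chain_ids,
                drug_count=drug_per_component[root],
                internal_intact_bonds=intact_per_component[root],
                glycoform_assignment=glyco,  # type: ignore[arg-type]
                mass=mass,
            )
        )
    subunits.sort(key=lambda s: s.mass)
    return DissociationSignature(
        isoform_label=isoform.label,
        subunits=tuple(subunits),
        unique_masses=_merge_unique([s.mass for s in subunits], merge_tolerance),
        merge_tolerance=merge_tolerance,
    )


def intact_mass(
    isoform: IsoformClass,
    assembly: AssemblySpec,
    glycoform: str | Mapping[str, str] | None = None,
) -> float:
    """Average mass of the intact conjugate for one isoform class."""
    n_intact = len(assembly.bonds) - len(isoform.representative.reduced_bonds)
    per_heavy = _resolve_glycoforms(assembly, glycoform)
    total = 0.0
    for chain_id, spec in assembly.chains.items():
        total += spec.reduced_average_mass
        if spec.role == "heavy":
            total += spec.glycoform_delta(per_heavy.get(chain_id))
    total += isoform.dar * assembly.drug.average_mass
    total -= n_intact * assembly.disulfide_mass_decrement
    return total
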