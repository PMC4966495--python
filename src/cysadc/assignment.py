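"""Isoform assignment from dissociated sub-unit masses.

Each positional isoform of a cysteine-conjugated ADC dissociates, under
denaturing reversed-phase conditions, into a characteristic set of
covalent sub-unit masses.  A heart-cut fraction of one HIC peak therefore
yields a set of deconvolved neutral masses that can be matched against
the library of predicted signatures.  An assignment is *unique* only when
the match is two-sided: every observed mass is explained by the candidate
(directly, as a glycoform variant, or as a single known modification
satellite of an explained mass) AND every expected unique mass of the
candidate is observed.  One-sided matches remain listed as candidates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from cysadc.conjugate_model import AssemblySpec, dissociate, enumerate_isoforms
from cysadc.ms_tools import (
    DEFAULT_MODIFICATIONS,
    MassMatch,
    ModificationTable,
    ppm_error,
)

__all__ = [
    "ExpectedMass",
    "LibraryEntry",
    "SignatureLibrary",
    "CandidateMatch",
    "AssignmentResult",
    "UniquenessReport",
    "build_library",
    "match_observed",
    "uniqueness_analysis",
]


@dataclass(frozen=True)
class ExpectedMass:
    """One expected unique sub-unit mass with its glycoform variants.

    ``variants`` maps a variant label (e.g. ``"G0F"``, ``"G0F/G1F"`` for a
    two-heavy-chain sub-unit, or ``""`` for glycan-free) to a mass in Da.
    Any observed variant satisfies the expectation — G0F and G1F forms of
    the same sub-unit count as one expected mass.
    """

    subunit: str
    variants: tuple[tuple[str, float], ...]

    @property
    def base_mass(self) -> float:
        return self.variants[0][1]


@dataclass(frozen=True)
class LibraryEntry:
    label: str
    dar: int
    expected: tuple[ExpectedMass, ...]

    @property
    def base_masses(self) -> tuple[float, ...]:
        return tuple(e.base_mass for e in self.expected)


@dataclass(frozen=True)
class SignatureLibrary:
    entries: tuple[LibraryEntry, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate isoform labels in signature library")

    def entry(self, label: str) -> LibraryEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)


@dataclass
class CandidateMatch:
    label: str
    dar: int
    matches: list[MassMatch]
    unexplained_observed: list[float]
    unobserved_expected: list[str]

    @property
    def defect_count(self) -> int:
        return len(self.unexplained_observed) + len(self.unobserved_expected)

    @property
    def mean_abs_ppm(self) -> float:
        direct = [abs(m.ppm_error) for m in self.matches if m.modification is None]
        return sum(direct) / len(direct) if direct else float("inf")


@dataclass
class AssignmentResult:
    observed_masses: list[float]
    candidates: list[CandidateMatch]
    unique: bool

    @property
    def best(self) -> CandidateMatch | None:
        return self.candidates[0] if self.candidates else None


@dataclass
class UniquenessReport:
    """Pairs of isoforms whose signatures could be confused.

    ``identical_pairs`` lists label pairs with indistinguishable unique
    mass sets; ``subset_pairs`` lists ``(inner, outer)`` where the inner
    isoform's signature is a strict subset of the outer's — a co-elution
    of the outer isoform could masquerade as inner plus extras.
    """

    identical_pairs: list[tuple[str, str]] = field(default_factory=list)
    subset_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.identical_pairs and not self.subset_pairs


def _glyco_variants(
    n_heavy: int, glycoforms: Sequence[tuple[str, float]]
) -> list[tuple[str, float]]:
    """Glycoform combinations (with repetition) for a sub-unit with n heavy chains."""
    if n_heavy == 0 or not glycoforms:
        return [("", 0.0)]
    variants: list[tuple[str, float]] = []
    for combo in itertools.combinations_with_replacement(glycoforms, n_heavy):
        name = "/".join(g[0] for g in combo)
        delta = sum(g[1] for g in combo)
        variants.append((name, delta))
    return variants


def build_library(
    assembly: AssemblySpec,
    glycoforms: Sequence[str] | None = None,
    merge_tolerance: float = 0.5,
) -> SignatureLibrary:
    """Build the signature library from the conjugate assembly.

    For each isoform class the dissociation signature is computed with the
    first configured glycoform on every heavy chain as the canonical base;
    each expected unique mass is then expanded over the glycoform
    combinations of its sub-unit's heavy chains.
    """
    heavy = next(s for s in assembly.chains.values() if s.role == "heavy")
    if glycoforms is None:
        names = [g[0] for g in heavy.glycoforms] or [None]  # type: ignore[list-item]
    else:
        names = list(glycoforms)
    canonical = names[0]
    glyco_pairs = [(n, heavy.glycoform_delta(n)) for n in names if n is not None]

    entries: list[LibraryEntry] = []
    for isoform in enumerate_isoforms(assembly):
        sig = dissociate(isoform, assembly, glycoform=canonical, merge_tolerance=merge_tolerance)
        # one ExpectedMass per unique mass; pick a representative sub-unit for each
        expected: list[ExpectedMass] = []
        used: set[int] = set()
        for unique in sig.unique_masses:
            rep = None
            for i, sub in enumerate(sig.subunits):
                if i not in used and abs(sub.mass - unique) <= merge_tolerance:
                    rep = sub
                    used.add(i)
                    break
            assert rep is not None
            n_heavy = sum(
                1 for c in rep.chain_ids if assembly.chains[c].role == "heavy"
            )
            base_delta = n_heavy * heavy.glycoform_delta(canonical)
            glycan_free = rep.mass - base_delta
            variants = tuple(
                (name, glycan_free + delta)
                for name, delta in _glyco_variants(n_heavy, glyco_pairs)
            ) or ((("", rep.mass),))
            expected.append(
                ExpectedMass(subunit=rep.composition_label(assembly.chains), variants=variants)
            )
        entries.append(LibraryEntry(label=isoform.label, dar=isoform.dar, expected=tuple(expected)))
    return SignatureLibrary(entries=tuple(entries))


def _mass_tolerance(predicted: float, ppm_tolerance: float, da_floor: float) -> float:
    return max(da_floor, ppm_tolerance * predicted * 1e-6)


def match_observed(
    observed: Sequence[float],
    lib: SignatureLibrary,
    ppm_tolerance: float = 10.0,
    da_floor: float = 1.0,
    modification_table: ModificationTable = DEFAULT_MODIFICATIONS,
) -> AssignmentResult:
    """Match a set of observed neutral masses against the signature library.

    ``da_floor`` is an absolute tolerance floor applied alongside the ppm
    criterion (10 ppm of a 23.6 kDa sub-unit is only 0.24 Da, below the
    deconvolution grid resolution).

    Candidates are ranked by (number of unexplained observed masses plus
    unobserved expected masses, then mean absolute ppm error of direct
    matches); the result is flagged unique when exactly one candidate has
    no defects.
    """
    observed = [float(m) for m in observed]
    if not observed:
        raise ValueError("no observed masses provided")
    if ppm_tolerance <= 0:
        raise ValueError("ppm_tolerance must be positive")

    candidates: list[CandidateMatch] = []
    for entry in lib.entries:
        matches: list[MassMatch] = []
        unexplained: list[float] = []
        observed_groups: set[int] = set()
        direct_hits: list[tuple[float, float]] = []  # (observed, variant mass)
        # first pass: direct / glycoform-variant matches
        pending: list[float] = []
        for m in observed:
            best: tuple[float, int, float] | None = None  # (|ppm|, group idx, variant mass)
            for gi, exp in enumerate(entry.expected):
                for _name, vmass in exp.variants:
                    if abs(m - vmass) <= _mass_tolerance(vmass, ppm_tolerance, da_floor):
                        err = abs(ppm_error(m, vmass))
                        if best is None or err < best[0]:
                            best = (err, gi, vmass)
            if best is not None:
                _, gi, vmass = best
                observed_groups.add(gi)
                matches.append(MassMatch(m, vmass, ppm_error(m, vmass)))
                direct_hits.append((m, vmass))
            else:
                pending.append(m)
        # second pass: single-modification satellites of directly matched masses
        for m in pending:
            satellite: MassMatch | None = None
            for _obs, parent in direct_hits:
                delta = m - parent
                for mod in modification_table.entries:
                    if abs(delta - mod.mass_delta) <= mod.tolerance:
                        pred = parent + mod.mass_delta
                        satellite = MassMatch(m, pred, ppm_error(m, pred), modification=mod.name)
                        break
                if satellite is not None:
                    break
            if satellite is not None:
                matches.append(satellite)
            else:
                unexplained.append(m)
        unobserved = [
            exp.subunit for gi, exp in enumerate(entry.expected) if gi not in observed_groups
        ]
        candidates.append(
            CandidateMatch(
                label=entry.label,
                dar=entry.dar,
                matches=matches,
                unexplained_observed=unexplained,
                unobserved_expected=unobserved,
            )
        )
    candidates.sort(key=lambda c: (c.defect_count, c.mean_abs_ppm, c.label))
    perfect = [c for c in candidates if c.defect_count == 0]
    return AssignmentResult(
        observed_masses=observed,
        candidates=candidates,
        unique=len(perfect) == 1,
    )


def _set_contained(a: Sequence[float], b: Sequence[float], tol: float) -> bool:
    return all(any(abs(x - y) <= tol for y in b) for x in a)


def uniqueness_analysis(lib: SignatureLibrary, tolerance: float = 0.5) -> UniquenessReport:
    """Pairwise signature comparison across the library.

    Reports isoform pairs whose unique-mass sets are indistinguishable
    within ``tolerance`` and strict subset relations (the smaller
    signature contained in the larger), which flag potential co-elution
    confounds.
    """
    report = UniquenessReport()
    for i, a in enumerate(lib.entries):
        for b in lib.entries[i + 1 :]:
            a_in_b = _set_contained(a.base_masses, b.base_masses, tolerance)
            b_in_a = _set_contained(b.base_masses, a.base_masses, tolerance)
            if a_in_b and b_in_a:
                report.identical_pairs.append((a.label, b.label))
            elif a_in_b:
                report.subset_pairs.append((a.label, b.label))
            elif b_in_a:
                report.subset_pairs.append((b.label, a.label))
    return report
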