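"""Conjugate topology: formula masses, isomer enumeration, dissociation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cysadc.conjugate_model import (
    AssemblySpec,
    ChainSpec,
    ChemicalFormula,
    ConfigurationError,
    DisulfideBond,
    DrugLinker,
    average_mass,
    dissociate,
    enumerate_isoforms,
    intact_mass,
    subunit_mass,
)

LIGHT_PLUS_1 = 23580.0
HEAVY_G0F_PLUS_3 = 51630.6


class TestAverageMass:
    @pytest.mark.parametrize(
        "formula, expected, tol",
        [
            ("C23H24N2O3", 376.46, 0.01),  # the maleimide drug-mimic
            ("H2O", 18.015, 0.001),
            ("C6H12O6", 180.156, 0.01),
        ],
    )
    def test_known_formulas(self, formula, expected, tol):
        assert average_mass(formula) == pytest.approx(expected, abs=tol)

    def test_empty_formula_is_massless(self):
        assert average_mass(ChemicalFormula({})) == 0.0

    def test_unknown_element_is_named_in_error(self):
        with pytest.raises(ValueError, match="Xq"):
            average_mass("C2Xq3")

    def test_agrees_with_pyteomics_average_masses(self):
        # independent mass table; agreement to the small spread between
        # atomic-weight conventions
        from pyteomics import mass as pmass

        ours = average_mass("C23H24N2O3")
        theirs = pmass.calculate_mass(formula="C23H24N2O3", average=True)
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ChemicalFormula({"C": -1})

    def test_underscore_style_formula_parses(self):
        assert average_mass("C_23_H_24_N_2_O_3_") == pytest.approx(376.46, abs=0.01)


def _linear_assembly(n_bonds: int, involution: dict[str, str]) -> AssemblySpec:
    """n disjoint light-chain pairs, one bond per pair, arbitrary bond symmetry."""
    light = ChainSpec(role="light", reduced_average_mass=1000.0)
    chains = {}
    bonds = []
    for i in range(n_bonds):
        a, b = f"A{i}", f"B{i}"
        chains[a] = light
        chains[b] = light
        bonds.append(DisulfideBond(f"b{i}", ((a, "LC-HC"), (b, "LC-HC"))))
    if not n_bonds:
        chains["A0"] = light
    return AssemblySpec(
        chains=chains,
        bonds=tuple(bonds),
        drug=DrugLinker(average_mass=100.0),
        symmetries=(involution,) if involution else (),
    )


@st.composite
def involutions(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    ids = [f"b{i}" for i in range(n)]
    k = draw(st.integers(min_value=0, max_value=n // 2))
    shuffled = draw(st.permutations(ids))
    perm = {i: i for i in ids}
    for j in range(k):
        a, b = shuffled[2 * j], shuffled[2 * j + 1]
        perm[a], perm[b] = b, a
    return n, perm


class TestEnumeration:
    def test_igg1_yields_nine_classes_with_expected_multiplicities(self, assembly):
        classes = enumerate_isoforms(assembly)
        assert len(classes) == 9
        per_dar = {}
        for c in classes:
            per_dar[c.dar] = per_dar.get(c.dar, 0) + 1
        assert per_dar == {0: 1, 2: 2, 4: 3, 6: 2, 8: 1}
        # all 16 reduction states appear exactly once across classes
        all_states = [m.reduced_bonds for c in classes for m in c.members]
        assert len(all_states) == 16
        assert len(set(all_states)) == 16

    def test_igg1_labels_follow_lc_hc_ordering(self, assembly, isoforms):
        assert set(isoforms) == {"0", "2a", "2b", "4a", "4b", "4c", "6a", "6b", "8"}
        site = lambda label: sorted(
            assembly.bond(b).site_class for b in isoforms[label].representative.reduced_bonds
        )
        assert site("2a") == ["LC-HC"]
        assert site("2b") == ["hinge"]
        assert site("4a") == ["LC-HC", "LC-HC"]
        assert site("4b") == ["LC-HC", "hinge"]
        assert site("4c") == ["hinge", "hinge"]
        assert site("6a") == ["LC-HC", "LC-HC", "hinge"]
        assert site("6b") == ["LC-HC", "hinge", "hinge"]

    def test_zero_bond_assembly_has_single_unconjugated_class(self):
        classes = enumerate_isoforms(_linear_assembly(0, {}))
        assert len(classes) == 1
        assert classes[0].dar == 0 and classes[0].label == "0"

    def test_single_bond_assembly_has_two_classes(self):
        classes = enumerate_isoforms(_linear_assembly(1, {"b0": "b0"}))
        assert [c.dar for c in classes] == [0, 2]

    def test_non_involution_symmetry_rejected(self):
        light = ChainSpec(role="light", reduced_average_mass=1000.0)
        chains = {f"C{i}": light for i in range(6)}
        bonds = tuple(
            DisulfideBond(f"b{i}", ((f"C{2*i}", "LC-HC"), (f"C{2*i+1}", "LC-HC")))
            for i in range(3)
        )
        cycle = {"b0": "b1", "b1": "b2", "b2": "b0"}  # 3-cycle, not an involution
        with pytest.raises(ConfigurationError):
            AssemblySpec(chains=chains, bonds=bonds, drug=DrugLinker(average_mass=1.0), symmetries=(cycle,))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(involutions())
    def test_enumeration_matches_brute_force_orbit_partition(self, case):
        """Oracle: partition all 2^n subsets into orbits of {id, sigma} directly."""
        n, perm = case
        assembly = _linear_assembly(n, perm)
        ids = [f"b{i}" for i in range(n)]

        # independent brute force: orbit of s is {s, sigma(s)}
        orbits = set()
        for r in range(n + 1):
            for combo in itertools.combinations(ids, r):
                s = frozenset(combo)
                image = frozenset(perm[b] for b in s)
                orbits.add(frozenset({s, image}))
        classes = enumerate_isoforms(assembly)
        assert len(classes) == len(orbits)
        got = {frozenset(m.reduced_bonds for m in c.members) for c in classes}
        assert got == orbits


class TestDissociation:
    def test_dar8_gives_two_unique_subunit_masses(self, signatures):
        sig = signatures["8"]
        assert len(sig.subunits) == 4
        assert [round(m, 1) for m in sig.unique_masses] == [LIGHT_PLUS_1, HEAVY_G0F_PLUS_3]

    def test_isoform_6b_gives_three_unique_masses(self, signatures):
        masses = [round(m, 1) for m in signatures["6b"].unique_masses]
        assert masses == [LIGHT_PLUS_1, HEAVY_G0F_PLUS_3, 74455.7]

    def test_dar0_stays_intact_with_no_drugs(self, signatures):
        sig = signatures["0"]
        assert len(sig.subunits) == 1
        assert sig.subunits[0].drug_count == 0
        assert sig.subunits[0].mass == pytest.approx(147401.5, abs=0.1)

    def test_mass_conservation_for_every_isoform_and_glycoform(self, assembly, isoforms):
        for glyco in ("G0F", "G1F"):
            for iso in isoforms.values():
                sig = dissociate(iso, assembly, glycoform=glyco)
                assert sig.total_mass == pytest.approx(
                    intact_mass(iso, assembly, glycoform=glyco), abs=1e-6
                )

    def test_drug_bookkeeping(self, assembly, isoforms):
        for iso in isoforms.values():
            sig = dissociate(iso, assembly, glycoform="G0F")
            n_reduced = len(iso.representative.reduced_bonds)
            assert sum(s.drug_count for s in sig.subunits) == 2 * n_reduced == iso.dar

    def test_nine_signatures_are_pairwise_distinct(self, signatures):
        mass_sets = [tuple(round(m, 1) for m in sig.unique_masses) for sig in signatures.values()]
        assert len(set(mass_sets)) == 9

    def test_intact_mass_increases_strictly_with_dar(self, assembly, isoforms):
        by_dar = sorted({(iso.dar, intact_mass(iso, assembly, "G0F")) for iso in isoforms.values()})
        masses = [m for _d, m in by_dar]
        assert all(b > a for a, b in zip(masses, masses[1:]))

    def test_dar8_intact_mass_algebra(self, assembly, isoforms):
        m0 = intact_mass(isoforms["0"], assembly, "G0F")
        m8 = intact_mass(isoforms["8"], assembly, "G0F")
        assert m8 == pytest.approx(m0 + 8 * 376.46 + 4 * 2.016, abs=1e-6)


class TestSubunitMass:
    def test_light_plus_one_drug(self, assembly):
        assert subunit_mass(["L1"], 1, 0, assembly) == pytest.approx(LIGHT_PLUS_1, abs=0.05)

    def test_heavy_g0f_plus_three_drugs(self, assembly):
        assert subunit_mass(["H1"], 3, 0, assembly, glycoform="G0F") == pytest.approx(
            HEAVY_G0F_PLUS_3, abs=0.05
        )

    def test_bare_light_chain_is_base_mass(self, assembly):
        assert subunit_mass(["L1"], 0, 0, assembly) == assembly.chains["L1"].reduced_average_mass

    def test_glycoform_on_light_chain_rejected(self, assembly):
        with pytest.raises(ValueError, match="light"):
            subunit_mass(["L1"], 0, 0, assembly, glycoform={"L1": "G0F"})
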