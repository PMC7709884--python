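"""Chemistry layer: compositions, exchange-site counting, isotope engine.

The convolution engine is checked against two independent oracles: exhaustive
isotopologue enumeration (exact for small formulas) and pyteomics peptide
masses.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pt_mass

from maldihdx import (
    ElementalComposition,
    PeptideFragment,
    basis_envelopes,
    composition_from_sequence,
    count_exchange_sites,
    deuterated_envelope,
    natural_isotopic_distribution,
)
from maldihdx.chem import (
    DEUTERIUM_MASS_SHIFT,
    ISOTOPES,
    PROTON_MASS,
    peptide_base_envelope,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def enumerate_isotopologues(composition: dict[str, int]) -> dict[int, tuple[float, float]]:
    """Exact envelope by brute-force enumeration over every atom's isotope.

    Returns {neutron offset: (probability, weighted-mean mass)}; feasible for
    formulas of up to ~8 atoms and exact up to float rounding.
    """
    atoms: list[list[tuple[int, float, float]]] = []
    for el, n in composition.items():
        atoms.extend([ISOTOPES[el]] * n)
    acc: dict[int, tuple[float, float]] = {}
    for combo in itertools.product(*atoms):
        off = sum(c[0] for c in combo)
        mass = sum(c[1] for c in combo)
        p = 1.0
        for c in combo:
            p *= c[2]
        p0, w0 = acc.get(off, (0.0, 0.0))
        acc[off] = (p0 + p, w0 + p * mass)
    return {k: (p, w / p) for k, (p, w) in acc.items()}


class TestComposition:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("GG", ElementalComposition(C=4, H=8, N=2, O=3)),
            ("G", ElementalComposition(C=2, H=5, N=1, O=2)),  # free glycine
        ],
    )
    def test_known_formulas(self, seq, expected):
        assert composition_from_sequence(PeptideFragment(seq)) == expected

    def test_gg_monoisotopic_mass(self):
        comp = composition_from_sequence(PeptideFragment("GG"))
        assert comp.monoisotopic_mass == pytest.approx(132.0535, abs=1e-4)

    @pytest.mark.parametrize("seq", ["FERRIGQPTLL", "DRVYIHPF", "GPMSTEKLKHHKIIF"])
    def test_protonated_mass_matches_pyteomics(self, seq):
        """[M+H]+ monoisotopic mass agrees with an independent calculator."""
        comp = composition_from_sequence(PeptideFragment(seq))
        ours = comp.monoisotopic_mass + PROTON_MASS
        theirs = pt_mass.calculate_mass(sequence=seq, charge=1)
        assert ours == pytest.approx(theirs, abs=1e-4)

    def test_unknown_residue_names_offender(self):
        with pytest.raises(ValueError, match=r"'B' at position 3"):
            PeptideFragment("GGBG")

    def test_range_must_match_length(self):
        with pytest.raises(ValueError, match="range"):
            PeptideFragment("GGG", range_start=1, range_end=5)


class TestExchangeSites:
    @pytest.mark.parametrize(
        "seq, n_amide",
        [
            ("DRVYIHPF", 6),  # angiotensin II: 7 bonds, one internal Pro
            ("FERRIGQPTLL", 9),  # deuterium incorporations 0..9
            ("A", 0),  # a single residue has no peptide bond
            ("PGGG", 3),  # N-terminal proline does not subtract
            ("GPGP", 1),
        ],
    )
    def test_amide_counts(self, seq, n_amide):
        assert count_exchange_sites(PeptideFragment(seq)).n_amide == n_amide

    def test_hydrogen_partition_is_exhaustive(self):
        frag = PeptideFragment("DRVYIHPF")
        sites = count_exchange_sites(frag)
        comp = composition_from_sequence(frag)
        assert sites.n_amide + sites.n_side + sites.n_fixed == comp.H

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40))
    def test_amide_rule_property(self, seq):
        """n_amide = L - 1 - internal prolines, for arbitrary sequences."""
        frag = PeptideFragment(seq)
        sites = count_exchange_sites(frag)
        expected = len(seq) - 1 - seq[1:].count("P")
        assert sites.n_amide == expected
        comp = composition_from_sequence(frag)
        assert sites.n_amide + sites.n_side + sites.n_fixed == comp.H


class TestNaturalDistribution:
    def test_single_carbon(self):
        env = natural_isotopic_distribution(ElementalComposition(C=1, H=0, N=0, O=0))
        assert env.mz == pytest.approx([12.0, 13.0034], abs=1e-4)
        assert env.abundance == pytest.approx([0.9893, 0.0107], abs=1e-12)

    def test_c100_monoisotopic_fraction_closed_form(self):
        env = natural_isotopic_distribution(
            ElementalComposition(C=100, H=0, N=0, O=0), prune_threshold=1e-6
        )
        assert env.abundance[0] == pytest.approx(0.9893**100, rel=1e-5)

    def test_normalized_and_lightest_first(self, angiotensin):
        comp = composition_from_sequence(angiotensin)
        env = natural_isotopic_distribution(comp)
        assert env.abundance.sum() == pytest.approx(1.0, abs=1e-9)
        assert env.mz[0] == pytest.approx(comp.monoisotopic_mass, abs=1e-6)
        assert np.all(np.diff(env.mz) > 0.99) and np.all(np.diff(env.mz) < 1.01)

    @pytest.mark.parametrize(
        "comp",
        [
            {"C": 3, "H": 2, "O": 2, "N": 1},
            {"C": 2, "S": 2, "H": 3},
            {"O": 4, "N": 4},
        ],
        ids=lambda c: "".join(f"{k}{v}" for k, v in c.items()),
    )
    def test_matches_exhaustive_enumeration(self, comp):
        """Convolution equals brute-force isotopologue enumeration."""
        full = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0} | comp
        env = natural_isotopic_distribution(
            ElementalComposition(**full), prune_threshold=0.0
        )
        oracle = enumerate_isotopologues(comp)
        total = sum(p for p, _ in oracle.values())
        for nom, mz, ab in zip(env.nominal, env.mz, env.abundance):
            p_ref, m_ref = oracle[int(nom)]
            assert ab == pytest.approx(p_ref / total, abs=1e-10)
            assert mz == pytest.approx(m_ref, abs=1e-6)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            natural_isotopic_distribution(ElementalComposition(C=0, H=0, N=0, O=0))


class TestDeuteratedEnvelopes:
    def test_k0_without_side_chains_is_base(self):
        frag = PeptideFragment("GAGA")  # no labile side chains beyond termini
        sites = count_exchange_sites(frag)
        base = peptide_base_envelope(frag, sites)
        sites0 = type(sites)(n_amide=sites.n_amide, n_side=0, n_fixed=sites.n_fixed)
        env = deuterated_envelope(base, 0, sites0, 0.9)
        np.testing.assert_allclose(env.mz, base.mz, atol=1e-12)
        np.testing.assert_allclose(env.abundance, base.abundance, atol=1e-12)

    def test_centroid_shift_is_k_deuterium_masses(self, angiotensin):
        sites = count_exchange_sites(angiotensin)
        base = peptide_base_envelope(angiotensin, sites)
        c0 = deuterated_envelope(base, 0, sites, 0.9).centroid
        for k in range(1, sites.n_amide + 1):
            ck = deuterated_envelope(base, k, sites, 0.9).centroid
            assert ck - c0 == pytest.approx(k * DEUTERIUM_MASS_SHIFT, abs=1e-6)

    def test_single_side_chain_site_is_two_point_mixture(self):
        frag = PeptideFragment("GAGA")
        sites_real = count_exchange_sites(frag)
        base = peptide_base_envelope(
            frag, type(sites_real)(sites_real.n_amide, 1, sites_real.n_fixed + 2)
        )
        one_site = type(sites_real)(n_amide=sites_real.n_amide, n_side=1, n_fixed=0)
        env = deuterated_envelope(base, 0, one_site, 0.9, prune_threshold=0.0)
        # first bin: only the all-light base peak with a protium side chain
        h_mass = ISOTOPES["H"][0][1]
        assert env.mz[0] == pytest.approx(base.mz[0] + h_mass, abs=1e-9)
        assert env.abundance[0] == pytest.approx(0.1 * base.abundance[0], rel=1e-9)

    def test_k_out_of_range_rejected(self, angiotensin):
        sites = count_exchange_sites(angiotensin)
        base = peptide_base_envelope(angiotensin, sites)
        with pytest.raises(ValueError, match="k_amide_D"):
            deuterated_envelope(base, sites.n_amide + 1, sites, 0.9)

    def test_solvent_fraction_monotone_in_centroid(self, angiotensin):
        sites = count_exchange_sites(angiotensin)
        base = peptide_base_envelope(angiotensin, sites)
        cents = [
            deuterated_envelope(base, 3, sites, fd).centroid
            for fd in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert np.all(np.diff(cents) > 0)


class TestBasis:
    def test_count_and_common_grid(self, angiotensin_basis):
        assert len(angiotensin_basis) == 7
        grid = angiotensin_basis[0].mz
        for env in angiotensin_basis[1:]:
            np.testing.assert_array_equal(env.mz, grid)
            assert env.abundance.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(grid) > 0.99) and np.all(np.diff(grid) < 1.01)

    def test_ten_envelopes_for_nine_amides(self, ak1_107_117):
        assert len(basis_envelopes(ak1_107_117)) == 10

    def test_zero_amide_peptide_single_component(self):
        basis = basis_envelopes(PeptideFragment("A"))
        assert len(basis) == 1
        assert basis[0].abundance.sum() == pytest.approx(1.0, abs=1e-9)
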