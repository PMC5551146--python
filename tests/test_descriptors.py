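"""Descriptor panel: hand-summed oracles, invariants, fixture coverage."""

import pytest
from rdkit import Chem

from boiledegg import compute_descriptors, load_measured_fa, load_oxon_pairs
from boiledegg.descriptors import (
    compute_counts,
    compute_mean_atomic_props,
    compute_mw_mr,
    compute_tpsa,
    compute_wlogp,
)

# Wildman-Crippen published atomic contributions used for hand-sums:
#   C1 sp3 C (no het neighbours) 0.1441 / MR 2.503
#   C18 aromatic CH carbon       0.1581 / MR 3.350
#   H1 hydrocarbon hydrogen      0.1230 / MR 1.057
WC_C1, WC_C18, WC_H1 = 0.1441, 0.1581, 0.1230
MR_C18, MR_H1 = 3.350, 1.057


def test_wlogp_methane_is_single_atom_sum():
    assert compute_wlogp("C") == pytest.approx(WC_C1 + 4 * WC_H1, abs=1e-4)


def test_wlogp_and_mr_benzene_hand_sum():
    """Six aromatic CH carbons + six hydrocarbon hydrogens, summed by hand
    from the published contribution table."""
    assert compute_wlogp("c1ccccc1") == pytest.approx(6 * (WC_C18 + WC_H1), abs=1e-4)
    _, mr = compute_mw_mr("c1ccccc1")
    assert mr == pytest.approx(6 * (MR_C18 + MR_H1), abs=1e-3)


@pytest.mark.parametrize(
    "smiles,expected",
    [
        ("c1ccccc1", 0.0),            # no polar atoms
        ("CCO", 20.23),               # single hydroxyl fragment (Ertl table)
        ("CCOCC", 9.23),              # ether oxygen
        ("CC(=O)OC", 26.30),          # ester = carbonyl O + ether O
    ],
)
def test_tpsa_fragment_lookup(smiles, expected):
    assert compute_tpsa(smiles) == pytest.approx(expected, abs=0.01)


def test_tpsa_sp_flag_only_affects_sp_molecules():
    # thiophosphoryl head: S/P contributions dominate when included
    thio = "CCOP(=S)(OCC)OCC"
    assert compute_tpsa(thio, include_sp=True) > compute_tpsa(thio, include_sp=False)
    assert compute_tpsa("CCO", include_sp=True) == compute_tpsa("CCO", include_sp=False)


def test_tpsa_zero_for_fully_halogenated_hydrocarbons():
    # the highly lipophilic non-polar organochlorine regime
    for smiles in ("ClC1C(Cl)C(Cl)C(Cl)C(Cl)C1Cl", "Clc1ccc(C(c2ccc(Cl)cc2)C(Cl)(Cl)Cl)cc1"):
        assert compute_tpsa(smiles) == 0.0


def test_counts_ethanol_butane_benzene():
    e = compute_counts("CCO")
    assert (e["n_hbd"], e["n_hba"], e["n_NO"]) == (1, 1, 1)
    assert e["frac_csp3"] == pytest.approx(1.0)
    assert compute_counts("CCCC")["n_rotatable"] == 1  # terminal bonds excluded
    b = compute_counts("c1ccccc1")
    assert b["n_aromatic_heavy"] == 6 and b["frac_csp3"] == 0.0


def test_counts_amide_bond_not_rotatable():
    assert compute_counts("CC(=O)NC")["n_rotatable"] == 0


def test_frac_csp3_defined_zero_without_carbon():
    assert compute_counts("O=S(=O)(O)O")["frac_csp3"] == 0.0


@pytest.mark.parametrize("smiles,mw", [("C", 16.04), ("O", 18.02)])
def test_mw_from_atomic_masses(smiles, mw):
    assert compute_mw_mr(smiles)[0] == pytest.approx(mw, abs=0.01)


def test_mean_atomic_props_two_element_mean():
    # methane: mean over 1 C and 4 H of the carbon-scaled constants
    mv, mp = compute_mean_atomic_props("C")
    assert mv == pytest.approx((1.0 + 4 * 0.299) / 5)
    assert mp == pytest.approx((1.0 + 4 * 0.379) / 5)


def test_mean_atomic_props_scaling_identity():
    # any all-carbon skeleton without hydrogens averages to exactly 1
    for smiles in ("[C]", "[C]1[C][C]1"):
        mv, mp = compute_mean_atomic_props(smiles)
        assert mv == 1.0 and mp == 1.0


def test_mean_atomic_props_brute_force_ethanol():
    mv, mp = compute_mean_atomic_props("CCO")
    # C2H6O recomputed by hand from the same constant table
    assert mv == pytest.approx((2 * 1.0 + 6 * 0.299 + 0.512) / 9)
    assert mp == pytest.approx((2 * 1.0 + 6 * 0.379 + 0.456) / 9)


@pytest.mark.parametrize("prop", ["wlogp", "tpsa", "mw", "molar_refractivity"])
def test_additivity_over_disconnected_fragments(prop):
    """Atom/fragment-additive descriptors sum over disconnected unions
    (checked before the largest-fragment policy is applied)."""
    one = compute_descriptors("CC(=O)Oc1ccccc1", with_mean_atomic=False)
    two = compute_descriptors("CCO", with_mean_atomic=False)
    both = compute_descriptors("CC(=O)Oc1ccccc1.CCO", with_mean_atomic=False)
    assert getattr(both, prop) == pytest.approx(getattr(one, prop) + getattr(two, prop), abs=1e-6)


def test_ch2_homologation_monotonicity():
    prev = compute_descriptors("CCC", with_mean_atomic=False)
    cur = compute_descriptors("CCCC", with_mean_atomic=False)
    assert cur.mw - prev.mw == pytest.approx(14.03, abs=0.01)
    assert cur.tpsa == prev.tpsa == 0.0
    assert cur.wlogp > prev.wlogp


@pytest.mark.parametrize(
    "aromatic,kekule",
    [
        ("c1ccccc1", "C1=CC=CC=C1"),
        ("Cc1ccccc1", "CC1=CC=CC=C1"),
        ("c1ccncc1", "C1=CC=NC=C1"),
        ("COP(=S)(OC)Oc1ccc([N+](=O)[O-])cc1", "COP(=S)(OC)OC1=CC=C([N+](=O)[O-])C=C1"),
    ],
)
def test_canonicalization_invariance(aromatic, kekule):
    """Kekulé and aromatic SMILES of the same molecule give identical panels."""
    assert compute_descriptors(aromatic) == compute_descriptors(kekule)


def test_panel_computable_for_every_fixture_compound():
    for table in (load_oxon_pairs(), load_measured_fa()[0]):
        for c in table:
            d = compute_descriptors(c.mol())  # dataclass invariants assert internally
            assert d.mw > 0 and d.n_heavy >= d.n_aromatic_heavy
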