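"""Condensed Fukui functions: full-table reproduction and properties."""

import numpy as np
import pytest

from cdftscreen import ChargeStateTriplet, cdd, fukui_from_charges, fukui_table, top_k_sites
from cdftscreen.synthetic import SyntheticSpec, gen_molecule, round_to_printed

PRINTED_CELL_TOL = 0.002  # charges printed to 3 dp feed each difference


def test_fukui_from_charges_anchor_rows():
    o3 = ChargeStateTriplet(atom_index=3, element="O",
                            q_neutral=-0.237, q_anion=-0.339, q_cation=-0.211)
    fm, fp, f0 = fukui_from_charges(o3)
    assert fm == pytest.approx(0.026, abs=1e-12)
    assert fp == pytest.approx(0.102, abs=1e-12)
    assert f0 == pytest.approx(0.064, abs=1e-12)
    assert cdd(fp, fm) == pytest.approx(0.076, abs=1e-12)

    n4 = ChargeStateTriplet(atom_index=4, element="N",
                            q_neutral=-0.104, q_anion=-0.106, q_cation=0.070)
    fm, fp, _ = fukui_from_charges(n4)
    assert fm == pytest.approx(0.174, abs=1e-12)
    assert fp == pytest.approx(0.002, abs=1e-12)  # published cell rounds to 0.001
    assert cdd(fp, fm) == pytest.approx(-0.172, abs=0.002)


def test_identical_charges_give_zero_indices():
    t = ChargeStateTriplet(atom_index=1, element="C",
                           q_neutral=0.1, q_anion=0.1, q_cation=0.1)
    assert fukui_from_charges(t) == (0.0, 0.0, 0.0)


@pytest.mark.parametrize("name", ["genistein", "hyoscyamine"])
def test_full_published_table_reproduction(bundle, name):
    """Every published f-, f+, f0 and CDD cell is reproduced from the charge
    columns within the 3-dp printing tolerance."""
    table = fukui_table(bundle.parents_apfd[name]).frame.set_index("atom_index")
    reported = bundle.reported["fukui"][name].set_index("atom_index")
    for col in ("f_minus", "f_plus", "f_zero", "cdd"):
        deviation = (table[col] - reported[col]).abs().max()
        assert deviation <= PRINTED_CELL_TOL + 1e-9, (name, col, deviation)


def test_site_classification_matches_discussed_sites(bundle):
    gen = fukui_table(bundle.parents_apfd["genistein"], tau=0.05)
    assert set(gen.sites("nucleophilic_site")) == {3, 9, 12}
    hyo = fukui_table(bundle.parents_apfd["hyoscyamine"], tau=0.05)
    assert hyo.sites("electrophilic_site") == [4]
    assert set(hyo.sites("nucleophilic_site")) == {39, 42}


def test_infinite_tau_flags_nothing(bundle):
    table = fukui_table(bundle.parents_apfd["genistein"], tau=float("inf"))
    assert (table.frame["site"] == "none").all()


def test_empty_charge_list_is_an_input_error(bundle):
    record = bundle.parents_apfd["genistein"].model_copy(update={"charges": []})
    with pytest.raises(ValueError, match="charges"):
        fukui_table(record)


def test_top_k_sites_ordering(bundle):
    gen = fukui_table(bundle.parents_apfd["genistein"])
    assert top_k_sites(gen, "cdd", 1) == [9]  # largest |CDD| in the table
    all_atoms = top_k_sites(gen, "cdd", 30)
    assert sorted(all_atoms) == list(range(1, 31))
    # k beyond the atom count truncates
    assert top_k_sites(gen, "f_plus", 99) == top_k_sites(gen, "f_plus", 30)


def test_top_k_unit_profile_ranks_designated_atom_first():
    n = 6
    profile = [0.0] * n
    profile[2] = 1.0
    record, _ = gen_molecule(SyntheticSpec(seed=3, n_atoms=n, fukui_minus=profile))
    table = fukui_table(record)
    assert top_k_sites(table, "f_minus", 1) == [3]
    assert np.allclose(table.frame["f_minus"], profile, atol=1e-12)


@pytest.mark.parametrize("seed", range(8))
def test_normalization_exact_on_synthetic_data(seed):
    """Sum f- = sum f+ = 1 and sum CDD = 0 at machine precision."""
    record, truth = gen_molecule(SyntheticSpec(seed=seed, n_atoms=25))
    frame = fukui_table(record).frame
    assert frame["f_minus"].sum() == pytest.approx(1.0, abs=1e-12)
    assert frame["f_plus"].sum() == pytest.approx(1.0, abs=1e-12)
    assert frame["cdd"].sum() == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(frame["f_minus"], truth.fukui_minus, atol=1e-12)
    assert np.allclose(frame["f_plus"], truth.fukui_plus, atol=1e-12)


def test_published_tables_normalization_within_rounding(bundle):
    gen = fukui_table(bundle.parents_apfd["genistein"]).frame
    assert gen["f_minus"].sum() == pytest.approx(1.0, abs=0.02)
    assert gen["f_plus"].sum() == pytest.approx(1.0, abs=0.02)
    hyo = fukui_table(bundle.parents_apfd["hyoscyamine"]).frame
    assert hyo["f_minus"].sum() == pytest.approx(1.0, abs=0.02)
    # the published anion column sums to -0.910, so f+ inherits the defect


def test_charge_and_population_conventions_agree():
    """With populations p = Z - q, population differences p(N)-p(N-1) and
    p(N+1)-p(N) equal the charge-difference f- and f+."""
    record, _ = gen_molecule(SyntheticSpec(seed=11, n_atoms=12))
    z = {"H": 1, "C": 6, "N": 7, "O": 8}
    for triplet in record.charges:
        fm, fp, _ = fukui_from_charges(triplet)
        zk = z[triplet.element]
        p_n = zk - triplet.q_neutral
        p_anion = zk - triplet.q_anion
        p_cation = zk - triplet.q_cation
        assert p_n - p_cation == pytest.approx(fm, abs=1e-12)
        assert p_anion - p_n == pytest.approx(fp, abs=1e-12)


def test_rounded_generator_output_stays_within_tolerance_policy():
    """After 3-dp table-style rounding, per-atom CDD moves by <= 0.002."""
    record, truth = gen_molecule(SyntheticSpec(seed=5, n_atoms=20))
    exact = fukui_table(record).frame
    rounded = fukui_table(round_to_printed(record, 3)).frame
    assert (exact["cdd"] - rounded["cdd"]).abs().max() <= 0.002 + 1e-12


def test_round_to_printed_rule():
    record, _ = gen_molecule(SyntheticSpec(seed=2, n_atoms=3))
    record = record.model_copy(update={"e_neutral": -0.1735})
    assert round_to_printed(record, 3).e_neutral == pytest.approx(-0.174)
    assert round_to_printed(record, 12).e_neutral == pytest.approx(-0.1735)
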