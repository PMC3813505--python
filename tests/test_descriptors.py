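"""Native descriptors: hand-counted panel, surface sampling, derived indices."""

import math

import numpy as np
import pytest
from rdkit import Chem

from conftest import make_3d_record, methane_record
from chemprof.chemio import MoleculeRecord
from chemprof.descriptors import (
    VDW_RADII, cohesion_index, compute_2d_descriptors, compute_sasa,
    globularity, largest_fragment, merge_descriptors, shrake_rupley,
)
from chemprof.synthdata import HAND_COUNTS, STRUCTURE_FIXTURES
from chemprof.vector import DescriptorVector


def record_from_smiles(smiles, rid="r"):
    return MoleculeRecord(record_id=rid, title=rid, mol=Chem.MolFromSmiles(smiles))


SMILES = dict(STRUCTURE_FIXTURES)


@pytest.mark.parametrize("name", sorted(HAND_COUNTS))
def test_integer_descriptors_match_hand_counts(name):
    """Counts are integers, so agreement with the hand-derived panel is exact."""
    dv = compute_2d_descriptors(record_from_smiles(SMILES[name], name))
    for desc, expected in HAND_COUNTS[name].items():
        assert dv[desc] == expected, f"{name}.{desc}"


def test_water_molar_weight():
    dv = compute_2d_descriptors(record_from_smiles("O", "water"))
    assert dv["MW"] == pytest.approx(18.02, abs=0.01)


def test_all_native_descriptors_flagged_native():
    dv = compute_2d_descriptors(record_from_smiles("CCO"))
    assert set(dv.provenance.values()) == {"native"}


def test_mw_additive_over_disconnected_fragments():
    a = compute_2d_descriptors(record_from_smiles("CCO"))["MW"]
    b = compute_2d_descriptors(record_from_smiles("c1ccccc1"))["MW"]
    mol = Chem.MolFromSmiles("CCO.c1ccccc1")
    from rdkit.Chem import Descriptors as RD

    assert RD.MolWt(mol) == pytest.approx(a + b, abs=1e-6)


def test_largest_fragment_selected_for_salts():
    dv = compute_2d_descriptors(record_from_smiles("c1ccccc1C(=O)[O-].[Na+]"))
    assert dv["NCC"] == 7  # sodium dropped, benzoate kept


def test_unparseable_valence_yields_all_missing():
    mol = Chem.MolFromSmiles("O=C(O)F", sanitize=True)
    bad = Chem.RWMol(mol)
    bad.GetAtomWithIdx(3).SetFormalCharge(0)
    bad.GetAtomWithIdx(3).SetNumExplicitHs(5)  # pentavalent fluorine
    rec = MoleculeRecord(record_id="bad", mol=bad.GetMol())
    dv = compute_2d_descriptors(rec)
    assert len(dv) == 0


def test_perception_mode_differs_where_expected():
    # an amide nitrogen is N+O-counted but not acceptor-perceived
    rec = record_from_smiles("CC(N)=O")
    lip = compute_2d_descriptors(rec, hb_mode="lipinski")
    per = compute_2d_descriptors(rec, hb_mode="perception")
    assert lip["HBA"] == 2
    assert per["HBA"] < lip["HBA"]


# ---------------------------------------------------------------------------
# surface family


def test_single_atom_sasa_closed_form():
    rho = VDW_RADII["C"]
    areas = shrake_rupley(np.zeros((1, 3)), np.array([rho]))
    assert areas[0] == pytest.approx(4 * math.pi * (rho + 1.4) ** 2, rel=1e-12)


def test_fully_overlapping_atoms_match_single_atom():
    rho = VDW_RADII["O"]
    one = shrake_rupley(np.zeros((1, 3)), np.array([rho])).sum()
    two = shrake_rupley(np.zeros((2, 3)), np.array([rho, rho]))
    assert two.sum() == pytest.approx(one, rel=1e-12)


def _mc_sasa_oracle(coords, radii, probe=1.4, n_points=10_000, seed=20240901):
    """Independent Monte-Carlo estimate: seeded random directions per atom."""
    rng = np.random.default_rng(seed)
    inflated = radii + probe
    total = 0.0
    for i in range(len(coords)):
        v = rng.standard_normal((n_points, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + inflated[i] * v
        ok = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j != i:
                ok &= ((pts - coords[j]) ** 2).sum(axis=1) > inflated[j] ** 2
        total += ok.mean() * 4 * math.pi * inflated[i] ** 2
    return total


def test_methane_sasa_matches_independent_oracle():
    rec = methane_record()
    dv = compute_sasa(rec)
    coords = np.array(
        [list(rec.mol.GetConformer().GetAtomPosition(i)) for i in range(5)]
    )
    radii = np.array([VDW_RADII[a.GetSymbol()] for a in rec.mol.GetAtoms()])
    oracle = _mc_sasa_oracle(coords, radii)
    assert dv["SASA_total"] == pytest.approx(oracle, rel=0.01)
    # methane is all carbon/CH hydrogen: hydrophobic surface is total surface
    assert dv["FOSA"] == pytest.approx(dv["SASA_total"], rel=1e-12)


def test_sasa_missing_without_coordinates():
    dv = compute_sasa(record_from_smiles("CCO"))
    assert len(dv) == 0


def test_fosa_never_exceeds_sasa_and_volume_positive():
    for smiles in ("CCO", "c1ccncc1", "CC(=O)O"):
        dv = compute_sasa(make_3d_record(smiles))
        assert 0 <= dv["FOSA"] <= dv["SASA_total"]
        assert dv["V_mol"] > 0
        # molecules are convex-ish blobs at this size: Glob below 1 + tolerance
        assert globularity(dv["SASA_total"], dv["V_mol"]) <= 1.05


def test_methane_volume_reasonable():
    # a single inflated carbon sphere has V = 4/3 pi (1.7+1.4)^3 ~ 125 A^3;
    # methane with its H shell is slightly larger, well under double
    dv = compute_sasa(methane_record())
    lone = 4.0 / 3.0 * math.pi * (VDW_RADII["C"] + 1.4) ** 3
    assert lone < dv["V_mol"] < 2 * lone


# ---------------------------------------------------------------------------
# derived indices


def test_globularity_of_sphere_is_one():
    for r in (1.0, 3.3, 10.0):
        v = 4.0 / 3.0 * math.pi * r**3
        s = 4.0 * math.pi * r**2
        assert globularity(s, v) == pytest.approx(1.0, rel=1e-12)


def test_globularity_library_mean_value():
    assert globularity(674.0, 1265.0) == pytest.approx(0.839, abs=0.002)


def test_globularity_inverse_in_sasa():
    g1 = globularity(500.0, 1000.0)
    g2 = globularity(1000.0, 1000.0)
    assert g2 == pytest.approx(g1 / 2.0, rel=1e-12)


def test_globularity_missing_for_nonpositive():
    assert globularity(0.0, 100.0) is None
    assert globularity(100.0, -1.0) is None


def test_cohesion_index_hand_values():
    assert cohesion_index(4, 4, 400.0) == pytest.approx(0.02, rel=1e-12)
    assert cohesion_index(10, 0, 500.0) == 0.0
    # a typical drug-like vector lands inside the 0.0-0.05 compliance band
    assert 0.0 <= cohesion_index(5, 2, 600.0) <= 0.05


# ---------------------------------------------------------------------------
# merging


def _vec(provenance, **values):
    dv = DescriptorVector()
    for k, v in values.items():
        dv.set(k, v, provenance)
    return dv


def test_merge_policy_selection():
    native = _vec("native", MW=406.2)
    imported = _vec("imported", MW=406.0)
    assert merge_descriptors(native, imported, "prefer_imported")["MW"] == 406.0
    assert merge_descriptors(native, imported, "prefer_native")["MW"] == 406.2


def test_merge_keeps_single_source_values():
    native = _vec("native", TPSA=63.6)
    merged = merge_descriptors(native, DescriptorVector(), "prefer_imported")
    assert merged["TPSA"] == 63.6
    assert merged.provenance["TPSA"] == "native"


def test_merge_conflict_warning(caplog):
    native = _vec("native", MW=300.0)
    imported = _vec("imported", MW=400.0)
    with caplog.at_level("WARNING", logger="chemprof.vector"):
        merged = merge_descriptors(native, imported, "prefer_imported")
    assert merged["MW"] == 400.0
    assert any("conflict" in r.message for r in caplog.records)


def test_merge_close_values_silent(caplog):
    with caplog.at_level("WARNING", logger="chemprof.vector"):
        merge_descriptors(_vec("native", MW=406.2), _vec("imported", MW=406.0),
                          "prefer_imported")
    assert not caplog.records


def test_merge_unknown_policy():
    with pytest.raises(ValueError):
        merge_descriptors(DescriptorVector(), DescriptorVector(), "prefer_best")
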