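import numpy as np
import pandas as pd
import pytest

from coevcontact import (
    StructureModel,
    fnat,
    interface_rmsd,
    make_toy_structure,
    pair_distances,
    precision_curve,
    protein_pair_in_contact,
    read_pdb,
    write_pdb,
)
from coevcontact.evaluation import EvaluationError, Residue, kabsch


def two_residue_structure(d):
    """One residue per chain, CB atoms exactly d apart."""
    return StructureModel({
        "A": {1: Residue("A", {"CA": np.zeros(3), "CB": np.array([0.0, 1.5, 0.0])})},
        "B": {1: Residue("A", {"CA": np.array([0.0, 1.5 + d + 1.5, 0.0]),
                               "CB": np.array([0.0, 1.5 + d, 0.0])})},
    })


def rigid_motion(s, angle=0.7, axis=(0.3, 0.5, 0.81), shift=(5.0, -3.0, 2.0)):
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(angle * np.asarray(axis) / np.linalg.norm(axis)).as_matrix()
    return s.transformed(R, np.asarray(shift))


class TestPairDistances:
    def test_constructed_distance(self):
        s = two_residue_structure(7.3)
        t = pair_distances(s, "A", "B")
        assert t.d_sc_min.iloc[0] == pytest.approx(7.3)

    def test_coincident_atoms_give_zero(self):
        s = two_residue_structure(0.0)
        assert pair_distances(s, "A", "B").d_sc_min.iloc[0] == pytest.approx(0.0)

    def test_missing_side_chain_is_nan(self):
        s = StructureModel({
            "A": {1: Residue("A", {"CA": np.zeros(3)})},  # no CB
            "B": {1: Residue("A", {"CA": np.array([5.0, 0, 0]),
                                   "CB": np.array([5.0, 1.5, 0])})},
        })
        t = pair_distances(s, "A", "B")
        assert np.isnan(t.d_sc_min.iloc[0])
        assert np.isnan(t.d_cb.iloc[0])
        assert t.d_ca.iloc[0] == pytest.approx(5.0)

    def test_glycine_side_chain_is_calpha(self):
        s = StructureModel({
            "A": {1: Residue("G", {"CA": np.zeros(3)})},
            "B": {1: Residue("A", {"CA": np.array([4.0, 0, 0]),
                                   "CB": np.array([4.0, 1.0, 0])})},
        })
        t = pair_distances(s, "A", "B")
        assert t.d_sc_min.iloc[0] == pytest.approx(np.sqrt(17))

    def test_symmetric_in_chain_order(self):
        s = make_toy_structure([(2, 3)], n_a=4, n_b=4)
        ab = pair_distances(s, "A", "B")
        ba = pair_distances(s, "B", "A")
        m1 = ab.set_index(["res_i", "res_j"]).d_sc_min
        m2 = ba.set_index(["res_j", "res_i"]).d_sc_min
        assert np.allclose(m1.sort_index().values, m2.sort_index().values)


class TestProteinPairContact:
    def test_touching_chains(self):
        s = make_toy_structure([(1, 1)], n_a=3, n_b=3)
        assert protein_pair_in_contact(s, "A", "B")

    def test_distant_chains(self):
        s = make_toy_structure([], separation=50.0, n_a=3, n_b=3)
        assert not protein_pair_in_contact(s, "A", "B")

    def test_boundary_exactly_twelve_inclusive(self):
        s = StructureModel({
            "A": {1: Residue("A", {"CA": np.zeros(3)})},
            "B": {1: Residue("A", {"CA": np.array([12.0, 0, 0])})},
        })
        assert protein_pair_in_contact(s, "A", "B", d_cut=12.0)
        s2 = StructureModel({
            "A": {1: Residue("A", {"CA": np.zeros(3)})},
            "B": {1: Residue("A", {"CA": np.array([12.0001, 0, 0])})},
        })
        assert not protein_pair_in_contact(s2, "A", "B", d_cut=12.0)


class TestPrecisionCurve:
    def test_hand_counted_fractions(self):
        scores = pd.DataFrame({
            "i_query": [1, 2, 3, 4],
            "j_query": [1, 2, 3, 4],
            "gremlin_score": [0.9, 0.9, 0.1, 0.1],
        })
        contacts = pd.DataFrame({
            "res_i": [1, 2, 3, 4],
            "res_j": [1, 2, 3, 4],
            "d_sc_min": [5.0, 30.0, 5.0, 30.0],
        })
        curve = precision_curve(scores, contacts, bins=np.array([0.0, 0.5, 1.0]))
        assert curve.n.tolist() == [2, 2]
        assert curve.fraction_contact.tolist() == [0.5, 0.5]

    def test_all_in_contact(self):
        scores = pd.DataFrame({"i_query": [1], "j_query": [1], "gremlin_score": [0.8]})
        contacts = pd.DataFrame({"res_i": [1], "res_j": [1], "d_sc_min": [3.0]})
        curve = precision_curve(scores, contacts, bins=np.array([0.5, 1.0]))
        assert curve.fraction_contact.iloc[0] == 1.0

    def test_empty_bin_reported_missing(self):
        scores = pd.DataFrame({"i_query": [1], "j_query": [1], "gremlin_score": [0.1]})
        contacts = pd.DataFrame({"res_i": [1], "res_j": [1], "d_sc_min": [3.0]})
        curve = precision_curve(scores, contacts, bins=np.array([0.0, 0.5, 1.0]))
        assert curve.n.iloc[1] == 0
        assert np.isnan(curve.fraction_contact.iloc[1])


class TestFnat:
    def test_self_is_one(self):
        s = make_toy_structure([(2, 2), (5, 5)], n_a=6, n_b=6, contact_distance=4.0)
        assert fnat(s, s) == 1.0

    def test_separated_model_is_zero(self):
        ref = make_toy_structure([(2, 2)], n_a=4, n_b=4, contact_distance=4.0)
        far = make_toy_structure([], separation=100.0, n_a=4, n_b=4)
        assert fnat(far, ref) == 0.0

    def test_single_broken_contact(self):
        ref = make_toy_structure([(1, 1)], n_a=3, n_b=3, contact_distance=4.0)
        model = make_toy_structure([(2, 1)], n_a=3, n_b=3, contact_distance=4.0)  # contact moved
        assert fnat(model, ref) == 0.0

    def test_no_reference_contacts_raises(self):
        empty = make_toy_structure([], separation=60.0, n_a=3, n_b=3)
        with pytest.raises(EvaluationError):
            fnat(empty, empty)


class TestInterfaceRMSD:
    def test_identical_structures(self):
        s = make_toy_structure([(2, 2), (3, 3)], n_a=6, n_b=6)
        assert interface_rmsd(s, s) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        s = make_toy_structure([(2, 2), (3, 3)], n_a=6, n_b=6)
        moved = rigid_motion(s)
        assert interface_rmsd(moved, s) == pytest.approx(0.0, abs=1e-6)

    def test_kabsch_matches_scipy(self, rng):
        from scipy.spatial.transform import Rotation

        P = rng.normal(0, 5, (8, 3))
        R_true = Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix()
        Q = P @ R_true.T + np.array([1.0, 2.0, 3.0]) + rng.normal(0, 0.1, (8, 3))
        R, t = kabsch(P, Q)
        rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert np.allclose(R, rot.as_matrix(), atol=1e-8)

    def test_displaced_chain_value(self):
        # displace chain B by 2 A after the interface superposition is
        # dominated by both chains equally; compare to an independent
        # least-squares computation on the same point sets
        ref = make_toy_structure([(2, 2), (3, 3), (4, 4)], n_a=6, n_b=6)
        model = StructureModel({
            "A": {k: Residue(r.name, dict(r.atoms)) for k, r in ref.chains["A"].items()},
            "B": {k: Residue(r.name, {a: xyz + np.array([0, 0, 2.0])
                                      for a, xyz in r.atoms.items()})
                  for k, r in ref.chains["B"].items()},
        })
        got = interface_rmsd(model, ref)
        # oracle: collect the same interface CA sets and superpose with scipy
        from scipy.spatial.transform import Rotation

        na, xa = ref.ca_coords("A")
        nb, xb = ref.ca_coords("B")
        d = np.linalg.norm(xa[:, None] - xb[None, :], axis=2)
        pa = xa[(d <= 12.0).any(axis=1)]
        pb = xb[(d <= 12.0).any(axis=0)]
        ref_pts = np.vstack([pa, pb])
        mod_pts = np.vstack([pa, pb + np.array([0, 0, 2.0])])
        rot, rssd = Rotation.align_vectors(
            ref_pts - ref_pts.mean(0), mod_pts - mod_pts.mean(0)
        )
        want = rssd / np.sqrt(len(ref_pts))
        assert got == pytest.approx(want, abs=1e-6)

    def test_too_few_interface_residues(self):
        far = make_toy_structure([], separation=60.0, n_a=4, n_b=4)
        with pytest.raises(EvaluationError):
            interface_rmsd(far, far)


class TestPdbIO:
    def test_roundtrip(self, tmp_path):
        s = make_toy_structure([(2, 2)], n_a=4, n_b=4)
        path = tmp_path / "toy.pdb"
        write_pdb(s, path)
        back = read_pdb(path)
        assert set(back.chains) == {"A", "B"}
        for cid in "AB":
            for num, res in s.chains[cid].items():
                for name, xyz in res.atoms.items():
                    assert np.allclose(back.chains[cid][num].atoms[name], xyz, atol=1e-3)
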