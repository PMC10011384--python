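"""Polar, apolar and interaction terms of the hydration free energy."""

import numpy as np
import pytest
from rdkit import Chem

import hydramol as hm
from hydramol.energy import surface_area
from hydramol.exceptions import ValenceError
from hydramol.io import AtomDescriptor
from hydramol.strengths import StrengthSet
from conftest import bfs_distances


def desc(index, element="O", hyb="sp3", n_l=0, n_H=0, n_LP=0, r_vdw=None):
    return AtomDescriptor(
        index=index, element=element, formal_charge=0, hyb=hyb,
        n_l=n_l, n_H=n_H, n_LP=n_LP, in_ring=False, q=0.0, r_vdw=r_vdw,
    )


class TestPolarTerm:
    def test_empty_sums(self):
        assert hm.polar_term(StrengthSet(), []) == 0.0

    def test_water_hand_value(self):
        # one O-H2 donor with sd = 1 and one acceptor with sa = 1, n_LP = 2:
        # 0.908 * 1 * 2^0.5 - 16.131 * 1 * 2^0.34 = -19.1345 kJ/mol by hand
        features = [desc(0, "O", n_H=2, n_LP=2), desc(1, "H"), desc(2, "H")]
        ss = StrengthSet(
            donor={1: 1.0, 2: 1.0}, acceptor={0: 1.0}, donor_heavy={1: 0, 2: 0}
        )
        value = hm.polar_term(ss, features)
        assert value == pytest.approx(-19.1345, abs=1e-3)

    def test_single_donor_coefficient_passthrough(self):
        features = [desc(0, "N", n_H=1)]
        ss = StrengthSet(donor={1: 1.0}, donor_heavy={1: 0})
        assert hm.polar_term(ss, features) == pytest.approx(0.908, abs=1e-12)

    def test_ch_donors_excluded_by_default_but_switchable(self):
        features = [desc(0, "C", n_H=1)]
        ss = StrengthSet(donor={1: 0.5}, donor_heavy={1: 0})
        assert hm.polar_term(ss, features) == 0.0
        assert hm.polar_term(ss, features, donor_scope="all-h") == pytest.approx(
            0.908 * 0.5, abs=1e-12
        )

    def test_donor_aggregation_mean_vs_max(self):
        features = [desc(0, "N", n_H=2)]
        ss = StrengthSet(donor={1: 0.4, 2: 0.8}, donor_heavy={1: 0, 2: 0})
        mean_val = hm.polar_term(ss, features)
        max_val = hm.polar_term(ss, features, donor_aggregation="max")
        assert mean_val == pytest.approx(0.908 * 0.6 * 2 ** 0.5, abs=1e-12)
        assert max_val == pytest.approx(0.908 * 0.8 * 2 ** 0.5, abs=1e-12)


class TestAtomicSurface:
    def test_unsubstituted_full_sphere(self):
        assert hm.atomic_surface(2.0, 0, "sp3") == pytest.approx(16 * np.pi, rel=1e-12)

    def test_quaternary_sp3_vanishes(self):
        assert hm.atomic_surface(1.7, 4, "sp3") == 0.0

    def test_sp2_hand_value(self):
        # 4 pi 1.5^2 (1 - 2/3) = 9.4248 by hand
        assert hm.atomic_surface(1.5, 2, "sp2") == pytest.approx(9.4248, abs=1e-4)

    def test_valence_error(self):
        with pytest.raises(ValenceError):
            hm.atomic_surface(1.5, 4, "sp2")

    def test_surface_bounds(self, synthetic_pool):
        for rec in synthetic_pool[:20]:
            for a in rec.atoms:
                if a.element == "H":
                    continue
                s = hm.atomic_surface(a.r_vdw, a.n_l, a.hyb)
                assert 0.0 <= s <= 4 * np.pi * a.r_vdw ** 2 + 1e-12


class TestApolarTerm:
    def test_constant_only(self):
        assert hm.apolar_term([], (0, 0, 0)) == pytest.approx(1.884, abs=1e-12)

    def test_ring_coefficient_passthrough(self):
        features = [desc(0, "C", hyb="sp3", n_l=0, r_vdw=1.7)]
        no_ring = hm.apolar_term(features, (0, 0, 0))
        one_ring = hm.apolar_term(features, (0, 0, 1))
        assert one_ring - no_ring == pytest.approx(-3.643, abs=1e-12)

    def test_single_sp3_atom_hand_value(self):
        # 1.884 + 0.0467 * 4 pi 1.7^2 = 3.580 kJ/mol by hand
        features = [desc(0, "C", hyb="sp3", n_l=0, r_vdw=1.7)]
        assert hm.apolar_term(features, (0, 0, 0)) == pytest.approx(3.580, abs=1e-3)


class TestInteractionTerm:
    @staticmethod
    def with_acceptors(smi, sa_by_element):
        rec = hm.prepare_record(hm.from_smiles(smi))
        ss = StrengthSet()
        for a in rec.atoms:
            if a.n_LP >= 1:
                ss.acceptor[a.index] = sa_by_element.get(a.element, 1.0)
        return rec, ss

    def test_single_acceptor_is_zero(self, water):
        ss = hm.molecular_strengths(water)
        assert hm.interaction_term(ss, water.atoms, water) == 0.0

    def test_two_acceptors_distance_three(self):
        # O-C-C-O: the two oxygens are three bonds apart; with sa = 1 and
        # n_LP forced to 1: g_i (1*F*1 + 1*F*1) = 4.9996 * 2 * 0.514 = 5.1396
        rec, ss = self.with_acceptors("OCCO", {"O": 1.0})
        for a in rec.atoms:
            if a.element == "O":
                a.n_LP = 1
        val = hm.interaction_term(ss, rec.atoms, rec)
        assert val == pytest.approx(5.1396, abs=1e-4)

    def test_beyond_three_bonds_zero(self):
        rec, ss = self.with_acceptors("OCCCO", {"O": 1.0})
        assert hm.interaction_term(ss, rec.atoms, rec) == 0.0

    def test_brute_force_oracle(self, synthetic_pool, calibrated_params):
        """Vectorised term equals an explicit double loop with BFS distances."""
        p = calibrated_params
        for rec in synthetic_pool:
            ss = hm.molecular_strengths(rec, p.strength)
            fast = hm.interaction_term(ss, rec.atoms, rec, p)
            acceptors = sorted(ss.acceptor)
            slow = 0.0
            for j in acceptors:
                dist = bfs_distances(rec.n_atoms, rec.bonds, j)
                a_j = ss.acceptor[j] * rec.atoms[j].n_LP ** p.exp_a
                for k in acceptors:
                    if k == j:
                        continue
                    a_k = ss.acceptor[k] * rec.atoms[k].n_LP ** p.exp_a
                    if dist[k] in (1, 2):
                        slow += a_j * a_k
                    elif dist[k] == 3:
                        slow += p.F * a_j * a_k
            slow *= p.g_i
            assert fast == pytest.approx(slow, abs=1e-9)


class TestTotalHydration:
    def test_additivity_exact(self, synthetic_pool, calibrated_params):
        for rec in synthetic_pool[:10]:
            res = hm.total_hydration(rec, calibrated_params)
            assert res.dG_total == res.dG_polar + res.dG_apolar + res.dG_interaction

    def test_water_polar_dominates(self, water, calibrated_params):
        res = hm.total_hydration(water, calibrated_params)
        assert res.dG_total < 0
        assert abs(res.dG_polar) > abs(res.dG_apolar)

    def test_atom_order_invariance(self, calibrated_params):
        rec = hm.prepare_record(hm.from_smiles("OCC(=O)NC", "amide"))
        res = hm.total_hydration(rec, calibrated_params)
        order = list(range(rec.n_atoms))
        rng = np.random.default_rng(3)
        rng.shuffle(order)
        permuted = Chem.RenumberAtoms(rec.mol, [int(i) for i in order])
        rec2 = hm.MoleculeRecord("perm", rec.smiles, permuted)
        rec2.conformer_source = "as-provided"
        hm.perceive_features(rec2)
        hm.compute_charges_radii(rec2)
        res2 = hm.total_hydration(rec2, calibrated_params)
        for attr in ("dG_polar", "dG_apolar", "dG_interaction", "dG_total", "N_s"):
            assert getattr(res2, attr) == pytest.approx(getattr(res, attr), abs=1e-9)

    def test_rigid_motion_invariance(self, calibrated_params):
        from scipy.spatial.transform import Rotation

        rec = hm.prepare_record(hm.from_smiles("CCO", "ethanol"))
        res = hm.total_hydration(rec, calibrated_params)
        rot = Rotation.from_euler("zyx", [11.0, 87.0, -40.0], degrees=True)
        new_xyz = rot.apply(rec.coordinates) + np.array([1.0, -5.0, 2.0])
        conf = rec.mol.GetConformer()
        for i, pos in enumerate(new_xyz):
            conf.SetAtomPosition(i, pos.tolist())
        hm.compute_charges_radii(rec)
        res2 = hm.total_hydration(rec, calibrated_params)
        assert res2.dG_total == pytest.approx(res.dG_total, abs=1e-7)

    def test_batch_contract_order_and_failures(self, calibrated_params):
        records = [
            hm.from_smiles("CCO", "a"),
            hm.from_smiles("c1ccccc1", "b"),
            hm.from_smiles("CCN", "c"),
        ]
        frame = hm.predict_hydration(records, calibrated_params)
        assert list(frame["id"]) == ["a", "b", "c"]
        assert (frame["error"] == "").all()
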