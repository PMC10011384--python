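"""Donor/acceptor strength equations and the shell-corrective charge."""

import numpy as np
import pytest
from rdkit import Chem

import hydramol as hm
from hydramol.exceptions import ChargesMissingError
from conftest import bfs_distances


def chain_record(n_heavy: int) -> hm.MoleculeRecord:
    """A linear all-carbon chain without hydrogens, charges settable by hand."""
    rw = Chem.RWMol()
    for _ in range(n_heavy):
        rw.AddAtom(Chem.Atom(6))
    for i in range(n_heavy - 1):
        rw.AddBond(i, i + 1, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.SanitizeMol(mol)
    rec = hm.MoleculeRecord("chain", Chem.MolToSmiles(mol), mol)
    hm.perceive_features(rec)
    return rec


def set_charges(rec, charges):
    for a, q in zip(rec.atoms, charges):
        a.q = float(q)


class TestDeltaQ:
    def test_null_charges(self):
        rec = chain_record(4)
        set_charges(rec, [0, 0, 0, 0])
        assert hm.delta_q(0, rec, T=0.274) == 0.0

    def test_single_alpha_neighbour(self):
        rec = chain_record(2)
        set_charges(rec, [0.0, 1.0])
        assert hm.delta_q(0, rec, T=0.274) == pytest.approx(0.274, abs=1e-12)

    def test_beta_minus_gamma(self):
        # no alpha charge, q(beta)=+1, q(gamma)=-1 -> T^2 - T^3
        rec = chain_record(4)
        set_charges(rec, [0.0, 0.0, 1.0, -1.0])
        expected = 0.274 ** 2 - 0.274 ** 3  # = 0.0545052 by hand
        assert hm.delta_q(0, rec, T=0.274) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0545052, abs=1e-7)

    def test_beyond_three_bonds_ignored(self):
        rec = chain_record(6)
        set_charges(rec, [0, 0, 0, 0, 5.0, -3.0])
        assert hm.delta_q(0, rec, T=0.274) == 0.0

    def test_missing_charges_raise(self):
        rec = chain_record(3)
        with pytest.raises(ChargesMissingError):
            hm.delta_q(0, rec)

    def test_brute_force_shell_oracle(self):
        """delta_q equals an explicit BFS shell enumeration on random graphs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 14))
            rw = Chem.RWMol()
            for _ in range(n):
                rw.AddAtom(Chem.Atom(6))
            degrees = [0] * n
            for i in range(1, n):
                choices = [j for j in range(i) if degrees[j] < 4]
                parent = int(rng.choice(choices))
                rw.AddBond(i, parent, Chem.BondType.SINGLE)
                degrees[i] += 1
                degrees[parent] += 1
            mol = rw.GetMol()
            mol.UpdatePropertyCache(strict=False)
            Chem.SanitizeMol(mol)
            rec = hm.MoleculeRecord("rand", "", mol)
            hm.perceive_features(rec)
            charges = rng.normal(0.0, 0.3, size=n)
            set_charges(rec, charges)
            t = float(rng.uniform(0.05, 0.9))
            for src in range(n):
                dist = bfs_distances(n, rec.bonds, src)
                expected = sum(
                    (t ** d) * charges[i]
                    for i, d in enumerate(dist)
                    if 1 <= d <= 3
                )
                assert hm.delta_q(src, rec, T=t) == pytest.approx(expected, abs=1e-12)


class TestAtomicStrengths:
    def test_water_closure(self, water, calibration):
        d, a = calibration
        params = hm.StrengthParams(D=d, A=a)
        assert hm.donor_strength(1, water, params) == pytest.approx(1.0, abs=1e-2)
        assert hm.donor_strength(2, water, params) == pytest.approx(1.0, abs=1e-2)
        assert hm.acceptor_strength(0, water, params) == pytest.approx(1.0, abs=1e-9)

    def test_donor_requires_hydrogen(self, water):
        with pytest.raises(ValueError):
            hm.donor_strength(0, water)

    def test_acceptor_requires_lone_pairs(self):
        rec = hm.prepare_record(hm.from_smiles("C"))
        with pytest.raises(ValueError):
            hm.acceptor_strength(0, rec)

    def test_zero_corrected_charge_gives_zero(self):
        rec = chain_record(2)
        set_charges(rec, [0.0, 0.0])
        rec.atoms[0].n_LP = 1  # force acceptor eligibility on the synthetic atom
        assert hm.acceptor_strength(0, rec, hm.StrengthParams()) == 0.0

    def test_linearity_in_calibration_coefficients(self, water):
        base = hm.StrengthParams(D=10.0, A=-2.0)
        double = hm.StrengthParams(D=20.0, A=-4.0)
        assert hm.donor_strength(1, water, double) == pytest.approx(
            2 * hm.donor_strength(1, water, base), rel=1e-12
        )
        assert hm.acceptor_strength(0, water, double) == pytest.approx(
            2 * hm.acceptor_strength(0, water, base), rel=1e-12
        )

    def test_locality_beyond_three_bonds(self):
        rec = hm.prepare_record(hm.from_smiles("CCCCCCO", "heptanol"))
        h_idx = next(
            a.index for a in rec.atoms
            if a.element == "H"
            and rec.mol.GetAtomWithIdx(a.index).GetNeighbors()[0].GetIdx() == 0
        )
        before = hm.donor_strength(h_idx, rec)
        far = next(
            a.index for a in rec.atoms
            if rec.distance_matrix()[h_idx][a.index] >= 4
        )
        rec.atoms[far].q += 0.5
        assert hm.donor_strength(h_idx, rec) == pytest.approx(before, abs=1e-12)

    def test_t_to_zero_limit(self, water):
        params = hm.StrengthParams(D=5.0, A=-3.0, T=1e-9)
        q = water.charges
        assert hm.donor_strength(1, water, params) == pytest.approx(5.0 * q[1], abs=1e-8)
        assert hm.acceptor_strength(0, water, params) == pytest.approx(-3.0 * q[0], abs=1e-8)


class TestMolecularStrengths:
    def test_aggregation_identity(self, synthetic_pool):
        for rec in synthetic_pool[:15]:
            ss = hm.molecular_strengths(rec)
            assert ss.sd_mol == ss.sdx_mol + ss.sdc_mol
            assert ss.sd_mol == pytest.approx(sum(ss.donor.values()), abs=1e-9)

    def test_acceptor_aggregate_weights_lone_pairs(self, water, calibrated_params):
        ss = hm.molecular_strengths(water, calibrated_params.strength)
        # one oxygen with sa = 1 and two lone pairs
        assert ss.sa_mol == pytest.approx(2.0, abs=1e-9)

    def test_every_hydrogen_and_lone_pair_atom_mapped(self, synthetic_pool):
        for rec in synthetic_pool[:15]:
            ss = hm.molecular_strengths(rec)
            h_idx = {a.index for a in rec.atoms if a.element == "H"}
            lp_idx = {a.index for a in rec.atoms if a.n_LP >= 1}
            assert set(ss.donor) == h_idx
            assert set(ss.acceptor) == lp_idx

    def test_no_donors_no_acceptors(self):
        rec = chain_record(3)
        set_charges(rec, [0.1, -0.2, 0.1])
        ss = hm.molecular_strengths(rec)
        assert ss.donor == {} and ss.acceptor == {}
        assert ss.sd_mol == ss.sa_mol == 0.0
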