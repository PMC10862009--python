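import numpy as np
import pytest

from helixgraft.energetics import (COULOMB_K, EnergyMatrix, cross_helix_energy,
                                   energy_matrix, hydrophobic_contacts,
                                   interhelix_contributors, pair_energy)
from helixgraft.forcefield import (AtomParams, ForceFieldParams,
                                   ParameterizationError, default_params)
from helixgraft.geometry import rotation_about_axis
from helixgraft.secondary_structure import add_amide_hydrogens
from helixgraft.structure_io import (AtomRecord, Ensemble, PolymerStructure,
                                     Residue, SegmentSpec)
from helixgraft.synthetic_data import (BUNDLE_ANCHORS, BUNDLE_HELIX_A,
                                       BUNDLE_HELIX_B, build_ideal_helix,
                                       build_two_helix_bundle)
from helixgraft.graft_design import mutate_to_alanine


def point_residue(res_seq, xyz, chain="A", res_name="GLY", atom="CA"):
    r = Residue(chain, res_seq, res_name)
    r.atoms.append(AtomRecord(atom, atom[0], np.asarray(xyz, dtype=float)))
    return r


def custom_params(charge=1.0, eps=0.0, rmin_half=2.0):
    return ForceFieldParams({("GLY", "CA"): AtomParams(charge, eps,
                                                       rmin_half)})


class TestPairEnergy:
    def test_two_unit_charges_at_ten_angstrom(self):
        ri = point_residue(1, [0, 0, 0])
        rj = point_residue(5, [10, 0, 0])
        coul, lj, tot = pair_energy(ri, rj, params=custom_params())
        assert coul == pytest.approx(COULOMB_K / 10.0)
        assert lj == 0.0 and tot == coul

    def test_lj_minimum_is_minus_epsilon(self):
        p = custom_params(charge=0.0, eps=0.25, rmin_half=2.0)
        ri = point_residue(1, [0, 0, 0])
        rj = point_residue(5, [4.0, 0, 0])   # r = rmin_ab
        coul, lj, tot = pair_energy(ri, rj, params=p)
        assert lj == pytest.approx(-0.25, abs=1e-12)
        assert coul == 0.0

    def test_beyond_cutoff_is_zero(self):
        ri = point_residue(1, [0, 0, 0])
        rj = point_residue(5, [12.5, 0, 0])
        assert pair_energy(ri, rj, params=custom_params()) == (0.0, 0.0, 0.0)

    def test_missing_parameter_names_atom(self):
        ri = point_residue(1, [0, 0, 0], res_name="ALA", atom="CQ")
        rj = point_residue(5, [5, 0, 0])
        with pytest.raises(ParameterizationError, match="CQ"):
            pair_energy(ri, rj)

    def test_brute_force_double_loop_oracle(self, rng):
        params = default_params()
        helix = add_amide_hydrogens(build_ideal_helix("AWLSEK"))
        residues = list(helix.residues("A"))
        for a in range(len(residues)):
            for b in range(a + 1, len(residues)):
                ri, rj = residues[a], residues[b]
                coul, lj, tot = pair_energy(ri, rj, params=params)
                # independent brute force over atom pairs
                bc = bl = 0.0
                adjacent = abs(ri.res_seq - rj.res_seq) == 1
                excl = {("C", "N"), ("CA", "N"), ("O", "N"),
                        ("C", "CA"), ("C", "H")}
                for ai in ri.atoms:
                    for aj in rj.atoms:
                        if adjacent and (ai.name, aj.name) in excl:
                            continue
                        r = float(np.linalg.norm(ai.coords - aj.coords))
                        if r > 12.0:
                            continue
                        pi = params.get(ri.res_name, ai.name)
                        pj = params.get(rj.res_name, aj.name)
                        bc += (COULOMB_K * pi.partial_charge
                               * pj.partial_charge / r)
                        eps = np.sqrt(pi.lj_epsilon * pj.lj_epsilon)
                        rmin = pi.lj_rmin_half + pj.lj_rmin_half
                        x6 = (rmin / r) ** 6
                        bl += eps * (x6 * x6 - 2 * x6)
                assert coul == pytest.approx(bc, abs=1e-9)
                assert lj == pytest.approx(bl, abs=1e-9)
                assert tot == pytest.approx(bc + bl, abs=1e-9)

    def test_coulomb_linear_in_charge(self):
        ri = point_residue(1, [0, 0, 0])
        rj = point_residue(5, [8, 0, 0])
        c1, _, _ = pair_energy(ri, rj, params=custom_params(charge=0.5))
        c2, _, _ = pair_energy(ri, rj, params=custom_params(charge=1.0))
        assert c2 == pytest.approx(4 * c1)  # both charges scale


class TestEnergyMatrix:
    def test_two_residue_reduction_matches_pair_energy(self):
        helix = build_ideal_helix("AL")
        M = energy_matrix(helix, [1, 2])
        withh = add_amide_hydrogens(helix)
        res = list(withh.residues("A"))
        coul, lj, tot = pair_energy(res[0], res[1])
        assert M.total[0, 1] == pytest.approx(tot, abs=1e-9)
        assert M.bands[0, 1] == "adjacent"

    def test_symmetry_and_component_sum(self, rng):
        helix = build_ideal_helix("AELKWQSD")
        xyz = helix.coords()
        frames = [xyz + rng.normal(0, 0.3, xyz.shape) for _ in range(3)]
        M = energy_matrix(Ensemble(helix, frames), SegmentSpec("A", 1, 8))
        np.testing.assert_allclose(M.total, M.total.T, atol=1e-6)
        off = ~np.eye(len(M.res_seqs), dtype=bool)
        np.testing.assert_allclose(M.total[off],
                                   (M.coulomb + M.lj)[off], atol=1e-9)
        assert np.isnan(np.diag(M.total)).all()

    def test_rigid_transform_invariance(self):
        helix = build_ideal_helix("AELKWQSD")
        M1 = energy_matrix(helix, SegmentSpec("A", 1, 8))
        R = rotation_about_axis(np.array([1.0, 2.0, 0.5]), 61.0)
        moved = helix.with_coords(helix.coords() @ R.T + 7.0)
        M2 = energy_matrix(moved, SegmentSpec("A", 1, 8))
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_allclose(M1.total[off], M2.total[off], atol=1e-8)

    def test_ideal_helix_band_structure(self):
        M = energy_matrix(build_ideal_helix("A" * 20),
                          SegmentSpec("A", 1, 20))
        sep = np.abs(np.subtract.outer(M.res_seqs, M.res_seqs))
        # the i,i+4 hydrogen-bonded band is labeled for interior pairs
        hbond_cells = (M.bands == "hbond_band") & (sep == 4)
        assert hbond_cells.sum() >= 20   # both triangles
        means = {b: M.band_mean(b) for b in ("adjacent", "hbond_band",
                                             "other")}
        assert means["adjacent"] < means["other"]
        assert means["hbond_band"] < means["other"]


class TestHydrophobicContacts:
    def test_distant_leucines_empty(self):
        a = point_residue(1, [0, 0, 0], res_name="LEU", atom="CB")
        b = point_residue(10, [20, 0, 0], res_name="LEU", atom="CB")
        s = PolymerStructure({"A": [a, b]})
        cm = hydrophobic_contacts(s, SegmentSpec("A", 1, 1),
                                  SegmentSpec("A", 10, 10))
        assert len(cm) == 0

    def test_polar_partner_excluded(self):
        a = point_residue(1, [0, 0, 0], res_name="LEU", atom="CB")
        b = point_residue(10, [3.8, 0, 0], res_name="SER", atom="CB")
        s = PolymerStructure({"A": [a, b]})
        cm = hydrophobic_contacts(s, SegmentSpec("A", 1, 1),
                                  SegmentSpec("A", 10, 10))
        assert len(cm) == 0

    def test_constructed_pairs_recovered(self):
        a1 = point_residue(1, [0, 0, 0], res_name="PHE", atom="CB")
        a2 = point_residue(2, [0, 8, 0], res_name="TRP", atom="CB")
        b1 = point_residue(10, [4.0, 0, 0], res_name="LEU", atom="CB")
        b2 = point_residue(11, [0, 20, 0], res_name="ILE", atom="CB")
        s = PolymerStructure({"A": [a1, a2, b1, b2]})
        cm = hydrophobic_contacts(s, SegmentSpec("A", 1, 2),
                                  SegmentSpec("A", 10, 11))
        assert [(p[0], p[1]) for p in cm.pairs] == [(1, 10)]
        assert cm.pairs[0][2] == pytest.approx(4.0)

    def test_glycine_uses_ca(self):
        a = point_residue(1, [0, 0, 0], res_name="GLY", atom="CA")
        b = point_residue(10, [3.0, 0, 0], res_name="LEU", atom="CB")
        s = PolymerStructure({"A": [a, b]})
        cm = hydrophobic_contacts(s, SegmentSpec("A", 1, 1),
                                  SegmentSpec("A", 10, 10))
        assert len(cm) == 0  # GLY is not in the hydrophobic set


def toy_matrix(total, res_seqs, chain="A"):
    total = np.asarray(total, dtype=float)
    return EnergyMatrix(chain, list(res_seqs), total, total * 0.5,
                        total * 0.5,
                        np.full(total.shape, "other", dtype="<U10"), 1)


class TestInterhelixContributors:
    def test_single_strong_cell_ranks_first(self):
        total = np.zeros((4, 4))
        total[0, 2] = total[2, 0] = -5.0
        M = toy_matrix(total, [1, 2, 11, 12])
        ranked = interhelix_contributors(M, SegmentSpec("A", 1, 2),
                                         SegmentSpec("A", 11, 12), top_k=2)
        assert ranked[0][0] in (1, 11) and ranked[0][1] == -5.0

    def test_zero_cross_block_ties_break_by_index(self):
        M = toy_matrix(np.zeros((4, 4)), [1, 2, 11, 12])
        ranked = interhelix_contributors(M, SegmentSpec("A", 1, 2),
                                         SegmentSpec("A", 11, 12), top_k=4)
        assert [r[0] for r in ranked] == [1, 2, 11, 12]
        assert all(r[1] == 0.0 for r in ranked)

    def test_overlapping_helices_rejected(self):
        M = toy_matrix(np.zeros((4, 4)), [1, 2, 3, 4])
        with pytest.raises(ValueError, match="overlap"):
            interhelix_contributors(M, SegmentSpec("A", 1, 3),
                                    SegmentSpec("A", 3, 4))

    def test_planted_aromatic_anchors_rank_top3(self, bundle):
        res = (list(range(BUNDLE_HELIX_A.start_res,
                          BUNDLE_HELIX_A.end_res + 1))
               + list(range(BUNDLE_HELIX_B.start_res,
                            BUNDLE_HELIX_B.end_res + 1)))
        M = energy_matrix(bundle, res)
        ranked = interhelix_contributors(M, BUNDLE_HELIX_A, BUNDLE_HELIX_B,
                                         top_k=3)
        assert sorted(r[0] for r in ranked) == sorted(BUNDLE_ANCHORS)

    def test_alanine_truncation_reduces_cross_energy(self, bundle):
        res = (list(range(BUNDLE_HELIX_A.start_res,
                          BUNDLE_HELIX_A.end_res + 1))
               + list(range(BUNDLE_HELIX_B.start_res,
                            BUNDLE_HELIX_B.end_res + 1)))
        wt = cross_helix_energy(energy_matrix(bundle, res),
                                BUNDLE_HELIX_A, BUNDLE_HELIX_B)
        mut = mutate_to_alanine(bundle, list(BUNDLE_ANCHORS))
        mu = cross_helix_energy(energy_matrix(mut, res),
                                BUNDLE_HELIX_A, BUNDLE_HELIX_B)
        assert wt < 0
        assert abs(mu) < abs(wt)


def test_residue_charges_sum_to_formal_charge():
    params = default_params()
    from helixgraft.forcefield import FORMAL_CHARGE, _SIDE_ATOMS
    for res in _SIDE_ATOMS:
        assert params.residue_charge(res) == pytest.approx(
            FORMAL_CHARGE.get(res, 0.0), abs=1e-3), res
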