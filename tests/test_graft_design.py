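import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helixgraft.graft_design import (ClashError, GeometryError, anchor_gap,
                                     build_chimera, build_initial_model,
                                     geometry_report, helix_span_estimate,
                                     mutate_to_alanine, recommend_linkers)
from helixgraft.structure_io import (AtomRecord, PolymerStructure, Residue,
                                     SegmentSpec, sequence_of)
from helixgraft.synthetic_data import (TOY_SCAFFOLD_LOOP, build_ideal_helix,
                                       build_toy_scaffold)


def _bead_chain(coords, chain_id="A", res_name="ALA"):
    residues = []
    for i, xyz in enumerate(coords):
        r = Residue(chain_id, i + 1, res_name)
        r.atoms.append(AtomRecord("CA", "C", np.asarray(xyz, dtype=float)))
        residues.append(r)
    return PolymerStructure({chain_id: residues})


class TestAnchorGap:
    def test_three_four_five_triangle(self):
        s = _bead_chain([(0, 0, 0), (1, 1, 1), (2, 2, 2), (3, 4, 0)])
        # loop = residues 2..3; flanks are residues 1 and 4
        assert anchor_gap(s, SegmentSpec("A", 2, 3)) == pytest.approx(5.0)

    def test_toy_scaffold_matches_direct_distance(self, toy_scaffold):
        a = toy_scaffold.get_residue("A", 46).atom("CA").coords
        b = toy_scaffold.get_residue("A", 51).atom("CA").coords
        expected = float(np.linalg.norm(b - a))
        assert anchor_gap(toy_scaffold, TOY_SCAFFOLD_LOOP) == \
            pytest.approx(expected, abs=1e-9)

    def test_loop_at_terminus_raises(self, toy_scaffold):
        with pytest.raises(GeometryError):
            anchor_gap(toy_scaffold, SegmentSpec("A", 30, 33))


class TestHelixSpan:
    @pytest.mark.parametrize("n,expected", [(1, 0.0), (20, 28.5), (35, 51.0)])
    def test_rise_times_steps(self, n, expected):
        assert helix_span_estimate(n) == pytest.approx(expected)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            helix_span_estimate(0)


class TestRecommendLinkers:
    def test_zero_mismatch_still_needs_slack(self):
        # 2n*3.5 >= 0 + 4.0  ->  n = 1
        assert recommend_linkers(10.0, 10.0) == 1

    def test_pentapeptide_for_31_angstrom_mismatch(self):
        # ceil((31+4)/7) = 5, one GGGGS per side
        assert recommend_linkers(10.0, 41.0) == 5

    def test_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            assert recommend_linkers(0.0, 100.0) == 10

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            recommend_linkers(-1.0, 5.0)

    @given(st.floats(0, 80), st.floats(0, 80))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_mismatch(self, a, b):
        lo, hi = sorted((abs(a - b), abs(a - b) + 5.0))
        assert recommend_linkers(0.0, lo) <= recommend_linkers(0.0, hi)


class TestBuildChimera:
    def test_length_arithmetic(self, toy_scaffold):
        donor = build_ideal_helix("A" * 20, chain_id="D", start_res=35)
        d = build_chimera(toy_scaffold, TOY_SCAFFOLD_LOOP, donor,
                          SegmentSpec("D", 35, 54))
        assert len(d.chimera_sequence) == 38 - 4 + 5 + 20 + 5

    def test_identity_graft_reproduces_scaffold_sequence(self, toy_scaffold):
        d = build_chimera(toy_scaffold, TOY_SCAFFOLD_LOOP, toy_scaffold,
                          TOY_SCAFFOLD_LOOP, "", "")
        assert d.chimera_sequence == sequence_of(toy_scaffold, "A")

    def test_index_map_bijection_and_donor_order(self, toy_scaffold):
        donor = build_ideal_helix("A" * 20, chain_id="D", start_res=35)
        d = build_chimera(toy_scaffold, TOY_SCAFFOLD_LOOP, donor,
                          SegmentSpec("D", 35, 54))
        positions = [e.chimera_pos for e in d.index_map]
        assert positions == list(range(1, len(d.chimera_sequence) + 1))
        donor_sources = [e.source_res_seq for e in d.index_map
                         if e.source == "donor"]
        assert donor_sources == list(range(35, 55))

    @given(st.integers(6, 30), st.integers(1, 25), st.integers(0, 8),
           st.integers(0, 8))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_length_identity_randomized(self, scaffold_len, donor_len,
                                        ln, lc):
        scaffold = build_ideal_helix("A" * scaffold_len)
        donor = build_ideal_helix("L" * donor_len, chain_id="D")
        loop = SegmentSpec("A", 3, 4)
        d = build_chimera(scaffold, loop, donor,
                          SegmentSpec("D", 1, donor_len),
                          "G" * ln, "G" * lc)
        assert len(d.chimera_sequence) == \
            scaffold_len - 2 + ln + donor_len + lc
        assert len(d.index_map) == len(d.chimera_sequence)


class TestInitialModel:
    def test_identity_graft_keeps_coordinates(self, toy_scaffold):
        d = build_chimera(toy_scaffold, TOY_SCAFFOLD_LOOP, toy_scaffold,
                          TOY_SCAFFOLD_LOOP, "", "")
        model = build_initial_model(d, toy_scaffold, toy_scaffold)
        np.testing.assert_array_equal(model.coords(), toy_scaffold.coords())

    def test_toy_graft_counts_and_no_clashes(self, toy_scaffold):
        donor = build_ideal_helix("A" * 10, chain_id="D", start_res=35)
        d = build_chimera(toy_scaffold, TOY_SCAFFOLD_LOOP, donor,
                          SegmentSpec("D", 35, 44), "GGGGS", "GGGGS")
        model = build_initial_model(d, toy_scaffold, donor)
        assert model.n_residues == len(d.chimera_sequence)
        # no heavy-atom pair of non-neighboring residues under 2.0 Å
        res_list = list(model.residues())
        for i, ri in enumerate(res_list):
            xi = np.array([a.coords for a in ri.heavy_atoms()])
            for rj in res_list[i + 2:]:
                xj = np.array([a.coords for a in rj.heavy_atoms()])
                dmin = np.linalg.norm(xi[:, None] - xj[None, :],
                                      axis=-1).min()
                assert dmin >= 2.0, (ri.res_seq, rj.res_seq, dmin)
        # scaffold coordinates outside the loop are kept bit-exactly
        scaffold_res = {r.res_seq: r for r in toy_scaffold.residues("A")}
        kept_before = [r for r in toy_scaffold.residues("A")
                       if r.res_seq < 47]
        for new, old in zip(model.residues(), kept_before):
            np.testing.assert_array_equal(
                np.array([a.coords for a in new.atoms]),
                np.array([a.coords for a in old.atoms]))

    def test_impossible_placement_reports_clash(self, toy_scaffold):
        # a dense ball of CA beads (radius ~8 Å, 1.5 Å grid) cannot be
        # placed near the anchors without overlapping the scaffold in
        # any rotation/standoff, so the clash must be reported
        pts = []
        grid = np.arange(-8.0, 8.01, 1.5)
        for x in grid:
            for y in grid:
                for z in grid:
                    if x * x + y * y + z * z <= 64.0:
                        pts.append((x, y, z))
        residues = []
        for i, p in enumerate(pts):
            r = Residue("D", i + 1, "ALA")
            r.atoms.append(AtomRecord("CA", "C", np.array(p)))
            residues.append(r)
        blob = PolymerStructure({"D": residues})
        d = build_chimera(toy_scaffold, TOY_SCAFFOLD_LOOP, blob,
                          SegmentSpec("D", 1, len(pts)), "", "")
        with pytest.raises(ClashError) as err:
            build_initial_model(d, toy_scaffold, blob)
        assert err.value.pairs  # offending pairs are reported


class TestGeometryReport:
    def test_fields_consistent(self, toy_scaffold):
        donor = build_ideal_helix("A" * 20, chain_id="D", start_res=35)
        rep = geometry_report(toy_scaffold, TOY_SCAFFOLD_LOOP, donor,
                              SegmentSpec("D", 35, 54))
        assert rep.helix_span_estimate == pytest.approx(28.5)
        assert rep.anchor_gap > 0 and rep.donor_end_to_end > 0
        assert rep.recommended_linker_len == recommend_linkers(
            rep.anchor_gap, rep.donor_end_to_end)


class TestMutateToAlanine:
    def test_tryptophan_truncated_to_cb(self, bundle):
        mut = mutate_to_alanine(bundle, [4])
        res = mut.get_residue("A", 4)
        assert res.res_name == "ALA"
        assert {a.name for a in res.atoms} == {"N", "CA", "C", "O", "CB"}

    def test_triple_mutation_count(self, bundle):
        mut = mutate_to_alanine(bundle, [4, 8, 11])
        changed = [r.res_seq for r, r0 in
                   zip(mut.residues("A"), bundle.residues("A"))
                   if r.res_name != r0.res_name]
        assert changed == [4, 8, 11]

    def test_idempotent_and_backbone_untouched(self, bundle):
        m1 = mutate_to_alanine(bundle, [4, 8, 11])
        m2 = mutate_to_alanine(m1, [4, 8, 11])
        np.testing.assert_array_equal(m1.coords(), m2.coords())
        for rs in (4, 8, 11):
            for name in ("N", "CA", "C", "O"):
                np.testing.assert_array_equal(
                    m1.get_residue("A", rs).atom(name).coords,
                    bundle.get_residue("A", rs).atom(name).coords)

    def test_glycine_warned_and_unchanged(self):
        s = build_ideal_helix("AGA")
        with pytest.warns(UserWarning, match="glycine"):
            mut = mutate_to_alanine(s, [2])
        assert mut.get_residue("A", 2).res_name == "GLY"

    def test_missing_position_raises(self, bundle):
        with pytest.raises(KeyError):
            mutate_to_alanine(bundle, [99])
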