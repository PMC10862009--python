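import itertools

import numpy as np
import pandas as pd
import pytest

from helixgraft.secondary_structure import assign_helix
from helixgraft.structure_io import SegmentSpec, sequence_of
from helixgraft.synthetic_data import (BUNDLE_ANCHORS, FrayConfig,
                                       HDXSimConfig, TOY_SCAFFOLD_LOOP,
                                       build_extended_chain,
                                       build_ideal_helix, build_toy_scaffold,
                                       build_two_helix_bundle,
                                       calibrate_propagation_weight,
                                       dssp_visible, simulate_fray,
                                       simulate_hdx,
                                       zb_expected_visible_fraction,
                                       zb_mean_helicity)


def zb_enumerate_helicity(n, s, sigma):
    """Brute-force Zimm–Bragg mean helicity for small chains."""
    z = 0.0
    h_sum = 0.0
    for states in itertools.product((0, 1), repeat=n):
        w = 1.0
        prev = 0
        for x in states:
            w *= (s ** x) * (sigma ** (x * (1 - prev)))
            prev = x
        z += w
        h_sum += w * sum(states) / n
    return h_sum / z


def naive_visible(states):
    """Reference implementation of the latent->assignment mapping."""
    n = len(states)
    out = [False] * n
    def turn(t):
        return all(states[t + k] for k in (1, 2, 3))
    for t in range(0, n - 5):
        if turn(t) and turn(t + 1):
            for j in range(t + 1, t + 5):
                out[j] = True
    return np.array(out)


class TestIdealBackbones:
    def test_helix_ca_ca_spacing(self, ideal_helix20):
        ca = np.array([r.atom("CA").coords
                       for r in ideal_helix20.residues("A")])
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.1)

    def test_helix_assigned_helical(self, ideal_helix20):
        codes = assign_helix(ideal_helix20).codes[0]
        assert set(codes[1:-1]) == {"H"}

    def test_single_residue(self):
        s = build_ideal_helix("W")
        assert s.n_residues == 1
        assert {a.name for a in next(s.residues()).atoms} == \
            {"N", "CA", "C", "O", "CB"}

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            build_ideal_helix("AZB")

    def test_extended_chain_is_straight(self):
        s = build_extended_chain("A" * 10)
        ca = np.array([r.atom("CA").coords for r in s.residues("A")])
        end_to_end = np.linalg.norm(ca[-1] - ca[0])
        assert end_to_end > 3.4 * 9   # nearly fully stretched


class TestToyScaffold:
    def test_documented_construction(self, toy_scaffold):
        assert toy_scaffold.n_residues == 38
        seq = sequence_of(toy_scaffold, "A")
        loop = sequence_of(toy_scaffold, "A")[17:21]
        assert loop == "VVAG"
        assert [r.res_seq for r in toy_scaffold.residues("A")][0] == 30
        assert TOY_SCAFFOLD_LOOP.start_res == 47

    def test_anchor_gap_matches_coordinates(self, toy_scaffold):
        a = toy_scaffold.get_residue("A", 46).atom("CA").coords
        b = toy_scaffold.get_residue("A", 51).atom("CA").coords
        gap = float(np.linalg.norm(b - a))
        assert 5.0 < gap < 12.0   # graftable, documented geometry

    def test_regeneration_bit_identical(self, toy_scaffold):
        again = build_toy_scaffold()
        np.testing.assert_array_equal(toy_scaffold.coords(), again.coords())


class TestZimmBragg:
    @pytest.mark.parametrize("n,s,sigma", [
        (6, 1.0, 0.1), (8, 1.5, 0.05), (10, 0.8, 0.3), (12, 2.0, 0.01)])
    def test_transfer_matrix_matches_enumeration(self, n, s, sigma):
        assert zb_mean_helicity(n, s, sigma) == pytest.approx(
            zb_enumerate_helicity(n, s, sigma), abs=1e-10)

    def test_visible_fraction_matches_enumeration(self):
        n, s, sigma = 10, 1.6, 0.05
        # brute force over all states of the expected visible fraction
        z = 0.0
        v_sum = 0.0
        for states in itertools.product((0, 1), repeat=n):
            w = 1.0
            prev = 0
            for x in states:
                w *= (s ** x) * (sigma ** (x * (1 - prev)))
                prev = x
            z += w
            vis = naive_visible(list(states))
            v_sum += w * vis[2:n - 2].mean()
        assert zb_expected_visible_fraction(n, s, sigma) == pytest.approx(
            v_sum / z, abs=1e-10)

    def test_mean_helicity_monotone_in_propagation_weight(self):
        vals = [zb_mean_helicity(20, s, 0.05)
                for s in (0.3, 0.7, 1.0, 1.5, 2.5, 5.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_calibration_hits_target(self):
        n, sigma = 25, 0.05
        for target in (0.4, 0.7, 0.9):
            s = calibrate_propagation_weight(n, sigma, target)
            assert zb_expected_visible_fraction(n, s, sigma) == \
                pytest.approx(target, abs=1e-3)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_propagation_weight(25, 0.05, 1.2)
        with pytest.raises(ValueError):
            calibrate_propagation_weight(25, 0.05, 0.0)


class TestDsspVisible:
    def test_matches_naive_rule_on_random_states(self, rng):
        for _ in range(50):
            states = rng.random(20) < 0.6
            np.testing.assert_array_equal(dssp_visible(states),
                                          naive_visible(list(states)))

    def test_short_runs_invisible(self):
        states = np.zeros(15, dtype=bool)
        states[5:8] = True   # 3-run: no two consecutive turns possible
        assert not dssp_visible(states).any()


class TestSimulateFray:
    def test_same_seed_bit_identical(self):
        cfg = FrayConfig(n_frames=40, seed=11)
        e1, t1 = simulate_fray(cfg)
        e2, t2 = simulate_fray(cfg)
        for a, b in zip(e1, e2):
            for fa, fb in zip(a.frames, b.frames):
                np.testing.assert_array_equal(fa, fb)
        for a, b in zip(t1.latent, t2.latent):
            np.testing.assert_array_equal(a, b)

    def test_replicates_differ(self):
        ens, truth = simulate_fray(FrayConfig(n_frames=40, seed=11))
        assert not np.array_equal(truth.latent[0], truth.latent[1])

    def test_assignment_agrees_with_visible_truth(self):
        cfg = FrayConfig(n_frames=150, seed=2)
        ens, truth = simulate_fray(cfg)
        k = cfg.exclude_terminal
        for e, vis in zip(ens, truth.visible):
            measured = assign_helix(e).is_helix()[:, k:-k]
            agreement = (measured == vis[:, k:-k]).mean()
            assert agreement > 0.97

    def test_noise_free_assignment_matches_visible_exactly_mostly(self):
        cfg = FrayConfig(n_frames=100, seed=9, coordinate_noise_sigma=0.0)
        ens, truth = simulate_fray(cfg)
        measured = assign_helix(ens[0]).is_helix()
        agreement = (measured == truth.visible[0]).mean()
        assert agreement > 0.995

    def test_recovers_target_helicity(self):
        cfg = FrayConfig(n_frames=500, seed=0, target_helicity=0.70)
        ens, truth = simulate_fray(cfg)
        from helixgraft.secondary_structure import helical_fraction
        rep = helical_fraction(ens, SegmentSpec("A", 1, cfg.n_res))
        assert rep.mean == pytest.approx(0.70, abs=0.05)
        assert truth.visible_fraction() == pytest.approx(0.70, abs=0.04)

    def test_higher_target_gives_higher_measured_helicity(self):
        lo_cfg = FrayConfig(n_frames=300, seed=1, target_helicity=0.5)
        hi_cfg = FrayConfig(n_frames=300, seed=1, target_helicity=0.85)
        _, lo = simulate_fray(lo_cfg)
        _, hi = simulate_fray(hi_cfg)
        assert hi.visible_fraction() > lo.visible_fraction()


class TestSimulateHdx:
    def test_zero_time_zero_uptake(self):
        cfg = HDXSimConfig(timepoints_s=(0.0, 60.0), noise_sd=0.0, seed=1)
        uptake, _ = simulate_hdx(cfg)
        at0 = uptake[uptake.timepoint_s == 0.0]
        assert np.allclose(at0.uptake, 0.0)

    def test_saturation_at_long_times(self):
        cfg = HDXSimConfig(timepoints_s=(1e12,), noise_sd=0.0, seed=1)
        uptake, _ = simulate_hdx(cfg)
        assert np.allclose(uptake.uptake, 1.0, atol=1e-6)

    def test_noise_free_protection_only_on_epitope(self):
        cfg = HDXSimConfig(noise_sd=0.0, seed=3,
                           protection_fold_change=10.0)
        uptake, truth = simulate_hdx(cfg)
        wide = uptake.pivot_table(index=["start_res", "end_res"],
                                  columns=["condition", "timepoint_s"],
                                  values="uptake")
        for (s, e), row in wide.iterrows():
            in_epi = bool(truth[(truth.start_res == s)
                                & (truth.end_res == e)].in_epitope.iloc[0])
            delta = row["bound"] - row["apo"]
            if in_epi:
                assert (delta < 0).any()
            else:
                assert np.allclose(delta, 0.0, atol=1e-12)

    def test_seed_determinism(self):
        u1, _ = simulate_hdx(HDXSimConfig(seed=4))
        u2, _ = simulate_hdx(HDXSimConfig(seed=4))
        pd.testing.assert_frame_equal(u1, u2)


def test_bundle_regeneration_deterministic(bundle):
    again = build_two_helix_bundle()
    np.testing.assert_array_equal(bundle.coords(), again.coords())


def test_bundle_anchor_identities(bundle):
    names = {rs: bundle.get_residue("A", rs).res_name
             for rs in BUNDLE_ANCHORS}
    assert names == {4: "TRP", 8: "TRP", 11: "TYR"}
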