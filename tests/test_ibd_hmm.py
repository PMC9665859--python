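"""Parental-origin HMM: transitions, emissions, posteriors, assembly."""

import numpy as np
import pandas as pd
import pytest

import mppqtl as m
from mppqtl.core import MISSING, ConfigError, InputError, NumericalDegeneracyError
from mppqtl.ibd import (
    OriginStateSpace,
    calc_ibd_mpp,
    emission_prob,
    posterior_origin_probs,
    transition_matrix,
)

from conftest import oracle_grid_posteriors


def space(pt):
    return OriginStateSpace.for_pop_type(m.PopType.parse(pt))


ALL_TYPES = ["DH", "F2", "RIL2", "RIL4", "RIL8", "RILinf"]


class TestTransitions:
    def test_dh_complete_linkage_is_identity(self):
        assert np.array_equal(transition_matrix(space("DH"), 0.0), np.eye(2))

    def test_dh_free_recombination(self):
        assert np.array_equal(
            transition_matrix(space("DH"), 0.5), np.full((2, 2), 0.5)
        )

    def test_f2_equals_two_gamete_enumeration(self):
        """The 4x4 F2 matrix from brute-force enumeration of the two
        gametes' independent switch/stay events."""
        r = 0.2
        sp = space("F2")
        expected = np.zeros((4, 4))
        for i, (a1, a2) in enumerate(sp.origin_pairs):
            for j, (b1, b2) in enumerate(sp.origin_pairs):
                p1 = r if a1 != b1 else 1 - r
                p2 = r if a2 != b2 else 1 - r
                expected[i, j] = p1 * p2
        assert np.allclose(transition_matrix(sp, r), expected, atol=1e-15)

    @pytest.mark.parametrize("pt", ALL_TYPES)
    @pytest.mark.parametrize("r", [0.0, 0.05, 0.25, 0.5])
    def test_rows_sum_to_one_and_prior_stationary(self, pt, r):
        sp = space(pt)
        T = transition_matrix(sp, r)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(sp.prior @ T, sp.prior, atol=1e-12)
        assert np.all(T >= 0)

    @pytest.mark.parametrize("pt", ALL_TYPES)
    def test_prior_sums_to_one(self, pt):
        assert space(pt).prior.sum() == pytest.approx(1.0)

    def test_rejects_bad_r(self):
        with pytest.raises(InputError):
            transition_matrix(space("DH"), 0.6)

    def test_rilinf_uses_inbred_line_recombination(self):
        # Haldane-Waddington: R = 2r/(1+2r)
        r = 0.1
        T = transition_matrix(space("RILinf"), r)
        assert T[0, 1] == pytest.approx(2 * r / (1 + 2 * r))


class TestEmissions:
    def test_error_free_informative_marker(self):
        sp = space("DH")
        e = emission_prob(sp, (0, 0), (0, 1), error_rate=0.0)
        assert e[0] == pytest.approx(1.0)
        assert e[1] == pytest.approx(0.0)

    def test_missing_observation_uninformative(self):
        sp = space("F2")
        e = emission_prob(sp, (MISSING, MISSING), (0, 1), error_rate=0.01)
        assert np.allclose(e, 1.0)

    def test_wrong_homozygote_two_allele_product(self):
        sp = space("DH")
        e = emission_prob(sp, (1, 1), (0, 1), error_rate=0.01)
        assert e[0] == pytest.approx(0.01 ** 2)
        assert e[1] == pytest.approx(0.99 ** 2)

    def test_monomorphic_marker_equal_across_states(self):
        sp = space("F2")
        e = emission_prob(sp, (0, 0), (0, 0), error_rate=0.01)
        assert np.allclose(e, e[0])

    def test_rejects_bad_error_rate(self):
        with pytest.raises(InputError):
            emission_prob(space("DH"), (0, 0), (0, 1), error_rate=0.5)


def _random_chain(rng, pt, n_markers, n_geno, eps):
    sp = space(pt)
    marker_pos = np.sort(rng.uniform(0, 30, n_markers))
    parent_alleles = np.vstack([np.zeros(n_markers), np.ones(n_markers)]).astype(int)
    obs = rng.integers(0, 2, size=(n_geno, n_markers, 2))
    obs[rng.random((n_geno, n_markers)) < 0.2] = MISSING
    return sp, marker_pos, parent_alleles, obs


class TestPosteriors:
    def test_single_uninformative_marker_returns_prior(self):
        sp = space("DH")
        post = posterior_origin_probs(
            np.array([5.0]),
            np.array([[[MISSING, MISSING]]]),
            np.array([[0], [1]]),
            sp,
            np.array([0.0, 5.0, 10.0]),
            error_rate=0.01,
        )
        assert np.allclose(post, 0.5)

    def test_dense_informative_markers_pin_origin(self):
        sp = space("DH")
        M = 20
        pos = np.arange(M, dtype=float)
        obs = np.zeros((1, M, 2), dtype=int)  # always parent-1 homozygote
        parents = np.vstack([np.zeros(M), np.ones(M)]).astype(int)
        post = posterior_origin_probs(pos, obs, parents, sp, pos, error_rate=0.0)
        assert np.allclose(post[..., 0], 1.0, atol=1e-12)

    @pytest.mark.parametrize("pt", ["DH", "F2", "RIL2"])
    def test_matches_exhaustive_path_enumeration(self, pt, rng):
        """Forward-backward equals the brute-force sum over all hidden
        paths on short chains (the defining property of the recursion)."""
        sp, marker_pos, parents, obs = _random_chain(rng, pt, 4, 3, 0.02)
        grid = np.array([0.5, 13.7, 29.9])
        got = posterior_origin_probs(marker_pos, obs, parents, sp, grid, 0.02)
        want = oracle_grid_posteriors(sp, marker_pos, grid, obs, parents, 0.02)
        assert np.allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_invariant_to_extra_pseudo_markers(self, rng):
        """Posteriors at shared grid points are unchanged when additional
        uniform-emission pseudo-positions are inserted (Markov
        consistency)."""
        sp, marker_pos, parents, obs = _random_chain(rng, "F2", 5, 4, 0.02)
        base_grid = np.array([2.0, 15.0, 28.0])
        dense_grid = np.sort(np.concatenate([base_grid, [5.5, 9.1, 20.3]]))
        p1 = posterior_origin_probs(marker_pos, obs, parents, sp, base_grid, 0.02)
        p2 = posterior_origin_probs(marker_pos, obs, parents, sp, dense_grid, 0.02)
        keep = [int(np.flatnonzero(np.isclose(dense_grid, g))[0]) for g in base_grid]
        assert np.allclose(p1, p2[:, keep, :], atol=1e-12)

    @pytest.mark.parametrize("pt", ALL_TYPES)
    def test_posteriors_sum_to_one(self, pt, rng):
        sp, marker_pos, parents, obs = _random_chain(rng, pt, 6, 5, 0.01)
        grid = np.linspace(0, 30, 7)
        post = posterior_origin_probs(marker_pos, obs, parents, sp, grid, 0.01)
        assert np.allclose(post.sum(axis=2), 1.0, atol=1e-10)

    def test_high_error_rate_approaches_prior(self, rng):
        sp, marker_pos, parents, obs = _random_chain(rng, "DH", 5, 3, 0.0)
        obs[obs == MISSING] = 0
        grid = np.array([10.0])
        post = posterior_origin_probs(marker_pos, obs, parents, sp, grid, 0.499)
        assert np.allclose(post, 0.5, atol=0.02)

    def test_impossible_data_at_zero_error_raises(self):
        # DH observed het at an informative marker is impossible at eps=0
        sp = space("DH")
        with pytest.raises(NumericalDegeneracyError, match="error rate > 0"):
            posterior_origin_probs(
                np.array([0.0]),
                np.array([[[0, 1]]]),
                np.array([[0], [1]]),
                sp,
                np.array([0.0]),
                error_rate=0.0,
            )

    def test_rejects_unsorted_positions(self):
        sp = space("DH")
        with pytest.raises(InputError):
            posterior_origin_probs(
                np.array([5.0, 1.0]),
                np.zeros((1, 2, 2), dtype=int),
                np.array([[0, 0], [1, 1]]),
                sp,
                np.array([0.0]),
            )


class TestCalcIbd:
    def test_structural_zeros_for_nonparental_founders(self, rng):
        design = m.make_design(
            ["P1", "P2", "P3"],
            [("F1", "P1", "P2", "DH"), ("F2", "P1", "P3", "DH")],
            10,
        )
        gmap = m.make_grid_map({"1": 20.0}, 5.0)
        markers, _ = m.simulate_population(design, gmap, rng)
        ibd = calc_ibd_mpp(gmap, markers, design, step_cM=5.0)
        p3 = ibd.founders.index("P3")
        p2 = ibd.founders.index("P2")
        assert np.all(ibd.counts[:10, :, p3] == 0.0)  # family 1 rows
        assert np.all(ibd.counts[10:, :, p2] == 0.0)  # family 2 rows

    @pytest.mark.parametrize("pt", ALL_TYPES)
    def test_ploidy_conservation(self, pt, rng):
        design = m.make_design(["P1", "P2"], [("F1", "P1", "P2", pt)], 15)
        gmap = m.make_grid_map({"1": 30.0, "2": 10.0}, 3.0)
        markers, _ = m.simulate_population(
            design, gmap, rng, genotype_error=0.02, missing_rate=0.1
        )
        ibd = calc_ibd_mpp(gmap, markers, design, step_cM=4.0)
        assert np.allclose(ibd.counts.sum(axis=2), 2.0, atol=1e-8)

    def test_recovers_simulator_truth_dense_markers(self, rng):
        """Expected counts track the true origin indicators on an
        error-free DH family with a 1 cM marker grid."""
        design = m.make_design(["P1", "P2"], [("F1", "P1", "P2", "DH")], 40)
        gmap = m.make_grid_map({"1": 60.0}, 1.0)
        markers, truth = m.simulate_population(design, gmap, rng)
        ibd = calc_ibd_mpp(gmap, markers, design, step_cM=1.0, error_rate=0.01)
        # grid == marker positions here
        true_counts = np.stack(
            [truth.true_counts_at_marker(j) for j in range(gmap.n_markers)], axis=1
        )
        err = np.abs(ibd.counts - true_counts).max(axis=2)
        assert err.mean() < 0.05
        assert (err < 0.05).mean() >= 0.99

    def test_unsupported_family_type_names_import_pathway(self):
        with pytest.raises(ConfigError, match="import"):
            m.make_design(["P1", "P2"], [("F1", "P1", "P2", "MAGIC8")], 5)

    def test_long_frame_round_trips_probabilities(self, rng):
        design = m.make_design(["P1", "P2"], [("F1", "P1", "P2", "F2")], 5)
        gmap = m.make_grid_map({"1": 10.0}, 5.0)
        markers, _ = m.simulate_population(design, gmap, rng)
        ibd = calc_ibd_mpp(gmap, markers, design, step_cM=5.0)
        long = ibd.to_long_frame()
        total = long.groupby(["genotype", "chromosome", "position"])["prob"].sum()
        assert np.allclose(total, 1.0, atol=1e-8)
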