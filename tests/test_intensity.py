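import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from metafoci.intensity import (
    IntensityMatrix,
    fdr_adjust,
    intensity_map,
    nnmf,
    pairwise_profile_tests,
    profile_difference_test,
    region_intensity_matrix,
    signature,
)
from metafoci.mcmc import MCMCConfig, PosteriorSamples
from metafoci.model import (
    ClusterKernels,
    MixtureWeights,
    ModelState,
    PopulationProcess,
    study_center_intensity,
)
from metafoci.synthetic import null_intensity_matrices


def make_state(centers, nu_s=1.0, nu_c=0.5, mu_cent=2.0, sigma_study=8.0):
    return ModelState(
        PopulationProcess(1e-5, np.asarray(centers, float).reshape(-1, 3)),
        ClusterKernels(sigma_study, 4.0),
        MixtureWeights(mu_cent, 2.0, 0.5, nu_s, nu_c),
    )


def fake_samples(states, category="x"):
    cfg = MCMCConfig(n_iter=len(states) + 1, burn_in=1, seed=0)
    return PosteriorSamples(category, states,
                            np.array([s.population.n_centers for s in states]),
                            np.zeros(len(states)), {}, cfg, 0)


class TestIntensityMap:
    def test_background_only_uniform_and_sums_to_rate(self, toy_world):
        _, mask, _, geom = toy_world
        s = fake_samples([make_state(np.empty((0, 3)), nu_s=2.0, nu_c=1.0)])
        grid = intensity_map(s, mask, geom=geom)
        vals = grid.values[mask.inside]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-12)
        assert grid.total == pytest.approx(3.0, rel=1e-9)

    def test_conservation_against_expected_count(self, toy_world):
        _, mask, _, geom = toy_world
        rng = np.random.default_rng(2)
        states = [make_state(rng.uniform(-20, 20, (k, 3)), nu_s=1.5)
                  for k in (1, 2, 3)]
        s = fake_samples(states)
        grid = intensity_map(s, mask, geom=geom)
        assert abs(grid.total - grid.expected_count) <= grid.quad_bound + 1e-9

    def test_coarser_grid_preserves_total(self):
        from metafoci.model import MaskGeometry
        from metafoci.synthetic import ScenarioConfig, make_toy_mask_atlas

        state = make_state([[0, 0, 0]], nu_s=1.0)
        totals = []
        for shape, vs in (((40, 48, 40), 2.0), ((20, 24, 20), 4.0)):
            mask, _ = make_toy_mask_atlas(
                ScenarioConfig(mask_shape=shape, voxel_size=vs))
            grid = intensity_map(fake_samples([state]), mask,
                                 geom=MaskGeometry(mask))
            totals.append(grid.total)
        assert totals[0] == pytest.approx(totals[1], rel=5e-3)

    def test_per_state_quadrature_oracle(self, toy_world):
        """Map mean equals direct per-state voxel quadrature."""
        _, mask, _, geom = toy_world
        states = [make_state([[0, 0, 0]]), make_state([[10, -5, 5]])]
        s = fake_samples(states)
        grid = intensity_map(s, mask, geom=geom)
        vox = mask.voxel_centers()
        v = mask.grid.voxel_volume
        oracle = np.mean(
            [study_center_intensity(st, vox, geom) * v for st in states], axis=0
        )
        np.testing.assert_allclose(grid.values[mask.inside], oracle, rtol=1e-9)


class TestRegionMatrix:
    def test_uniform_state_equal_regions(self, toy_world):
        _, mask, atlas, geom = toy_world
        s = fake_samples([make_state(np.empty((0, 3)), nu_s=2.0, nu_c=1.0)])
        m = region_intensity_matrix(s, atlas, mask, geom=geom)
        np.testing.assert_allclose(m.values, m.values[0, 0], rtol=1e-9)

    def test_center_inside_region_maximal(self, toy_world):
        _, mask, atlas, geom = toy_world
        # place the center at the middle of region 1's box
        r1 = np.argwhere(atlas.labels == 1)
        from metafoci.io_atlas import voxel_to_world

        mid = voxel_to_world(mask.grid, r1.mean(axis=0))[0]
        s = fake_samples([make_state(mid, nu_s=0.1, nu_c=0.1, sigma_study=6.0)])
        m = region_intensity_matrix(s, atlas, mask, geom=geom)
        assert np.argmax(m.values[0]) == 0  # region 1 = column 0

    def test_matches_voxelwise_recomputation(self, toy_world):
        _, mask, atlas, geom = toy_world
        state = make_state([[5, 5, 5]])
        s = fake_samples([state])
        m = region_intensity_matrix(s, atlas, mask, geom=geom)
        vox = mask.voxel_centers()
        vals = study_center_intensity(state, vox, geom) * mask.grid.voxel_volume
        labels = atlas.labels[mask.inside]
        for r in range(atlas.n_regions):
            sel = labels == r + 1
            assert m.values[0, r] == pytest.approx(vals[sel].mean(), rel=1e-9)


class TestSignature:
    def test_single_row(self):
        m = IntensityMatrix(np.array([[1.0, 2.0, 3.0]]), "x", ["a", "b", "c"])
        np.testing.assert_allclose(signature(m), [1, 2, 3])

    def test_constant_matrix(self):
        m = np.full((7, 4), 2.5)
        np.testing.assert_allclose(signature(m), 2.5)

    def test_random_matrix_mean_oracle(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(size=(5, 3))
        np.testing.assert_allclose(signature(m), m.sum(axis=0) / 5, rtol=1e-12)

    def test_commutes_with_state_then_region_averaging(self, toy_world):
        _, mask, atlas, geom = toy_world
        rng = np.random.default_rng(4)
        states = [make_state(rng.uniform(-15, 15, (2, 3))) for _ in range(4)]
        s = fake_samples(states)
        m = region_intensity_matrix(s, atlas, mask, geom=geom)
        sig = signature(m)
        # average states first, then region means
        vox = mask.voxel_centers()
        v = mask.grid.voxel_volume
        mean_map = np.mean([study_center_intensity(st, vox, geom) * v
                            for st in states], axis=0)
        labels = atlas.labels[mask.inside]
        other = np.array([mean_map[labels == r + 1].mean()
                          for r in range(atlas.n_regions)])
        np.testing.assert_allclose(sig, other, rtol=1e-9)


class TestNNMF:
    def test_exact_rank_one(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 2, size=(5, 1))
        h = rng.uniform(0.5, 2, size=(1, 7))
        res = nnmf(w @ h, k=1, restarts=5, seed=1)
        assert res.error < 1e-8

    def test_rank_two_product(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.1, 1, (5, 2)) @ rng.uniform(0.1, 1, (2, 7))
        res = nnmf(a, k=2, restarts=10, seed=3)
        assert res.error < 1e-6
        assert np.all(res.W >= 0) and np.all(res.H >= 0)

    def test_error_trace_monotone(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(size=(6, 9))
        res = nnmf(a, k=3, restarts=3, seed=7)
        assert np.all(np.diff(res.error_trace) <= 1e-12)

    def test_matches_sklearn_quality(self):
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(9)
        a = rng.uniform(size=(5, 7))
        ours = nnmf(a, k=2, restarts=10, seed=11).error
        sk = NMF(n_components=2, init="nndsvda", max_iter=2000,
                 random_state=0).fit(a)
        theirs = sk.reconstruction_err_**2
        assert ours <= theirs * 1.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nnmf(np.array([[1.0, -0.1]]), k=1)
        with pytest.raises(ValueError):
            nnmf(np.ones((3, 3)), k=0)
        with pytest.raises(ValueError):
            nnmf(np.ones((3, 3)), k=4)


class TestProfileDifferenceTest:
    def brute_force(self, mi, mj):
        t, r = mi.shape
        dbar = np.sign(mi.mean(0) - mj.mean(0))
        count = 0
        for ti in range(t):
            s = sum(abs(np.sign(mi[ti, ri] - mj[ti, ri]) - dbar[ri])
                    for ri in range(r))
            if s >= r:
                count += 1
        return min(1.0, (2.0**r / t) * count)

    def test_all_same_side_gives_zero(self):
        mi = np.ones((6, 3)) + 0.1 * np.arange(6)[:, None]
        mj = np.zeros((6, 3))
        assert profile_difference_test(mi, mj) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_enumeration_oracle_small(self, seed):
        rng = np.random.default_rng(seed)
        t, r = rng.integers(4, 11), rng.integers(1, 4)
        mi = rng.uniform(size=(t, r))
        mj = rng.uniform(size=(t, r))
        assert profile_difference_test(mi, mj) == pytest.approx(
            self.brute_force(mi, mj)
        )

    def test_symmetry_and_region_permutation_invariance(self):
        rng = np.random.default_rng(6)
        mi, mj = rng.uniform(size=(8, 4)), rng.uniform(size=(8, 4))
        p1 = profile_difference_test(mi, mj)
        assert profile_difference_test(mj, mi) == pytest.approx(p1)
        perm = rng.permutation(4)
        assert profile_difference_test(mi[:, perm], mj[:, perm]) == pytest.approx(p1)

    def test_subset_argument_uses_subset_size(self):
        rng = np.random.default_rng(7)
        mi, mj = rng.uniform(size=(10, 5)), rng.uniform(size=(10, 5))
        sub = [0, 2]
        assert profile_difference_test(mi, mj, subset=sub) == pytest.approx(
            self.brute_force(mi[:, sub], mj[:, sub])
        )

    def test_null_calibration(self):
        """No true difference: rejection rate at alpha=.05 stays <= alpha."""
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(200):
            mi = null_intensity_matrices(200, 5, "identity",
                                         seed=int(rng.integers(2**31)))
            mj = null_intensity_matrices(200, 5, "identity",
                                         seed=int(rng.integers(2**31)))
            if profile_difference_test(mi, mj) < 0.05:
                rejections += 1
        assert rejections / 200 <= 0.05

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            profile_difference_test(np.ones((4, 2)), np.ones((4, 3)))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        mi=arrays(float, (6, 3), elements=st.floats(0.0, 10.0)),
        mj=arrays(float, (6, 3), elements=st.floats(0.0, 10.0)),
    )
    def test_p_value_bounds_and_symmetry_property(self, mi, mj):
        p = profile_difference_test(mi, mj)
        assert 0.0 <= p <= 1.0
        assert profile_difference_test(mj, mi) == pytest.approx(p)


class TestFDR:
    def test_all_zero_rejected(self):
        q, rej = fdr_adjust([0.0, 0.0, 0.0])
        assert rej.all()

    def test_hand_bh_computation(self):
        q, rej = fdr_adjust([0.01, 0.02, 0.03, 0.5], q=0.05)
        np.testing.assert_array_equal(rej, [True, True, True, False])
        assert np.all(np.diff(np.sort(q)) >= -1e-15)  # monotone q-values

    def test_single_pvalue_unchanged(self):
        q, rej = fdr_adjust([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_pairwise_count(self):
        rng = np.random.default_rng(0)
        mats = {c: IntensityMatrix(rng.uniform(size=(6, 3)), c, ["a", "b", "c"])
                for c in "abcde"}
        out = pairwise_profile_tests(mats)
        assert len(out) == 5 * 4 // 2
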