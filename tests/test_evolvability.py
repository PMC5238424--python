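import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modulrate.evolvability import (
    draw_skewers,
    evolutionary_pmatrix,
    pmatrix_from_array,
    skewer_indices,
)
from modulrate.gpa import gpa
from modulrate.io import LandmarkDataset, tree_from_newick
from modulrate.phylo import bm_covariance, phylo_transform
from modulrate.simulate import SimulationSpec, simulate_bm_shapes

from oracles import pic_contrasts


def random_psd(d, rng, rank=None):
    A = rng.normal(size=(d, rank or d))
    return A @ A.T / d


class TestEvolutionaryPMatrix:
    def test_symmetric_psd_right_dimension(self, default_study, default_aligned):
        P = evolutionary_pmatrix(default_aligned, default_study.tree,
                                 default_study.modules, "face")
        k = default_study.modules.count("face")
        assert P.matrix.shape == (2 * k, 2 * k)
        np.testing.assert_allclose(P.matrix, P.matrix.T, atol=1e-12)
        assert P.eigenvalues[-1] > -1e-10 * P.eigenvalues[0]
        assert P.effective_rank <= min(len(default_aligned.species) - 1, 2 * k)

    def test_star_tree_equals_sample_covariance(self):
        spec = SimulationSpec(n_species=30, tree_model="star", seed=31)
        study = simulate_bm_shapes(spec)
        aligned = gpa(study.dataset)
        P = evolutionary_pmatrix(aligned, study.tree, study.modules, "braincase")
        cols = study.modules.columns("braincase")
        Y = aligned.tangent_means()[:, cols]
        np.testing.assert_allclose(P.matrix, np.cov(Y.T, ddof=1), atol=1e-12)

    def test_matches_contrasts_covariance_on_five_tips(self, five_tip_tree):
        ordering = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(32)
        Y = rng.normal(size=(5, 4))
        bm = bm_covariance(five_tip_tree, ordering)
        U = phylo_transform(Y, bm)
        P = U.T @ U / 4.0
        contrasts = pic_contrasts(five_tip_tree, Y, ordering)
        np.testing.assert_allclose(P, contrasts.T @ contrasts / 4.0, atol=1e-10)


class TestDrawSkewers:
    def test_unit_norm_and_default_count(self):
        betas = draw_skewers(6, seed=0)
        assert betas.shape == (1000, 6)
        np.testing.assert_allclose(np.linalg.norm(betas, axis=1), 1.0, atol=1e-12)

    def test_deterministic_given_seed(self):
        np.testing.assert_array_equal(draw_skewers(4, 50, seed=9), draw_skewers(4, 50, seed=9))

    def test_uniform_on_sphere(self):
        # mean direction ~ 0 for uniform draws
        betas = draw_skewers(3, 20000, seed=1)
        assert np.linalg.norm(betas.mean(axis=0)) < 0.02


class TestSkewerIndices:
    def test_identity_matrix_all_ones(self):
        res = skewer_indices(np.eye(5), draw_skewers(5, 200, seed=2))
        for name in ("evolvability", "respondability", "conditional_evolvability", "autonomy"):
            np.testing.assert_allclose(res.raw[name], 1.0, atol=1e-10)

    def test_axis_aligned_case(self):
        res = skewer_indices(np.diag([2.0, 1.0]), np.array([[1.0, 0.0]]))
        assert res.raw["evolvability"][0] == pytest.approx(2.0)
        assert res.raw["respondability"][0] == pytest.approx(2.0)
        assert res.raw["conditional_evolvability"][0] == pytest.approx(2.0)
        assert res.raw["autonomy"][0] == pytest.approx(1.0)
        assert res.raw["constraints"][0] == pytest.approx(1.0)

    def test_mean_evolvability_approaches_trace_over_d(self):
        P = np.diag([2.0, 1.0])
        res = skewer_indices(P, draw_skewers(2, 10000, seed=3))
        e = res.raw["evolvability"]
        se = e.std(ddof=1) / np.sqrt(e.size)
        assert abs(e.mean() - 1.5) < 3 * se
        # theoretical skewer variance for d=2: e = 1.5 + cos(2t)/2, var = 1/8
        assert e.var(ddof=1) == pytest.approx(1.0 / 8.0, rel=0.1)

    def test_hansen_houle_inequalities_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            d = rng.integers(2, 8)
            P = random_psd(d, rng)
            res = skewer_indices(P, draw_skewers(d, 100, seed=int(rng.integers(2**31))))
            e, r, c, a = (res.raw[n] for n in
                          ("evolvability", "respondability",
                           "conditional_evolvability", "autonomy"))
            assert np.all(c <= e + 1e-10)
            assert np.all(e <= r + 1e-10)
            assert np.all((a > 0) & (a <= 1 + 1e-12))
            assert np.all((res.raw["constraints"] >= 0) & (res.raw["constraints"] <= 1 + 1e-12))

    def test_equality_iff_eigenvector(self):
        rng = np.random.default_rng(5)
        P = random_psd(4, rng)
        vals, vecs = np.linalg.eigh(P)
        res = skewer_indices(P, vecs.T)  # each skewer an eigenvector
        np.testing.assert_allclose(res.raw["evolvability"], res.raw["respondability"], atol=1e-10)
        np.testing.assert_allclose(res.raw["autonomy"], 1.0, atol=1e-10)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        P = random_psd(5, rng)
        betas = draw_skewers(5, 64, seed=7)
        Q = np.linalg.qr(rng.normal(size=(5, 5)))[0]
        res1 = skewer_indices(P, betas)
        res2 = skewer_indices(Q @ P @ Q.T, betas @ Q.T)
        for name in ("evolvability", "respondability", "conditional_evolvability", "autonomy"):
            np.testing.assert_allclose(res2.raw[name], res1.raw[name], atol=1e-8)

    def test_rank_deficient_uses_positive_eigenspace(self):
        rng = np.random.default_rng(8)
        P = random_psd(6, rng, rank=3)
        res = skewer_indices(P, draw_skewers(6, 100, seed=9))
        a = res.raw["autonomy"]
        assert np.all((a > 0) & (a <= 1 + 1e-12))
        c, e = res.raw["conditional_evolvability"], res.raw["evolvability"]
        assert np.all(c <= e + 1e-12)

    def test_procrustes_pmatrix_indices_well_defined(self, default_study, default_aligned):
        # near-singular directions from superimposition must not produce
        # the impossible negative conditional evolvabilities / autonomies
        P = evolutionary_pmatrix(default_aligned, default_study.tree,
                                 default_study.modules, "face")
        res = skewer_indices(P, draw_skewers(P.dim, 500, seed=10))
        for v in res.raw.values():
            assert np.all(np.isfinite(v))
        assert np.all(res.raw["conditional_evolvability"] <= res.raw["evolvability"] + 1e-18)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="rank-0|positive"):
            skewer_indices(np.zeros((3, 3)), draw_skewers(3, 5, seed=11))

    def test_summary_consistent_with_raw(self):
        res = skewer_indices(np.diag([3.0, 1.0, 0.5]), draw_skewers(3, 50, seed=12))
        for name, v in res.raw.items():
            assert res.summary[name]["mean"] == pytest.approx(v.mean())
            assert res.summary[name]["min"] == pytest.approx(v.min())
            assert res.summary[name]["max"] == pytest.approx(v.max())


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 2**20), d=st.integers(2, 6))
def test_skewer_bounds_property(seed, d):
    """c <= e <= r and a in (0,1] for arbitrary PSD matrices and skewers."""
    rng = np.random.default_rng(seed)
    P = random_psd(d, rng)
    res = skewer_indices(P, draw_skewers(d, 20, seed=seed))
    assert np.all(res.raw["conditional_evolvability"] <= res.raw["evolvability"] + 1e-10)
    assert np.all(res.raw["evolvability"] <= res.raw["respondability"] + 1e-10)
    assert np.all(res.raw["autonomy"] > 0)
    assert np.all(res.raw["autonomy"] <= 1 + 1e-12)
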