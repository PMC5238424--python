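import numpy as np
import pytest

from modulrate.gpa import gpa
from modulrate.io import LandmarkDataset, ModuleMap, tree_from_newick
from modulrate.phylo import bm_covariance, phylo_transform
from modulrate.rates import clade_rates, compare_module_rates, sigma_mult
from modulrate.simulate import SimulationSpec, base_configuration, simulate_bm_shapes, simulate_tree


class TestSigmaMult:
    def test_zero_data_zero_rate(self):
        assert sigma_mult(np.zeros((10, 6)), 3) == 0.0

    def test_per_landmark_normalization(self):
        rng = np.random.default_rng(0)
        U = rng.normal(size=(15, 4))
        doubled = np.hstack([U, U])
        assert sigma_mult(doubled, 4) == pytest.approx(sigma_mult(U, 2), rel=1e-12)

    def test_recovers_true_bm_rate(self):
        # simulate flattened BM tip data directly; per-landmark rate 0.01
        true_rate = 0.01
        n, k = 100, 5
        estimates = []
        for seed in range(50):
            tree = simulate_tree(n, seed=seed)
            bm = bm_covariance(tree)
            L = np.linalg.cholesky(bm.C)
            rng = np.random.default_rng(1000 + seed)
            Y = L @ rng.normal(size=(n, 2 * k)) * np.sqrt(true_rate / 2.0)
            U = phylo_transform(Y, bm)
            estimates.append(sigma_mult(U, k))
        assert np.mean(estimates) == pytest.approx(true_rate, rel=0.10)

    def test_star_tree_closed_form(self):
        b = 2.5  # star branch length
        n, k = 30, 3
        labels = [f"t{i:02d}" for i in range(n)]
        tree = tree_from_newick("(" + ",".join(f"{s}:{b}" for s in labels) + ");")
        bm = bm_covariance(tree, labels)
        Y = np.random.default_rng(1).normal(size=(n, 2 * k))
        U = phylo_transform(Y, bm)
        expected = ((Y - Y.mean(axis=0)) ** 2).sum() / (b * n * k)
        assert sigma_mult(U, k) == pytest.approx(expected, rel=1e-10)

    def test_zero_landmark_count_error(self):
        with pytest.raises(ValueError):
            sigma_mult(np.ones((5, 2)), 0)


class TestCompareModuleRates:
    def test_identical_blocks_ratio_one(self, default_study):
        # overwrite braincase coordinates with the face coordinates
        ds = default_study.dataset
        coords = ds.coordinates.copy()
        coords[:, 5:, :] = coords[:, :5, :]
        twin = LandmarkDataset(list(ds.specimen_ids), list(ds.species_ids), coords)
        aligned = gpa(twin)
        res = compare_module_rates(aligned, default_study.tree, default_study.modules,
                                   n_sim=99, seed=1)
        assert res.ratio == pytest.approx(1.0, abs=1e-8)
        assert res.p_value > 0.9

    def test_ratio_invariant_to_global_rescaling(self, default_study):
        ds = default_study.dataset
        aligned1 = gpa(ds)
        scaled = LandmarkDataset(
            list(ds.specimen_ids), list(ds.species_ids), 12.5 * ds.coordinates
        )
        aligned2 = gpa(scaled)
        r1 = compare_module_rates(aligned1, default_study.tree, default_study.modules,
                                  n_sim=9, seed=2)
        r2 = compare_module_rates(aligned2, default_study.tree, default_study.modules,
                                  n_sim=9, seed=2)
        assert r2.ratio == pytest.approx(r1.ratio, rel=1e-8)

    def test_ratio_invariant_to_branch_rescaling(self, default_study, default_aligned):
        tree2 = tree_from_newick(default_study.tree.newick())
        for edge in tree2.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 7.0
        r1 = compare_module_rates(default_aligned, default_study.tree,
                                  default_study.modules, n_sim=9, seed=3)
        r2 = compare_module_rates(default_aligned, tree2, default_study.modules,
                                  n_sim=9, seed=3)
        # individual rates scale inversely with time units; the ratio does not
        for m in r1.rates:
            assert r2.rates[m] == pytest.approx(r1.rates[m] / 7.0, rel=1e-8)
        assert r2.ratio == pytest.approx(r1.ratio, rel=1e-8)

    def test_detects_strong_rate_difference(self):
        spec = SimulationSpec(n_species=80, sigma2_face=0.05, sigma2_brain=0.005, seed=21)
        study = simulate_bm_shapes(spec)
        res = compare_module_rates(gpa(study.dataset), study.tree, study.modules,
                                   n_sim=199, seed=4)
        assert res.ratio > 3.0
        assert res.p_value < 0.05

    def test_one_sided_matches_upper_tail_rule(self, default_study, default_aligned):
        res = compare_module_rates(default_aligned, default_study.tree,
                                   default_study.modules, n_sim=199, seed=5,
                                   two_sided=False)
        expected = (np.sum(res.null_ratios >= res.ratio) + 1.0) / 200.0
        assert res.p_value == pytest.approx(expected)


def _two_clade_study(seed, n_per_clade=30, p=10, k=5, face_multiplier=3.0):
    """Two sister clades; clade B's face landmarks evolve faster."""
    rng = np.random.default_rng(seed)
    left = simulate_tree(n_per_clade, seed=seed * 2 + 1)
    right = simulate_tree(n_per_clade, seed=seed * 2 + 2)
    # relabel and join under a root with stem branches of length 0.5
    for i, leaf in enumerate(left.tree.leaf_node_iter()):
        leaf.taxon.label = f"a{i:02d}"
    for i, leaf in enumerate(right.tree.leaf_node_iter()):
        leaf.taxon.label = f"b{i:02d}"
    nl = left.newick().rstrip(";").strip()
    nr = right.newick().rstrip(";").strip()
    tree = tree_from_newick(f"({nl}:0.5,{nr}:0.5);")

    base = base_configuration(p, k).ravel()
    v = 0.01 / 2.0  # per-coordinate base rate
    d = 2 * p
    states = {}
    tip_state = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = base.copy()
            node._in_b = None
            continue
        parent = node.parent_node
        label = node.taxon.label if node.is_leaf() else None
        in_b = parent._in_b
        if in_b is None:
            first = next(iter(node.leaf_iter())).taxon.label
            in_b = first.startswith("b")
        node._in_b = in_b
        rates = np.full(d, v)
        if in_b:
            rates[: 2 * k] *= face_multiplier
        t = node.edge.length
        states[node] = states[parent] + np.sqrt(t * rates) * rng.standard_normal(d)
        if node.is_leaf():
            tip_state[node.taxon.label] = states[node]
    species = sorted(tip_state)
    configs = np.stack([tip_state[s].reshape(-1, 2) for s in species])
    dataset = LandmarkDataset(species, species, configs)
    modules = ModuleMap({i: ("face" if i < k else "braincase") for i in range(p)})
    clades = {s: ("A" if s.startswith("a") else "B") for s in species}
    return dataset, tree, modules, clades


class TestCladeRates:
    def test_single_clade_reduces_to_overall_rates(self, default_study, default_aligned):
        clades = {s: "all" for s in default_study.species}
        table = clade_rates(default_aligned, default_study.tree, default_study.modules,
                            clades, n_sim=9, seed=6)
        overall = compare_module_rates(default_aligned, default_study.tree,
                                       default_study.modules, n_sim=9, seed=6)
        for m, rate in overall.rates.items():
            assert table.rates["all"][m] == pytest.approx(rate, rel=1e-10)
        assert table.ratios["all"] == pytest.approx(overall.ratio, rel=1e-10)

    def test_small_clades_excluded_with_warning(self, default_study, default_aligned):
        clades = {s: "big" for s in default_study.species}
        lone = default_study.species[0]
        clades[lone] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            table = clade_rates(default_aligned, default_study.tree,
                                default_study.modules, clades, n_sim=9, seed=7)
        assert table.excluded == ["tiny"]
        assert "tiny" not in table.clades

    def test_pairwise_power_for_threefold_difference(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            dataset, tree, modules, clades = _two_clade_study(seed)
            aligned = gpa(dataset)
            table = clade_rates(aligned, tree, modules, clades, n_sim=199,
                                seed=100 + seed)
            i, j = table.clades.index("A"), table.clades.index("B")
            if table.pairwise_p["face"][i, j] < 0.05:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_pairwise_matrix_symmetric(self, default_study, default_aligned):
        half = len(default_study.species) // 2
        clades = {
            s: ("one" if i < half else "two")
            for i, s in enumerate(default_study.species)
        }
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # arbitrary halves need not be monophyletic
            table = clade_rates(default_aligned, default_study.tree,
                                default_study.modules, clades, n_sim=19, seed=8)
        for m, P in table.pairwise_p.items():
            np.testing.assert_allclose(P, P.T)
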