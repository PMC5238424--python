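"""Calibration experiments: statistical behaviour of the pipeline on
synthetic studies with known truth.

Each experiment simulates replicate studies under stated conditions,
runs the full geometry + comparative stack on each, and reports recovery
or error rates.  They double as the package's acceptance checks and as a
template for users who want to gauge power at their own sample sizes.
"""

from __future__ import annotations

import numpy as np

from .covariation import cr_test, phylo_pls
from .gpa import gpa
from .phylo import bm_covariance, phylo_transform
from .rates import compare_module_rates, module_order, sigma_mult
from .simulate import SimulationSpec, simulate_bm_shapes

__all__ = [
    "rate_ratio_recovery",
    "rate_test_type_i_error",
    "cr_modularity_power",
    "cr_type_i_error",
    "pls_null_uniformity",
]


def _child_seeds(seed: int, stream: int, n: int) -> np.ndarray:
    """n reproducible integer seeds below 2^31 for one experiment stream."""
    ss = np.random.SeedSequence((int(seed), int(stream)))
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) & 0x7FFFFFFF


def _aligned_study(spec: SimulationSpec):
    study = simulate_bm_shapes(spec)
    return study, gpa(study.dataset)


def _observed_ratio(aligned, tree, modules) -> float:
    first, second = module_order(modules)
    U = phylo_transform(aligned.tangent_means(), bm_covariance(tree, aligned.species))
    r1 = sigma_mult(U[:, modules.columns(first)], modules.count(first))
    r2 = sigma_mult(U[:, modules.columns(second)], modules.count(second))
    return r1 / r2


def rate_ratio_recovery(
    n_replicates: int = 20,
    n_species: int = 50,
    n_landmarks: int = 10,
    k_face: int = 5,
    sigma2_face: float = 0.02,
    sigma2_brain: float = 0.01,
    seed: int = 0,
) -> dict:
    """Recover a true face:braincase rate ratio from replicate studies."""
    seeds = _child_seeds(seed, 101, n_replicates)
    ratios = []
    for s in seeds:
        spec = SimulationSpec(
            n_species=n_species, n_landmarks=n_landmarks, k_face=k_face,
            sigma2_face=sigma2_face, sigma2_brain=sigma2_brain, seed=int(s),
        )
        study, aligned = _aligned_study(spec)
        ratios.append(_observed_ratio(aligned, study.tree, study.modules))
    ratios = np.array(ratios)
    return {
        "true_ratio": sigma2_face / sigma2_brain,
        "median_ratio": float(np.median(ratios)),
        "ratios": ratios,
        "n_replicates": n_replicates,
        "n_species": n_species,
    }


def rate_test_type_i_error(
    n_replicates: int = 200,
    n_species: int = 40,
    n_sim: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the equal-rates test when rates truly are equal."""
    seeds = _child_seeds(seed, 102, n_replicates)
    pvals = []
    for s in seeds:
        spec = SimulationSpec(n_species=n_species, seed=int(s))
        study, aligned = _aligned_study(spec)
        res = compare_module_rates(
            aligned, study.tree, study.modules, n_sim=n_sim, seed=int(s) + 1
        )
        pvals.append(res.p_value)
    pvals = np.array(pvals)
    return {
        "rejection_rate": float(np.mean(pvals <= alpha)),
        "alpha": alpha,
        "p_values": pvals,
        "n_replicates": n_replicates,
    }


def cr_modularity_power(
    n_replicates: int = 50,
    n_species: int = 100,
    within_correlation: float = 0.7,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Detection rate of the CR test on truly modular data (no
    between-module covariance, correlated within modules, star tree)."""
    seeds = _child_seeds(seed, 103, n_replicates)
    pvals = []
    for s in seeds:
        spec = SimulationSpec(
            n_species=n_species, rho=0.0, within_correlation=within_correlation,
            tree_model="star", seed=int(s),
        )
        study, aligned = _aligned_study(spec)
        res = cr_test(aligned, study.tree, study.modules, n_perm=n_perm, seed=int(s) + 1)
        pvals.append(res.p_value)
    pvals = np.array(pvals)
    return {
        "detection_rate": float(np.mean(pvals < alpha)),
        "p_values": pvals,
        "n_replicates": n_replicates,
    }


def cr_type_i_error(
    n_replicates: int = 200,
    n_species: int = 100,
    n_landmarks: int = 10,
    correlation: float = 0.3,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the CR test on fully integrated data: one
    covariance regime (equicorrelation) across all landmarks.

    The single regime is imposed directly on shape-space species means:
    superimposing any actual landmark geometry induces landmark-specific
    covariance, so exchangeability — the premise of a type-I calibration
    of the landmark-permutation null — only exists at the shape level.
    """
    from .gpa import AlignedShapes
    from .simulate import simulate_tree

    d = 2 * n_landmarks
    k = n_landmarks // 2
    modules = SimulationSpec(n_landmarks=n_landmarks, k_face=k).module_map()
    Sigma = np.full((d, d), correlation)
    np.fill_diagonal(Sigma, 1.0)
    A = np.linalg.cholesky(Sigma)
    species = sorted(f"t{i + 1:03d}" for i in range(n_species))
    tree = simulate_tree(n_species, seed=seed, model="star")
    # the uniform consensus direction keeps the projected covariance
    # exchangeable under landmark relabelling
    c = np.full(d, 1.0 / np.sqrt(d))
    seeds = _child_seeds(seed, 104, n_replicates)
    pvals = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        Y = rng.standard_normal((n_species, d)) @ A.T
        aligned = AlignedShapes.from_species_means(Y, species, consensus=c)
        res = cr_test(aligned, tree, modules, n_perm=n_perm, seed=int(s) + 1)
        pvals.append(res.p_value)
    pvals = np.array(pvals)
    return {
        "rejection_rate": float(np.mean(pvals <= alpha)),
        "alpha": alpha,
        "p_values": pvals,
        "n_replicates": n_replicates,
    }


def pls_null_uniformity(
    n_replicates: int = 50,
    n_species: int = 100,
    n_landmarks: int = 10,
    n_perm: int = 199,
    seed: int = 0,
) -> dict:
    """Permutation p-values of r-PLS on truly independent blocks: should
    be approximately uniform (mean near 0.5).

    Independence is imposed directly in shape space (block-diagonal
    evolutionary covariance on a pure-birth tree): superimposition always
    couples the blocks of one configuration, so an exact independence
    null exists only at the shape level.
    """
    from .gpa import AlignedShapes
    from .simulate import simulate_tree

    k = n_landmarks // 2
    dk = 2 * k
    modules = SimulationSpec(n_landmarks=n_landmarks, k_face=k).module_map()
    # within-block structure, between-block independence
    B = np.full((dk, dk), 0.5)
    np.fill_diagonal(B, 1.0)
    A = np.linalg.cholesky(B)
    # consensus supported on block 2 only: the tangent projection then
    # modifies block 2 as a function of block 2 alone
    c = np.zeros(2 * n_landmarks)
    c[dk:] = 1.0 / np.sqrt(dk)
    seeds = _child_seeds(seed, 105, n_replicates)
    pvals = []
    for i, s in enumerate(seeds):
        tree = simulate_tree(n_species, seed=int(s))
        species = sorted(tree.taxa)
        L = np.linalg.cholesky(bm_covariance(tree, species).C)
        rng = np.random.default_rng(int(s))
        Y1 = L @ rng.standard_normal((n_species, dk)) @ A.T
        Y2 = L @ rng.standard_normal((n_species, dk)) @ A.T
        aligned = AlignedShapes.from_species_means(np.hstack([Y1, Y2]), species, consensus=c)
        res = phylo_pls(aligned, tree, modules, n_perm=n_perm, seed=int(s) + 1)
        pvals.append(res.p_value)
    pvals = np.array(pvals)
    return {"mean_p": float(pvals.mean()), "p_values": pvals, "n_replicates": n_replicates}
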