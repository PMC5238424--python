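"""Multivariate Brownian-motion rates of module evolution.

The net rate of a module with k landmarks is sigma^2 = trace(U'U)/(n k)
on the module's GLS-transformed columns: the phylogenetically corrected
mean squared change per landmark per unit branch-length time.  Observed
face/braincase rate ratios are tested against a null distribution built
by simulating equal-rate Brownian motion on the same tree, preserving
the observed evolutionary correlation structure (integration inflates
the sampling variance of the ratio and therefore belongs in the null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gpa import AlignedShapes
from .io import ModuleMap, PhyloTree, normalize_taxon
from .phylo import BMStructure, bm_covariance, phylo_transform

__all__ = [
    "RateResult",
    "CladeRateTable",
    "sigma_mult",
    "compare_module_rates",
    "clade_rates",
]


@dataclass
class RateResult:
    rates: dict[str, float]  # per-landmark Procrustes variance per unit time
    ratio: float  # face / braincase (first / second reported module)
    ratio_labels: tuple[str, str]
    p_value: float
    null_ratios: np.ndarray
    n_sim: int
    two_sided: bool
    ultrametric: bool


@dataclass
class CladeRateTable:
    clades: list[str]
    rates: dict[str, dict[str, float]]  # clade -> module -> rate
    ratios: dict[str, float]  # clade -> face/braincase ratio
    pairwise_p: dict[str, np.ndarray]  # module -> symmetric (n_clades, n_clades)
    excluded: list[str]
    non_monophyletic: list[str]
    n_sim: int


def module_order(modules: ModuleMap) -> tuple[str, str]:
    """Report order for ratios: face over braincase when those are the
    labels, otherwise file order of first appearance."""
    if set(modules.labels) == {"face", "braincase"}:
        return ("face", "braincase")
    seen: dict[str, None] = {}
    for i in range(modules.n_landmarks):
        seen.setdefault(modules.assignments[i], None)
    first, second = list(seen)[:2]
    return (first, second)


def sigma_mult(U: np.ndarray, k: int) -> float:
    """Net evolutionary rate of a transformed block: trace(U'U)/(n k)."""
    if k <= 0:
        raise ValueError("landmark count k must be positive")
    U = np.asarray(U, dtype=float)
    return float(np.sum(U * U) / (U.shape[0] * k))


def _null_rate_matrix(U: np.ndarray) -> tuple[np.ndarray, float]:
    """Equal-rates null: observed evolutionary correlations scaled to a
    common per-coordinate variance (the pooled observed rate)."""
    n, d = U.shape
    E = U.T @ U / (n - 1)
    pooled = np.trace(E) / d
    sd = np.sqrt(np.clip(np.diag(E), 1e-300, None))
    Q = E / np.outer(sd, sd)
    np.fill_diagonal(Q, 1.0)
    vals, vecs = np.linalg.eigh(Q)
    floor = 1e-8 * vals.max()
    if vals.min() < floor:
        warnings.warn(
            "singular evolutionary correlation matrix; shrunk to nearest positive-definite",
            stacklevel=3,
        )
        vals = np.clip(vals, floor, None)
        Q = vecs @ np.diag(vals) @ vecs.T
        # renormalize to unit diagonal so the pooled rate stays the scale
        qd = np.sqrt(np.diag(Q))
        Q = Q / np.outer(qd, qd)
    return pooled * Q, pooled


def _module_stats(U2: np.ndarray, cols_by_module: dict[str, np.ndarray], k: dict[str, int], n: int):
    """Per-module rates from squared transformed data (supports a leading
    simulation axis)."""
    return {
        m: U2[..., cols].sum(axis=(-2, -1)) / (n * k[m]) for m, cols in cols_by_module.items()
    }


def compare_module_rates(
    aligned: AlignedShapes,
    tree: PhyloTree,
    modules: ModuleMap,
    n_sim: int = 999,
    seed: int | np.random.SeedSequence | None = None,
    two_sided: bool = True,
) -> RateResult:
    """Observed per-module rates and a simulation test of rate equality.

    The null simulates ``n_sim`` Brownian-motion datasets on the tree with
    a common per-landmark rate (the pooled observed rate) and the observed
    evolutionary correlation structure.  The default test statistic is
    max(ratio, 1/ratio); ``two_sided=False`` uses the raw ratio and an
    upper-tail proportion instead.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if not tree.is_ultrametric:
        warnings.warn("tree is not ultrametric; rates are still per unit branch length", stacklevel=2)
    Y = aligned.tangent_means()
    bm = bm_covariance(tree, aligned.species)
    U = phylo_transform(Y, bm)
    n = U.shape[0]
    first, second = module_order(modules)
    cols = {m: modules.columns(m) for m in (first, second)}
    k = {m: modules.count(m) for m in (first, second)}
    rates = {m: sigma_mult(U[:, cols[m]], k[m]) for m in (first, second)}
    if rates[second] <= 0:
        raise ValueError("degenerate data: zero rate in a module")
    ratio = rates[first] / rates[second]

    R0, _ = _null_rate_matrix(U)
    A = np.linalg.cholesky(R0)
    L = np.linalg.cholesky(bm.C)
    B = bm.centering @ L  # maps iid deviations to transformed tip data
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_sim, n, U.shape[1]))
    Ustar = np.einsum("ij,sjk,lk->sil", B, Z, A, optimize=True)
    null = _module_stats(Ustar**2, cols, k, n)
    null_ratio = null[first] / null[second]

    if two_sided:
        stat_obs = max(ratio, 1.0 / ratio)
        stat_null = np.maximum(null_ratio, 1.0 / null_ratio)
    else:
        stat_obs = ratio
        stat_null = null_ratio
    p = (np.sum(stat_null >= stat_obs) + 1.0) / (n_sim + 1.0)
    return RateResult(
        rates=rates,
        ratio=float(ratio),
        ratio_labels=(first, second),
        p_value=float(p),
        null_ratios=null_ratio,
        n_sim=n_sim,
        two_sided=two_sided,
        ultrametric=tree.is_ultrametric,
    )


def _is_monophyletic(tree: PhyloTree, species: set[str]) -> bool:
    taxa = [tx for tx in tree.tree.taxon_namespace if normalize_taxon(tx.label) in species]
    mrca = tree.tree.mrca(taxa=taxa)
    below = {normalize_taxon(lf.taxon.label) for lf in mrca.leaf_iter()}
    return below == species


def clade_rates(
    aligned: AlignedShapes,
    tree: PhyloTree,
    modules: ModuleMap,
    clades: dict[str, str],
    n_sim: int = 999,
    seed: int | np.random.SeedSequence | None = None,
) -> CladeRateTable:
    """Per-clade module rates and pairwise between-clade rate tests.

    Each clade's rates come from the GLS machinery on the induced subtree.
    Pairwise contrasts per module are tested against a single-rate null
    simulated on the full tree: for every simulated dataset the clade-wise
    rates are recomputed and the between-clade ratio statistic
    max(r, 1/r) collected.
    """
    species_set = set(aligned.species)
    groups: dict[str, list[str]] = {}
    for sp, label in clades.items():
        sp = normalize_taxon(sp)
        if sp in species_set:
            groups.setdefault(label, []).append(sp)
    excluded = [c for c, sps in groups.items() if len(sps) < 3]
    for c in excluded:
        warnings.warn(f"clade {c!r} has fewer than 3 species; excluded", stacklevel=2)
    groups = {c: sorted(sps) for c, sps in groups.items() if len(sps) >= 3}
    if not groups:
        raise ValueError("no clade with at least 3 species")
    non_mono = [c for c, sps in groups.items() if not _is_monophyletic(tree, set(sps))]
    for c in non_mono:
        warnings.warn(f"clade {c!r} is not monophyletic in the tree", stacklevel=2)

    first, second = module_order(modules)
    cols = {m: modules.columns(m) for m in (first, second)}
    k = {m: modules.count(m) for m in (first, second)}

    Y = aligned.tangent_means()
    full_bm = bm_covariance(tree, aligned.species)
    U_full = phylo_transform(Y, full_bm)
    sp_index = {s: i for i, s in enumerate(aligned.species)}

    clade_names = sorted(groups)
    clade_bm: dict[str, BMStructure] = {}
    clade_idx: dict[str, np.ndarray] = {}
    rates: dict[str, dict[str, float]] = {}
    ratios: dict[str, float] = {}
    for c in clade_names:
        sub = tree.prune_to(groups[c])
        bm_c = bm_covariance(sub, groups[c])
        idx = np.array([sp_index[s] for s in groups[c]])
        clade_bm[c] = bm_c
        clade_idx[c] = idx
        Uc = phylo_transform(Y[idx], bm_c)
        rates[c] = {m: sigma_mult(Uc[:, cols[m]], k[m]) for m in (first, second)}
        ratios[c] = rates[c][first] / rates[c][second]

    # single-rate null on the full tree, clade rates recomputed per simulation
    R0, _ = _null_rate_matrix(U_full)
    A = np.linalg.cholesky(R0)
    L = np.linalg.cholesky(full_bm.C)
    rng = np.random.default_rng(seed)
    d = Y.shape[1]
    n_full = len(aligned.species)
    null_rates = {m: np.empty((n_sim, len(clade_names))) for m in (first, second)}
    for s in range(n_sim):
        Ystar = L @ rng.standard_normal((n_full, d)) @ A.T
        for j, c in enumerate(clade_names):
            Uc = clade_bm[c].centering @ Ystar[clade_idx[c]]
            Uc2 = Uc * Uc
            for m in (first, second):
                null_rates[m][s, j] = Uc2[:, cols[m]].sum() / (len(clade_idx[c]) * k[m])

    pairwise_p = {}
    nc = len(clade_names)
    for m in (first, second):
        P = np.ones((nc, nc))
        for i in range(nc):
            for j in range(i + 1, nc):
                r_obs = rates[clade_names[i]][m] / rates[clade_names[j]][m]
                stat_obs = max(r_obs, 1.0 / r_obs)
                r_null = null_rates[m][:, i] / null_rates[m][:, j]
                stat_null = np.maximum(r_null, 1.0 / r_null)
                p = (np.sum(stat_null >= stat_obs) + 1.0) / (n_sim + 1.0)
                P[i, j] = P[j, i] = p
        pairwise_p[m] = P

    return CladeRateTable(
        clades=clade_names,
        rates=rates,
        ratios=ratios,
        pairwise_p=pairwise_p,
        excluded=sorted(excluded),
        non_monophyletic=sorted(non_mono),
        n_sim=n_sim,
    )
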