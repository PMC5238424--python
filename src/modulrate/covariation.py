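"""Phylogenetic modularity (covariance ratio) and integration (two-block PLS).

Both statistics are computed on GLS-transformed species means (see
:mod:`modulrate.phylo`), so covariances are evolutionary covariances under
Brownian motion.  The covariance-ratio coefficient CR is the Frobenius
norm of the between-module covariance block over the geometric mean of
the within-module norms with variances excluded; small CR relative to a
landmark-permutation null signals modularity.  r-PLS is the correlation
of the first pair of partial-least-squares block scores; 0 reads as
completely modular, 1 as completely integrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .gpa import AlignedShapes
from .io import ModuleMap, PhyloTree
from .phylo import bm_covariance, phylo_transform

__all__ = [
    "ModularityResult",
    "IntegrationResult",
    "cr_coefficient",
    "cr_test",
    "phylo_pls",
]


@dataclass
class ModularityResult:
    observed_cr: float
    permuted: np.ndarray
    p_value: float
    n_permutations: int
    module_sizes: dict[str, int]
    exact: bool = False


@dataclass
class IntegrationResult:
    r_pls: float
    p_value: float
    permuted: np.ndarray
    left_vector: np.ndarray
    right_vector: np.ndarray
    scores_left: np.ndarray
    scores_right: np.ndarray
    percent_covariance: float
    n_permutations: int


def _landmark_pair_sums(S: np.ndarray, p: int, exclude_same_landmark: bool) -> np.ndarray:
    """p x p matrix G with G[a, b] = sum of squared covariances between the
    coordinates of landmarks a and b.  The diagonal holds the same-landmark
    x/y cross terms (never the variances), or zero when those are excluded
    from the within-module norms."""
    G = np.empty((p, p))
    S2 = S * S
    for a in range(p):
        ra = slice(2 * a, 2 * a + 2)
        for b in range(p):
            G[a, b] = S2[ra, 2 * b : 2 * b + 2].sum()
    # strip variances from the diagonal; optionally also the x/y covariance
    for a in range(p):
        G[a, a] -= S2[2 * a, 2 * a] + S2[2 * a + 1, 2 * a + 1]
        if exclude_same_landmark:
            G[a, a] = 0.0
    return G


def _cr_from_pairs(G: np.ndarray, in_module1: np.ndarray) -> float:
    z = in_module1.astype(float)
    zc = 1.0 - z
    between = z @ G @ zc  # ordered coordinate pairs of the S12 block
    w1 = z @ G @ z
    w2 = zc @ G @ zc
    denom = np.sqrt(w1 * w2)
    if denom <= 0:
        raise ValueError(
            "within-module covariance norm is zero (a module with a single "
            "landmark has no off-diagonal block)"
        )
    return float(np.sqrt(between / denom))


def cr_coefficient(
    U: np.ndarray,
    modules: ModuleMap,
    exclude_same_landmark: bool = True,
) -> float:
    """Covariance-ratio coefficient of a transformed species x 2p matrix.

    With S = U'U/(n-1) partitioned by module, CR = ||S12||_F /
    sqrt(||S11*||_F ||S22*||_F) where * zeroes the variance diagonal (and,
    by default, the same-landmark x/y covariances)."""
    U = np.asarray(U, dtype=float)
    p = modules.n_landmarks
    if U.shape[1] != 2 * p:
        raise ValueError(f"expected {2 * p} columns for {p} landmarks, got {U.shape[1]}")
    S = U.T @ U / (U.shape[0] - 1)
    G = _landmark_pair_sums(S, p, exclude_same_landmark)
    in_m1 = np.zeros(p, dtype=bool)
    in_m1[modules.landmarks(modules.labels[0])] = True
    return _cr_from_pairs(G, in_m1)


def cr_test(
    aligned: AlignedShapes,
    tree: PhyloTree,
    modules: ModuleMap,
    n_perm: int = 9999,
    seed: int | np.random.SeedSequence | None = None,
    exclude_same_landmark: bool = True,
) -> ModularityResult:
    """Permutation test for modularity under Brownian motion.

    Whole landmarks (x and y together) are reassigned to pseudo-modules of
    the observed sizes; significance is the one-tailed probability of a
    permuted CR at or below the observed value, with the add-one rule.
    When ``n_perm`` exceeds the number of distinct assignments the full
    enumeration is used instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    p = modules.n_landmarks
    k1 = modules.count(modules.labels[0])
    Y = aligned.tangent_means()
    bm = bm_covariance(tree, aligned.species)
    U = phylo_transform(Y, bm)
    S = U.T @ U / (U.shape[0] - 1)
    G = _landmark_pair_sums(S, p, exclude_same_landmark)

    observed_mask = np.zeros(p, dtype=bool)
    observed_mask[modules.landmarks(modules.labels[0])] = True
    observed = _cr_from_pairs(G, observed_mask)

    n_distinct = comb(p, k1)
    if n_perm >= n_distinct:
        values = np.array(
            [_cr_from_pairs(G, _mask(p, idx)) for idx in combinations(range(p), k1)]
        )
        # the observed assignment is one of the enumerated ones
        p_value = float(np.sum(values <= observed + 1e-15) / n_distinct)
        return ModularityResult(
            observed_cr=observed,
            permuted=values,
            p_value=p_value,
            n_permutations=n_distinct,
            module_sizes={m: modules.count(m) for m in modules.labels},
            exact=True,
        )

    rng = np.random.default_rng(seed)
    values = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(p)[:k1]
        values[i] = _cr_from_pairs(G, _mask(p, idx))
    p_value = (np.sum(values <= observed) + 1.0) / (n_perm + 1.0)
    return ModularityResult(
        observed_cr=observed,
        permuted=values,
        p_value=float(p_value),
        n_permutations=n_perm,
        module_sizes={m: modules.count(m) for m in modules.labels},
    )


def _mask(p: int, idx) -> np.ndarray:
    m = np.zeros(p, dtype=bool)
    m[list(idx)] = True
    return m


def phylo_pls(
    aligned: AlignedShapes,
    tree: PhyloTree,
    modules: ModuleMap,
    n_perm: int = 9999,
    seed: int | np.random.SeedSequence | None = None,
) -> IntegrationResult:
    """Phylogenetic two-block partial least squares between modules.

    The first singular pair of the evolutionary cross-covariance matrix
    S12 = U1'U2/(n-1) gives block scores whose correlation is r-PLS.
    Significance: the rows of block 2 are permuted across the tips on the
    original species means, the GLS transform re-applied, and the observed
    r compared to the permuted ones (add-one rule, upper tail).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = aligned.tangent_means()
    n = Y.shape[0]
    if n < 4:
        raise ValueError("phylogenetic PLS requires at least 4 species")
    cols1 = modules.columns(modules.labels[0])
    cols2 = modules.columns(modules.labels[1])
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each block needs at least 2 columns")
    bm = bm_covariance(tree, aligned.species)
    M = bm.centering
    U1 = M @ Y[:, cols1]
    U2 = M @ Y[:, cols2]
    if np.allclose(U1, 0) or np.allclose(U2, 0):
        raise ValueError("constant block: correlation undefined")

    r_obs, v1, w1, s = _first_pair(U1, U2)
    scores1 = U1 @ v1
    scores2 = U2 @ w1
    percent = float(s[0] ** 2 / np.sum(s**2) * 100.0)

    rng = np.random.default_rng(seed)
    Y2 = Y[:, cols2]
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        U2p = M @ Y2[perm]
        permuted[i], _, _, _ = _first_pair(U1, U2p)
    p_value = (np.sum(permuted >= r_obs) + 1.0) / (n_perm + 1.0)
    return IntegrationResult(
        r_pls=r_obs,
        p_value=float(p_value),
        permuted=permuted,
        left_vector=v1,
        right_vector=w1,
        scores_left=scores1,
        scores_right=scores2,
        percent_covariance=percent,
        n_permutations=n_perm,
    )


def _first_pair(U1: np.ndarray, U2: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    S12 = U1.T @ U2 / (U1.shape[0] - 1)
    u, s, vt = np.linalg.svd(S12, full_matrices=False)
    v1, w1 = u[:, 0], vt[0]
    a = U1 @ v1
    b = U2 @ w1
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom <= 0:
        raise ValueError("degenerate block scores: correlation undefined")
    # scores are GLS-centered already, so this is a correlation about zero;
    # v1'S12 w1 = s[0] >= 0 guarantees r >= 0
    r = float((a @ b) / denom)
    return r, v1, w1, s
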