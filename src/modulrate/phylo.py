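"""Brownian-motion comparative machinery.

Everything downstream of the geometry layer runs through the same
generalized-least-squares transform: with C the n x n matrix of shared
branch lengths implied by the tree, C = L L', T = L^-1, and
w = (1'C^-1 1)^-1 1'C^-1 the GLS root weights, the transform
U = T (Y - 1 a) with a = w Y turns tip data into uncorrelated,
unit-variance-per-unit-time deviations whose cross-product U'U is the
evolutionary sums-of-squares-and-cross-products matrix (the same
quantity phylogenetically independent contrasts estimate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import PhyloTree, normalize_taxon

__all__ = [
    "BMStructure",
    "AncestralStates",
    "bm_covariance",
    "phylo_transform",
    "ancestral_states",
    "phylomorphospace",
]

_MAX_CONDITION = 1e12


@dataclass
class BMStructure:
    """Tree-implied covariance and its GLS factorizations for one ordering."""

    ordering: list[str]
    C: np.ndarray  # (n, n) shared branch lengths
    depths: np.ndarray  # root-to-tip depths (= diag of C)
    T: np.ndarray  # inverse Cholesky factor: T' T = C^-1
    root_weights: np.ndarray  # (n,) GLS weights, sum to 1
    centering: np.ndarray  # (n, n): T (I - 1 w), applied to tip data

    @property
    def n(self) -> int:
        return len(self.ordering)


def _shared_path_matrix(tree: PhyloTree, ordering: list[str]) -> np.ndarray:
    index = {normalize_taxon(name): i for i, name in enumerate(ordering)}
    n = len(ordering)
    C = np.zeros((n, n))
    t = tree.tree
    t.calc_node_root_distances(return_leaf_distances_only=False)
    for node in t.postorder_node_iter():
        if node.is_leaf():
            label = normalize_taxon(node.taxon.label)
            if label not in index:
                raise ValueError(f"tree tip {label!r} not in requested ordering")
            i = index[label]
            C[i, i] = node.root_distance
            node._tips_below = [i]
        else:
            depth = node.root_distance if node.parent_node is not None else 0.0
            child_sets = [c._tips_below for c in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        C[i, child_sets[b]] = depth
                        C[np.asarray(child_sets[b]), i] = depth
            node._tips_below = [i for s in child_sets for i in s]
    return C


def bm_covariance(tree: PhyloTree, ordering: list[str] | None = None) -> BMStructure:
    """Brownian-motion covariance structure of a tree's tips.

    C[i, j] is the branch length shared by tips i and j on their paths
    from the root; the diagonal holds root-to-tip depths.
    """
    if ordering is None:
        ordering = sorted(tree.taxa)
    ordering = [normalize_taxon(s) for s in ordering]
    if sorted(ordering) != sorted(tree.taxa):
        raise ValueError("ordering must cover the tree tips exactly")
    C = _shared_path_matrix(tree, ordering)

    zero_tips = [ordering[i] for i in range(len(ordering)) if C[i, i] <= 0]
    if zero_tips:
        raise ValueError(f"tips with zero root-to-tip depth make C singular: {zero_tips}")
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        # zero-length terminal branches duplicate rows of C
        bad = _suspect_tips(tree, ordering)
        raise ValueError(
            f"phylogenetic covariance is numerically singular (cond={cond:.3g}); "
            f"suspect zero-length terminal branches at tips: {bad or 'unknown'}"
        )
    L = np.linalg.cholesky(C)
    T = scipy.linalg.solve_triangular(L, np.eye(len(ordering)), lower=True)
    Cinv = T.T @ T
    ones = np.ones(len(ordering))
    w = Cinv @ ones / (ones @ Cinv @ ones)
    centering = T @ (np.eye(len(ordering)) - np.outer(ones, w))
    return BMStructure(
        ordering=ordering,
        C=C,
        depths=np.diag(C).copy(),
        T=T,
        root_weights=w,
        centering=centering,
    )


def _suspect_tips(tree: PhyloTree, ordering: list[str]) -> list[str]:
    bad = []
    for leaf in tree.tree.leaf_node_iter():
        if leaf.edge.length is not None and leaf.edge.length <= 0:
            bad.append(normalize_taxon(leaf.taxon.label))
    return bad


def phylo_transform(Y: np.ndarray, bm: BMStructure) -> np.ndarray:
    """GLS transform U = T (Y - 1 a); rows of Y must follow ``bm.ordering``."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != bm.n:
        raise ValueError(f"Y has {Y.shape[0]} rows but the tree has {bm.n} tips")
    return bm.centering @ Y


def gls_root(Y: np.ndarray, bm: BMStructure) -> np.ndarray:
    """GLS estimate of the root state, a = w'Y."""
    return bm.root_weights @ np.atleast_2d(np.asarray(Y, dtype=float))


@dataclass
class AncestralStates:
    """BM maximum-likelihood states at internal nodes."""

    node_labels: list[str]
    states: np.ndarray  # (n_internal, d)
    root: np.ndarray  # (d,)
    tip_labels: list[str]


def ancestral_states(Y: np.ndarray, tree: PhyloTree, ordering: list[str] | None = None) -> AncestralStates:
    """Maximum-likelihood ancestral states under Brownian motion.

    Equivalent to branch-length-weighted squared-change parsimony: the
    estimates jointly minimize sum over branches of (change)^2 / length.
    Computed in closed form as the GLS conditional expectation
    a + C_anc,tips C^-1 (Y - 1 a).
    """
    if tree.tree.seed_node is None:
        raise ValueError("rooted tree required")
    bm = bm_covariance(tree, ordering)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != bm.n:
        raise ValueError("one row per tip required, ordered as the tree ordering")
    a = gls_root(Y, bm)
    index = {name: i for i, name in enumerate(bm.ordering)}

    t = tree.tree
    t.calc_node_root_distances(return_leaf_distances_only=False)
    internal = [nd for nd in t.preorder_node_iter() if not nd.is_leaf()]
    labels = []
    for k, nd in enumerate(internal):
        labels.append(nd.label if nd.label else f"node_{k}")
        nd._anc_idx = k

    # cross-covariance of each internal node with each tip: depth of their MRCA
    n_int = len(internal)
    cov = np.zeros((n_int, bm.n))
    # tips below each internal node share path = node depth; others share mrca depth,
    # found by walking up from the node
    for nd in internal:
        depth = nd.root_distance if nd.parent_node is not None else 0.0
        below = {index[normalize_taxon(lf.taxon.label)] for lf in nd.leaf_iter()}
        for i in below:
            cov[nd._anc_idx, i] = depth
        anc = nd.parent_node
        covered = set(below)
        while anc is not None:
            anc_depth = anc.root_distance if anc.parent_node is not None else 0.0
            anc_below = {index[normalize_taxon(lf.taxon.label)] for lf in anc.leaf_iter()}
            for i in anc_below - covered:
                cov[nd._anc_idx, i] = anc_depth
            covered |= anc_below
            anc = anc.parent_node

    resid = Y - a[None, :]
    Cinv_resid = bm.T.T @ (bm.T @ resid)
    states = a[None, :] + cov @ Cinv_resid
    root_idx = internal[0]._anc_idx if internal else None
    root = states[root_idx] if root_idx is not None else a
    return AncestralStates(node_labels=labels, states=states, root=root, tip_labels=list(bm.ordering))


@dataclass
class Phylomorphospace:
    """Tip and node coordinates plus an edge list for plotting."""

    tip_labels: list[str]
    tip_coords: np.ndarray  # (n_tips, 2)
    node_labels: list[str]
    node_coords: np.ndarray  # (n_internal, 2)
    edges: list[tuple[str, str]]  # (parent_label, child_label)


def phylomorphospace(scores: np.ndarray, species: list[str], tree: PhyloTree) -> Phylomorphospace:
    """Project a phylogeny into a 2-D ordination (PC1/PC2 by convention).

    Tips sit at their scores; internal nodes at their BM maximum-likelihood
    ancestral states on those scores (equivalent, by linearity of GLS, to
    reconstructing full shapes and projecting).
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    anc = ancestral_states(scores, tree, ordering=species)
    t = tree.tree
    node_label = {}
    k = 0
    for nd in t.preorder_node_iter():
        if not nd.is_leaf():
            node_label[nd] = anc.node_labels[k]
            k += 1
        else:
            node_label[nd] = normalize_taxon(nd.taxon.label)
    edges = []
    for nd in t.preorder_node_iter():
        if nd.parent_node is not None:
            edges.append((node_label[nd.parent_node], node_label[nd]))
    return Phylomorphospace(
        tip_labels=list(anc.tip_labels),
        tip_coords=scores,
        node_labels=list(anc.node_labels),
        node_coords=anc.states,
        edges=edges,
    )
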