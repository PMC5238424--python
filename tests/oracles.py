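"""Independent oracles: brute-force or closed-form implementations kept
deliberately separate from the package's code paths."""

from __future__ import annotations

import numpy as np

from modulrate.io import PhyloTree, normalize_taxon


def grid_rotation_distance(a: np.ndarray, b: np.ndarray, step: float = 1e-5) -> float:
    """Minimum distance between pre-centered, pre-scaled 2-D configurations
    over a brute-force grid of rotation angles."""
    pa = a - a.mean(axis=0)
    pa /= np.sqrt((pa**2).sum())
    pb = b - b.mean(axis=0)
    pb /= np.sqrt((pb**2).sum())
    theta = np.arange(0.0, 2 * np.pi, step)
    # ||R(t) pb - pa||^2 = 2 - 2 (cos t * s + sin t * c) with
    # s = sum(pb * pa), c = sum(cross terms); evaluate on the grid
    s = float((pb * pa).sum())
    c = float((pb[:, 0] * pa[:, 1] - pb[:, 1] * pa[:, 0]).sum())
    d2 = 2.0 - 2.0 * (np.cos(theta) * s + np.sin(theta) * c)
    return float(np.sqrt(d2.min()))


def pic_contrasts(tree: PhyloTree, Y: np.ndarray, ordering: list[str]) -> np.ndarray:
    """Felsenstein's phylogenetically independent contrasts by the pruning
    algorithm.  Returns the standardized contrasts, one row per internal
    node-merge (polytomies resolved by sequential pairing)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    index = {normalize_taxon(s): i for i, s in enumerate(ordering)}
    contrasts: list[np.ndarray] = []

    def prune(node):
        # returns (state, extra_branch_length_to_add_to_parent_edge)
        if node.is_leaf():
            return Y[index[normalize_taxon(node.taxon.label)]].copy(), 0.0
        children = []
        for ch in node.child_nodes():
            x, extra = prune(ch)
            children.append((x, ch.edge.length + extra))
        # sequentially merge children (exact for bifurcations)
        x1, v1 = children[0]
        for x2, v2 in children[1:]:
            contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
            x1 = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
            v1 = v1 * v2 / (v1 + v2)
        return x1, v1

    prune(tree.tree.seed_node)
    return np.array(contrasts)


def weighted_squared_change_states(tree: PhyloTree, y: np.ndarray, ordering: list[str]) -> np.ndarray:
    """Internal-node states minimizing sum over branches of
    (change)^2 / branch length, by direct numerical optimization."""
    from scipy.optimize import minimize

    y = np.asarray(y, dtype=float)
    index = {normalize_taxon(s): i for i, s in enumerate(ordering)}
    internal = [nd for nd in tree.tree.preorder_node_iter() if not nd.is_leaf()]
    pos = {nd: i for i, nd in enumerate(internal)}

    edges = []
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        parent = pos[nd.parent_node]
        if nd.is_leaf():
            edges.append((parent, None, index[normalize_taxon(nd.taxon.label)], nd.edge.length))
        else:
            edges.append((parent, pos[nd], None, nd.edge.length))

    def objective(states):
        total = 0.0
        for parent, child, tip, length in edges:
            target = y[tip] if tip is not None else states[child]
            total += (states[parent] - target) ** 2 / length
        return total

    x0 = np.full(len(internal), y.mean())
    res = minimize(objective, x0, method="BFGS", options={"gtol": 1e-12, "maxiter": 10000})
    return res.x


def cr_elementwise(
    U: np.ndarray, module1_landmarks, p: int, exclude_same_landmark: bool = True
) -> float:
    """Covariance-ratio coefficient by direct element-wise evaluation."""
    U = np.asarray(U, dtype=float)
    S = U.T @ U / (U.shape[0] - 1)
    in1 = np.zeros(p, dtype=bool)
    in1[list(module1_landmarks)] = True
    lm_of = np.repeat(np.arange(p), 2)
    between = within1 = within2 = 0.0
    d = 2 * p
    for i in range(d):
        for j in range(d):
            a, b = lm_of[i], lm_of[j]
            if in1[a] != in1[b]:
                if in1[a]:  # count each ordered pair of the S12 block once
                    between += S[i, j] ** 2
                continue
            if i == j:
                continue
            if a == b and exclude_same_landmark:
                continue
            if in1[a]:
                within1 += S[i, j] ** 2
            else:
                within2 += S[i, j] ** 2
    return float(np.sqrt(between / np.sqrt(within1 * within2)))


def plain_two_block_pls(Y1: np.ndarray, Y2: np.ndarray) -> float:
    """Ordinary (non-phylogenetic) two-block PLS correlation of the first
    singular pair, on column-centered data."""
    Y1 = Y1 - Y1.mean(axis=0)
    Y2 = Y2 - Y2.mean(axis=0)
    S12 = Y1.T @ Y2 / (Y1.shape[0] - 1)
    u, s, vt = np.linalg.svd(S12, full_matrices=False)
    a = Y1 @ u[:, 0]
    b = Y2 @ vt[0]
    return float((a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))
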