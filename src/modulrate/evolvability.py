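"""Random-skewers evolvability indices from phylogenetic P-matrices.

A module's P-matrix is the evolutionary variance-covariance matrix of its
shape coordinates — U'U/(n-1) on GLS-transformed species means, the same
quantity the covariance of phylogenetically independent contrasts
estimates.  Random skewers probe it with unit selection gradients beta
via the multivariate breeder's equation (response = P beta) and summarize
evolvability e = b'Pb, respondability r = ||Pb||, conditional
evolvability c = (b'P^-b)^-1, autonomy a = c/e, and constraints = |cos|
of the angle between the response and the leading eigenvector of P (the
line of least evolutionary resistance).

Procrustes P-matrices are rank-deficient (superimposition removes four
degrees of freedom from 2-D configurations), so every product is
evaluated in the positive eigenspace of P, where the Hansen-Houle
inequalities c <= e <= r and a in (0, 1] hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpa import AlignedShapes
from .io import ModuleMap, PhyloTree
from .phylo import bm_covariance, phylo_transform

__all__ = [
    "PMatrix",
    "SkewerResult",
    "evolutionary_pmatrix",
    "draw_skewers",
    "skewer_indices",
]

INDEX_NAMES = ("evolvability", "respondability", "conditional_evolvability", "autonomy", "constraints")


@dataclass
class PMatrix:
    module: str
    matrix: np.ndarray  # (d, d) symmetric PSD
    eigenvalues: np.ndarray  # descending
    effective_rank: int

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[0])


@dataclass
class SkewerResult:
    module: str
    raw: dict[str, np.ndarray]  # index name -> per-skewer values
    summary: dict[str, dict[str, float]]  # index name -> {mean, min, max}
    responses: np.ndarray  # (n_skewers, d) response vectors P beta
    n_skewers: int


def evolutionary_pmatrix(
    aligned: AlignedShapes,
    tree: PhyloTree,
    modules: ModuleMap,
    module: str,
) -> PMatrix:
    """Phylogenetically corrected P-matrix of one module's coordinates."""
    if module not in modules.labels:
        raise ValueError(f"unknown module {module!r}; have {modules.labels}")
    if len(aligned.species) < 4:
        raise ValueError("P-matrix estimation requires at least 4 species")
    Y = aligned.tangent_means()
    bm = bm_covariance(tree, aligned.species)
    U = phylo_transform(Y[:, modules.columns(module)], bm)
    P = U.T @ U / (U.shape[0] - 1)
    P = (P + P.T) / 2.0
    vals = np.linalg.eigvalsh(P)[::-1]
    rank = int(np.sum(vals > 1e-10 * max(vals[0], 1e-300)))
    return PMatrix(module=module, matrix=P, eigenvalues=vals, effective_rank=rank)


def pmatrix_from_array(matrix: np.ndarray, module: str = "module") -> PMatrix:
    """Wrap a plain symmetric PSD array as a PMatrix."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("square matrix required")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    M = (M + M.T) / 2.0
    vals = np.linalg.eigvalsh(M)[::-1]
    if vals[-1] < -1e-10 * max(abs(vals[0]), 1.0):
        raise ValueError("matrix is not positive semidefinite")
    rank = int(np.sum(vals > 1e-10 * max(vals[0], 1e-300)))
    return PMatrix(module=module, matrix=M, eigenvalues=vals, effective_rank=rank)


def draw_skewers(
    d: int, n: int = 1000, seed: int | np.random.SeedSequence | None = None
) -> np.ndarray:
    """n random unit selection gradients, uniform on the (d-1)-sphere.

    Independent standard-normal coordinates, normalized to unit length;
    reproducible for a given seed.
    """
    if d < 1 or n < 1:
        raise ValueError("d and n must be >= 1")
    rng = np.random.default_rng(seed)
    betas = rng.standard_normal((n, d))
    norms = np.linalg.norm(betas, axis=1, keepdims=True)
    # a zero draw has probability zero; guard anyway
    norms[norms == 0] = 1.0
    return betas / norms


def skewer_indices(
    P: PMatrix | np.ndarray,
    skewers: np.ndarray,
    rel_tol: float = 1e-10,
) -> SkewerResult:
    """Evolvability indices of a P-matrix over a set of selection gradients.

    Each beta is projected into the positive eigenspace of P (eigenvalues
    above ``rel_tol`` times the largest) and renormalized there, so the
    pseudo-inverse in conditional evolvability is well defined and
    c <= e <= r with autonomy in (0, 1] is guaranteed.
    """
    if not isinstance(P, PMatrix):
        P = pmatrix_from_array(P)
    vals, vecs = np.linalg.eigh(P.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > rel_tol * max(vals[0], 0.0)
    if not np.any(keep):
        raise ValueError("rank-0 P-matrix: no positive eigenvalues")
    lam = vals[keep]
    V = vecs[:, keep]
    leading = V[:, 0]

    skewers = np.atleast_2d(np.asarray(skewers, dtype=float))
    if skewers.shape[1] != P.dim:
        raise ValueError(f"skewers have dimension {skewers.shape[1]}, P has {P.dim}")
    B = skewers @ V  # eigenspace coefficients
    norms = np.linalg.norm(B, axis=1)
    if np.any(norms <= 0):
        raise ValueError("a skewer is orthogonal to the positive eigenspace of P")
    B = B / norms[:, None]

    e = B**2 @ lam
    r = np.sqrt(B**2 @ lam**2)
    c = 1.0 / (B**2 @ (1.0 / lam))
    a = c / e
    responses = (B * lam) @ V.T  # P beta, evaluated in the eigenspace
    constraints = np.abs(responses @ leading) / np.linalg.norm(responses, axis=1)

    raw = dict(zip(INDEX_NAMES, (e, r, c, a, constraints)))
    summary = {
        name: {"mean": float(v.mean()), "min": float(v.min()), "max": float(v.max())}
        for name, v in raw.items()
    }
    return SkewerResult(
        module=P.module,
        raw=raw,
        summary=summary,
        responses=responses,
        n_skewers=skewers.shape[0],
    )
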