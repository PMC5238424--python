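"""Generalized Procrustes superimposition and shape PCA.

Partial Procrustes superimposition: every configuration is centered,
scaled to unit centroid size and rotated (no reflection) to the running
consensus until the consensus stabilises.  Species means are the averages
of aligned conspecific specimens, rescaled to unit centroid size.
Downstream statistics operate on tangent-space coordinates — the
orthogonal projection of aligned shapes onto the tangent plane at the
consensus — flattened in (x1, y1, ..., xp, yp) order so that module
column blocks are contiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import LandmarkDataset

__all__ = ["AlignedShapes", "ShapeSpace", "gpa", "shape_pca", "procrustes_distance"]


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    centered = config - config.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||source @ R - target||_F."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


@dataclass
class AlignedShapes:
    """Result of generalized Procrustes analysis."""

    specimen_ids: list[str]
    species_ids: list[str]
    aligned: np.ndarray  # (n_specimens, p, 2), Procrustes units
    centroid_sizes: np.ndarray  # (n_specimens,), original units
    consensus: np.ndarray  # (p, 2)
    species: list[str]  # sorted unique species labels
    species_means: np.ndarray  # (n_species, 2p) flattened, unit centroid size
    iterations_used: int
    converged: bool

    @property
    def n_landmarks(self) -> int:
        return int(self.aligned.shape[1])

    @classmethod
    def from_species_means(
        cls,
        species_means: np.ndarray,
        species: list[str],
        consensus: np.ndarray | None = None,
    ) -> "AlignedShapes":
        """Wrap an already-superimposed species x 2p matrix (rows in sorted
        species order) as an AlignedShapes, e.g. for data simulated directly
        in shape space."""
        Y = np.asarray(species_means, dtype=float)
        n, d = Y.shape
        p = d // 2
        if sorted(species) != list(species):
            raise ValueError("rows must follow sorted species order")
        if consensus is None:
            c = np.zeros(d)
            c[:] = 1.0 / np.sqrt(d)
        else:
            c = np.asarray(consensus, dtype=float).ravel()
            c = c / np.linalg.norm(c)
        return cls(
            specimen_ids=list(species),
            species_ids=list(species),
            aligned=Y.reshape(n, p, 2),
            centroid_sizes=np.ones(n),
            consensus=c.reshape(p, 2),
            species=list(species),
            species_means=Y,
            iterations_used=0,
            converged=True,
        )

    def tangent_means(self) -> np.ndarray:
        """Species means orthogonally projected onto the tangent plane at
        the consensus; the coordinates all downstream statistics consume."""
        c = self.consensus.ravel()
        c = c / np.linalg.norm(c)
        return self.species_means - np.outer(self.species_means @ c, c)


@dataclass
class ShapeSpace:
    """Principal-components summary of species-mean shape variation."""

    eigenvalues: np.ndarray  # descending, >= 0
    loadings: np.ndarray  # (2p, n_components), orthonormal columns
    scores: np.ndarray  # (n_species, n_components)
    proportion_variance: np.ndarray
    species: list[str]
    center: np.ndarray  # grand mean of tangent coordinates


def gpa(dataset: LandmarkDataset, tol: float = 1e-10, max_iter: int = 100) -> AlignedShapes:
    """Iterative generalized Procrustes superimposition.

    Convergence is declared when the root-mean-square displacement of the
    consensus between iterations falls below ``tol``.
    """
    configs = dataset.coordinates.astype(float)
    n, p, _ = configs.shape
    if p < 3:
        raise ValueError("superimposition requires at least 3 landmarks")
    sizes = np.empty(n)
    scaled = np.empty_like(configs)
    for i in range(n):
        centered = configs[i] - configs[i].mean(axis=0)
        cs = np.sqrt((centered**2).sum())
        if cs <= 0:
            raise ValueError(
                f"specimen {dataset.specimen_ids[i]!r} has zero centroid size (all landmarks coincident)"
            )
        sizes[i] = cs
        scaled[i] = centered / cs

    # align everything to the first configuration, then iterate on the mean
    consensus = scaled[0].copy()
    aligned = scaled.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = scaled[i] @ _optimal_rotation(scaled[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.sqrt((new_consensus**2).sum())
        if norm <= 0:
            raise ValueError("degenerate consensus (all configurations cancel)")
        new_consensus /= norm
        shift = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge after {max_iter} iterations", stacklevel=2)

    # final pass against the converged consensus
    for i in range(n):
        aligned[i] = scaled[i] @ _optimal_rotation(scaled[i], consensus)

    species = sorted(set(dataset.species_ids))
    species_means = np.empty((len(species), 2 * p))
    labels = np.asarray(dataset.species_ids)
    for k, sp in enumerate(species):
        mean_cfg = aligned[labels == sp].mean(axis=0)
        mean_cfg -= mean_cfg.mean(axis=0)
        cs = np.sqrt((mean_cfg**2).sum())
        species_means[k] = (mean_cfg / cs).ravel()

    return AlignedShapes(
        specimen_ids=list(dataset.specimen_ids),
        species_ids=list(dataset.species_ids),
        aligned=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        species=species,
        species_means=species_means,
        iterations_used=iterations,
        converged=converged,
    )


def shape_pca(aligned: AlignedShapes, n_components: int | None = None) -> ShapeSpace:
    """Eigendecomposition of the covariance of flattened species means.

    Scores are centered tangent-space species means projected on the
    orthonormal loadings; with all components retained they reproduce
    pairwise Euclidean distances among species means exactly.
    """
    means = aligned.tangent_means()
    n_species, d = means.shape
    if n_species < 3:
        raise ValueError("shape PCA requires at least 3 species")
    center = means.mean(axis=0)
    centered = means - center
    cov = centered.T @ centered / (n_species - 1)
    eigenvalues, vectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    vectors = vectors[:, order]

    rank = int(np.sum(eigenvalues > 1e-12 * max(eigenvalues[0], 1e-300)))
    if n_components is None:
        n_components = rank
    elif n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    total = eigenvalues.sum()
    proportion = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return ShapeSpace(
        eigenvalues=eigenvalues[:n_components],
        loadings=vectors[:, :n_components],
        scores=centered @ vectors[:, :n_components],
        proportion_variance=proportion[:n_components],
        species=list(aligned.species),
        center=center,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, then ``b`` is
    rotated optimally onto ``a``.
    """
    pa = a - a.mean(axis=0)
    pa /= np.sqrt((pa**2).sum())
    pb = b - b.mean(axis=0)
    pb /= np.sqrt((pb**2).sum())
    rb = pb @ _optimal_rotation(pb, pa)
    return float(np.linalg.norm(rb - pa))
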