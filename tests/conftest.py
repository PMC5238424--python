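import numpy as np
import pytest

from modulrate.gpa import gpa
from modulrate.io import tree_from_newick
from modulrate.simulate import SimulationSpec, simulate_bm_shapes


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (40 species, 10 landmarks, 5+5 modules)."""
    return simulate_bm_shapes(SimulationSpec(seed=42))


@pytest.fixture(scope="session")
def default_aligned(default_study):
    return gpa(default_study.dataset)


@pytest.fixture(scope="session")
def integrated_study():
    """Strongly integrated study: equal rates, cross-correlation 0.9."""
    spec = SimulationSpec(n_species=60, rho=0.9, within_correlation=0.0, seed=7)
    return simulate_bm_shapes(spec)


@pytest.fixture
def five_tip_tree():
    return tree_from_newick("(((A:1,B:1):1,(C:1.5,D:0.5):0.5):1,E:3);")


@pytest.fixture
def triangle():
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])


def orthogonal_map_study(seed=0, n=20, k=4, scale=1.7):
    """Aligned species means, star tree and module map where the braincase
    block is an orthogonal, scaled copy of the face block (within the
    tangent plane of the consensus), so r-PLS must equal 1 exactly."""
    from modulrate.io import ModuleMap

    rng = np.random.default_rng(seed)
    d = 4 * k
    c = rng.normal(size=d)
    c /= np.linalg.norm(c)
    A = scale * np.linalg.qr(rng.normal(size=(2 * k, 2 * k)))[0]
    v = c[: 2 * k] + A @ c[2 * k :]
    Y1 = rng.normal(size=(n, 2 * k))
    Y1 -= np.outer(Y1 @ v, v) / (v @ v)  # rows of [Y1, Y1 A] orthogonal to c
    Y = np.hstack([Y1, Y1 @ A])
    species = [f"t{i:02d}" for i in range(n)]
    aligned = make_aligned_stub(Y, species, consensus=c)
    tree = tree_from_newick("(" + ",".join(f"{s}:1" for s in species) + ");")
    modules = ModuleMap({i: ("face" if i < k else "braincase") for i in range(2 * k)})
    return aligned, tree, modules


def make_aligned_stub(Y, species, consensus=None):
    """AlignedShapes carrying arbitrary flattened species means already
    orthogonal to the consensus (so tangent projection is the identity)."""
    from modulrate.gpa import AlignedShapes

    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    p = d // 2
    if consensus is None:
        consensus = np.zeros(d)
        consensus[-1] = 1.0  # unit vector off the data's support by construction
    c = consensus / np.linalg.norm(consensus)
    Yt = Y - np.outer(Y @ c, c)
    return AlignedShapes(
        specimen_ids=list(species),
        species_ids=list(species),
        aligned=Yt.reshape(n, p, 2),
        centroid_sizes=np.ones(n),
        consensus=c.reshape(p, 2),
        species=sorted(species),
        species_means=Yt[np.argsort(species)],
        iterations_used=1,
        converged=True,
    )
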