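"""Readers and writers for the formats the pipeline touches.

Landmark data arrive as TPS files (the tpsDig2 dialect: an ``LM=p`` header,
``p`` whitespace-separated ``x y`` rows, then ``ID=``/``IMAGE=``/``SCALE=``
records per specimen).  Trees arrive as Newick or NEXUS with branch lengths
in time units.  Module hypotheses arrive as two-column CSV
(``landmark_index,module``).  Landmark indices are 1-based in every file and
message, 0-based internally.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "LandmarkDataset",
    "ModuleMap",
    "PhyloTree",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "read_tree",
    "read_module_map",
    "write_module_map",
    "match_taxa",
    "normalize_taxon",
]


class TPSParseError(ValueError):
    """Raised for malformed TPS input."""


def normalize_taxon(name: str) -> str:
    """Canonical taxon name: trimmed, internal whitespace collapsed to '_'."""
    return re.sub(r"\s+", "_", name.strip())


@dataclass
class LandmarkDataset:
    """Named 2-D landmark configurations with species labels.

    ``coordinates`` has shape (n_specimens, p, 2), in image units.
    """

    specimen_ids: list[str]
    species_ids: list[str]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.specimen_ids)
        if len(self.species_ids) != n:
            raise ValueError("one species label per specimen required")
        self.species_ids = [normalize_taxon(s) for s in self.species_ids]
        if len(set(self.specimen_ids)) != n:
            dupes = sorted({s for s in self.specimen_ids if self.specimen_ids.count(s) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")
        if self.coordinates.ndim != 3 or self.coordinates.shape[0] != n or self.coordinates.shape[2] != 2:
            raise ValueError("coordinates must have shape (n_specimens, p, 2)")
        if self.coordinates.shape[1] < 1:
            raise ValueError("at least 1 landmark required")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite landmark coordinates")

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_landmarks(self) -> int:
        return int(self.coordinates.shape[1])

    @property
    def species(self) -> list[str]:
        """Unique species labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.species_ids:
            seen.setdefault(s, None)
        return list(seen)

    def subset_species(self, keep: list[str]) -> "LandmarkDataset":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.species_ids) if s in keep_set]
        return LandmarkDataset(
            [self.specimen_ids[i] for i in idx],
            [self.species_ids[i] for i in idx],
            self.coordinates[idx],
        )


@dataclass
class ModuleMap:
    """Assignment of every landmark to exactly one of two modules."""

    assignments: dict[int, str]  # 0-based landmark index -> module label

    def __post_init__(self) -> None:
        p = len(self.assignments)
        if sorted(self.assignments) != list(range(p)):
            raise ValueError("module map must cover landmarks 1..p exactly once")
        labels = sorted(set(self.assignments.values()))
        if len(labels) != 2:
            raise ValueError(f"exactly two modules required, got {labels}")
        self.labels = labels
        if any(self.count(m) == 0 for m in labels):
            raise ValueError("both modules must be non-empty")

    @property
    def n_landmarks(self) -> int:
        return len(self.assignments)

    def count(self, label: str) -> int:
        return sum(1 for v in self.assignments.values() if v == label)

    def landmarks(self, label: str) -> np.ndarray:
        """0-based landmark indices of a module, ascending."""
        return np.array(sorted(i for i, v in self.assignments.items() if v == label), dtype=int)

    def columns(self, label: str) -> np.ndarray:
        """Column indices of a module in (x1,y1,...,xp,yp) flattened order."""
        lm = self.landmarks(label)
        return np.sort(np.concatenate([2 * lm, 2 * lm + 1]))

    def landmark_vector(self) -> np.ndarray:
        """Per-landmark module label as an array of strings."""
        return np.array([self.assignments[i] for i in range(self.n_landmarks)])


@dataclass
class PhyloTree:
    """Rooted, branch-length-annotated phylogeny (wraps a dendropy Tree)."""

    tree: dendropy.Tree
    ultrametric_tol: float = 1e-6

    def __post_init__(self) -> None:
        labels = self.taxa
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                raise ValueError("branch lengths required on every edge")
            if edge.length < 0:
                raise ValueError("negative branch length")
        if len(self.tree.seed_node.child_nodes()) < 2:
            # a unifurcating root usually indicates an unrooted input
            raise ValueError("root must have degree >= 2")

    @property
    def taxa(self) -> list[str]:
        return [normalize_taxon(leaf.taxon.label) for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            normalize_taxon(leaf.taxon.label): leaf.root_distance
            for leaf in self.tree.leaf_node_iter()
        }

    @property
    def height(self) -> float:
        return max(self.tip_depths().values())

    @property
    def is_ultrametric(self) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return bool(np.ptp(d) <= self.ultrametric_tol * max(d.max(), 1.0))

    def prune_to(self, keep: list[str]) -> "PhyloTree":
        """Induced subtree on ``keep``; patristic distances are preserved."""
        t = self.tree.clone(depth=1)
        keep_norm = {normalize_taxon(k) for k in keep}
        taxa = [tx for tx in t.taxon_namespace if normalize_taxon(tx.label) in keep_norm]
        t.retain_taxa(taxa)
        # retain_taxa suppresses unifurcations and merges branch lengths
        return PhyloTree(t, self.ultrametric_tol)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tps(path: str | Path) -> LandmarkDataset:
    """Parse a tpsDig2-style TPS file of 2-D landmarks.

    SCALE records are applied multiplicatively; specimen order is preserved.
    3-D files (``LM3=``) are rejected: the pipeline is strictly 2-D.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise TPSParseError(f"{path}: empty TPS file")

    specimens: list[dict] = []
    current: dict | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"^(LM3?|ID|IMAGE|SCALE)\s*=\s*(.*)$", line, flags=re.IGNORECASE)
        if m:
            key, value = m.group(1).upper(), m.group(2).strip()
            if key == "LM3":
                raise TPSParseError(f"{path}:{lineno}: 3-D landmark data (LM3=) not supported")
            if key == "LM":
                if current is not None:
                    specimens.append(current)
                current = {"lm": int(value), "rows": [], "id": None, "scale": 1.0, "image": None}
            elif current is None:
                raise TPSParseError(f"{path}:{lineno}: {key}= record before any LM= header")
            elif key == "ID":
                current["id"] = value
            elif key == "SCALE":
                current["scale"] = float(value)
            elif key == "IMAGE":
                current["image"] = value
        else:
            if current is None:
                raise TPSParseError(f"{path}:{lineno}: coordinate row before any LM= header")
            parts = line.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path}:{lineno}: expected 'x y' coordinate row, got {line!r}"
                )
            try:
                current["rows"].append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(f"{path}:{lineno}: unparseable coordinates {line!r}") from exc
    if current is not None:
        specimens.append(current)
    if not specimens:
        raise TPSParseError(f"{path}: no specimens found")

    specimen_ids, species_ids, coords = [], [], []
    p = specimens[0]["lm"]
    for i, spec in enumerate(specimens):
        sid = spec["id"] if spec["id"] is not None else f"specimen_{i + 1}"
        if spec["lm"] != len(spec["rows"]):
            raise TPSParseError(
                f"{path}: specimen {sid!r}: LM={spec['lm']} but {len(spec['rows'])} coordinate rows"
            )
        if spec["lm"] != p:
            raise TPSParseError(
                f"{path}: specimen {sid!r}: landmark count {spec['lm']} differs from first specimen ({p})"
            )
        if sid in specimen_ids:
            raise TPSParseError(f"{path}: duplicate specimen ID {sid!r}")
        specimen_ids.append(sid)
        # species label: strip a trailing specimen suffix "species__n" if present
        species_ids.append(normalize_taxon(sid.rsplit("__", 1)[0]))
        coords.append(np.asarray(spec["rows"], dtype=float) * spec["scale"])
    return LandmarkDataset(specimen_ids, species_ids, np.stack(coords))


def write_tps(dataset: LandmarkDataset, path: str | Path, precision: int = 10) -> None:
    """Write a dataset back to TPS; inverse of :func:`read_tps` up to formatting."""
    lines = []
    for i, sid in enumerate(dataset.specimen_ids):
        lines.append(f"LM={dataset.n_landmarks}")
        for x, y in dataset.coordinates[i]:
            lines.append(f"{x:.{precision}f} {y:.{precision}f}")
        lines.append(f"ID={sid}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree(path: str | Path, format: str = "newick") -> PhyloTree:
    """Read a rooted tree with branch lengths from Newick or NEXUS."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"format must be 'newick' or 'nexus', got {format!r}")
    try:
        tree = dendropy.Tree.get(path=str(path), schema=format, preserve_underscores=True)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise ValueError(f"{path}: unparseable {format} tree: {exc}") from exc
    return PhyloTree(tree)


def tree_from_newick(newick: str) -> PhyloTree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return PhyloTree(tree)


def read_module_map(path: str | Path) -> ModuleMap:
    """Read a two-column CSV ``landmark_index,module`` (1-based indices)."""
    assignments: dict[int, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"landmark_index", "module"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns landmark_index,module")
        for row in reader:
            idx = int(row["landmark_index"])
            if idx < 1:
                raise ValueError(f"{path}: landmark_index must be >= 1, got {idx}")
            if idx - 1 in assignments:
                raise ValueError(f"{path}: landmark {idx} assigned twice")
            assignments[idx - 1] = row["module"].strip()
    return ModuleMap(assignments)


def write_module_map(modules: ModuleMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["landmark_index", "module"])
        for i in range(modules.n_landmarks):
            writer.writerow([i + 1, modules.assignments[i]])


def match_taxa(
    dataset: LandmarkDataset,
    tree: PhyloTree,
    policy: str = "intersect",
) -> tuple[LandmarkDataset, PhyloTree]:
    """Reconcile species names between landmark data and tree.

    Under ``intersect`` both objects are pruned to the shared species;
    under ``strict`` any mismatch is an error.  Matching is exact after
    whitespace/underscore normalization — no fuzzy matching.
    """
    if policy not in ("intersect", "strict"):
        raise ValueError(f"policy must be 'intersect' or 'strict', got {policy!r}")
    data_species = {normalize_taxon(s) for s in dataset.species}
    tree_species = set(tree.taxa)
    shared = sorted(data_species & tree_species)
    data_only = sorted(data_species - tree_species)
    tree_only = sorted(tree_species - data_species)
    if policy == "strict" and (data_only or tree_only):
        raise ValueError(
            f"taxon mismatch under strict policy: in data only {data_only}; in tree only {tree_only}"
        )
    if len(shared) < 3:
        raise ValueError(
            f"fewer than 3 shared species ({len(shared)}); "
            f"in data only: {data_only}; in tree only: {tree_only}"
        )
    pruned_data = dataset.subset_species(shared)
    pruned_tree = tree if not tree_only else tree.prune_to(shared)
    return pruned_data, pruned_tree
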