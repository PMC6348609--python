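"""Rooted-tree data model: topology, chronogram, newick I/O, MRCA lookup.

The engine dates nodes on a *fixed* rooted bifurcating topology, so the tree
container is deliberately minimal: integer node ids, parent/child arrays, and
leaf labels.  Node ages live in a separate :class:`Chronogram` so that a single
topology can carry many age vectors during MCMC.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Topology",
    "Chronogram",
    "TreeError",
    "MalformedNewickError",
    "DuplicateLabelError",
    "PolytomyError",
    "parse_newick",
    "write_newick",
    "mrca",
]


class TreeError(ValueError):
    """Base class for tree construction/validation failures."""


class MalformedNewickError(TreeError):
    """The newick string could not be parsed."""


class DuplicateLabelError(TreeError):
    """Two leaves carry the same label."""


class PolytomyError(TreeError):
    """An internal node has more than two (or fewer than two) children."""


@dataclass(frozen=True)
class Topology:
    """Rooted bifurcating topology over integer node ids.

    Nodes are numbered ``0 .. n_nodes-1`` in postorder (children before
    parents), so the root is always ``n_nodes - 1``.  Leaves carry unique
    string labels; internal nodes are identified by their descendant leaf set.
    """

    parent: np.ndarray                 # parent id per node; -1 at the root
    children: tuple[tuple[int, ...], ...]
    labels: tuple[str | None, ...]     # leaf label or None for internal nodes

    def __post_init__(self) -> None:
        leaf_labels = [l for l in self.labels if l is not None]
        if len(set(leaf_labels)) != len(leaf_labels):
            dupes = sorted({l for l in leaf_labels if leaf_labels.count(l) > 1})
            raise DuplicateLabelError(f"duplicate leaf labels: {dupes}")
        for i, kids in enumerate(self.children):
            if kids and len(kids) != 2:
                raise PolytomyError(
                    f"node {i} has {len(kids)} children; only bifurcating "
                    "trees are supported"
                )
        if int(np.sum(self.parent < 0)) != 1:
            raise TreeError("topology must have exactly one root")
        object.__setattr__(self, "_label_to_node",
                           {l: i for i, l in enumerate(self.labels) if l is not None})

    # -- basic accessors ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> list[int]:
        return [i for i, kids in enumerate(self.children) if not kids]

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i, kids in enumerate(self.children) if kids]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    def node_of(self, label: str) -> int:
        try:
            return self._label_to_node[label]
        except KeyError:
            raise TreeError(f"unknown leaf label {label!r}") from None

    def postorder(self) -> range:
        """Node ids in postorder (construction guarantees this ordering)."""
        return range(self.n_nodes)

    def clade_leafset(self, node: int) -> frozenset[str]:
        """Labels of all leaves descending from (and including) ``node``."""
        out: list[str] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.children[v]:
                stack.extend(self.children[v])
            else:
                out.append(self.labels[v])
        return frozenset(out)

    def clades(self) -> set[frozenset[str]]:
        return {self.clade_leafset(i) for i in self.internal_nodes}

    def same_shape(self, other: "Topology") -> bool:
        """Topological equality: same leaf set and same set of clades."""
        return (set(self.leaf_labels) == set(other.leaf_labels)
                and self.clades() == other.clades())


@dataclass
class Chronogram:
    """A topology with node ages in Ma (leaves contemporaneous at age 0)."""

    topology: Topology
    ages: np.ndarray                   # age in Ma per node id

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.shape != (self.topology.n_nodes,):
            raise TreeError("ages must have one entry per node")
        validate_ages(self.topology, self.ages)

    @property
    def root_age(self) -> float:
        return float(self.ages[self.topology.root])

    def branch_durations(self) -> np.ndarray:
        """Duration (Ma) of the branch above each node; 0 at the root."""
        t = self.topology
        dur = np.zeros(t.n_nodes)
        nz = t.parent >= 0
        dur[nz] = self.ages[t.parent[nz]] - self.ages[nz]
        return dur


def validate_ages(topology: Topology, ages: np.ndarray) -> None:
    if not np.all(np.isfinite(ages)):
        raise TreeError("all node ages must be finite")
    for leaf in topology.leaves:
        if ages[leaf] != 0.0:
            raise TreeError(f"leaf {topology.labels[leaf]!r} must have age 0")
    if ages[topology.root] <= 0:
        raise TreeError("root age must be positive")
    nonroot = topology.parent >= 0
    if not np.all(ages[topology.parent[nonroot]] > ages[nonroot]):
        raise TreeError("every parent must be strictly older than its children")


def ages_are_valid(topology: Topology, ages: np.ndarray) -> bool:
    """Non-throwing variant of :func:`validate_ages` (used in MCMC kernels)."""
    if ages[topology.root] <= 0:
        return False
    nonroot = topology.parent >= 0
    return bool(np.all(ages[topology.parent[nonroot]] > ages[nonroot]))


# ---------------------------------------------------------------------------
# newick I/O (parsing delegated to dendropy; we validate and flatten)
# ---------------------------------------------------------------------------

def _from_dendropy(tree: dendropy.Tree) -> tuple[Topology, np.ndarray]:
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    children: list[tuple[int, ...]] = [()] * n
    labels: list[str | None] = [None] * n
    lengths = np.zeros(n)
    for nd in nodes:
        i = index[id(nd)]
        kids = nd.child_nodes()
        children[i] = tuple(index[id(c)] for c in kids)
        for c in kids:
            parent[index[id(c)]] = i
        if not kids:
            if nd.taxon is None or not nd.taxon.label:
                raise MalformedNewickError("unlabeled leaf in newick input")
            labels[i] = nd.taxon.label
        if len(kids) == 1:
            raise PolytomyError("internal node with a single child")
    topo = Topology(parent=parent, children=tuple(children),
                    labels=tuple(labels))
    for nd in nodes:
        lengths[index[id(nd)]] = nd.edge.length if nd.edge.length is not None else 0.0
    return topo, lengths


def parse_newick(text: str) -> Topology:
    """Parse a rooted newick string into a :class:`Topology`.

    Raises :class:`MalformedNewickError` on syntax errors,
    :class:`DuplicateLabelError` on repeated leaf labels and
    :class:`PolytomyError` if any internal node is not bifurcating.
    """
    topo, _ = _parse_newick_with_lengths(text)
    return topo


def _parse_newick_with_lengths(text: str) -> tuple[Topology, np.ndarray]:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            raise DuplicateLabelError(str(exc)) from exc
        raise MalformedNewickError(f"could not parse newick: {exc}") from exc
    if tree.seed_node is None or not tree.seed_node.child_nodes():
        raise MalformedNewickError("newick input contains no tree")
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label if leaf.taxon is not None else None
        if lab in seen:
            raise DuplicateLabelError(f"duplicate leaf labels: [{lab!r}]")
        if lab is not None:
            seen.add(lab)
    return _from_dendropy(tree)


def parse_newick_chronogram(text: str) -> Chronogram:
    """Parse a newick string whose branch lengths are age differences in Ma.

    Leaf ages are pinned at 0 and node ages are accumulated tipward; the input
    must be ultrametric to 1e-6 relative tolerance.
    """
    topo, lengths = _parse_newick_with_lengths(text)
    ages = np.zeros(topo.n_nodes)
    # node age = branch length + max child age; require consistency over leaves
    for i in topo.postorder():
        if topo.children[i]:
            kid_ages = [ages[c] + lengths[c] for c in topo.children[i]]
            if max(kid_ages) > 0 and (max(kid_ages) - min(kid_ages)) > 1e-6 * max(kid_ages):
                raise TreeError("branch lengths are not ultrametric; cannot "
                                "interpret them as ages")
            ages[i] = float(np.mean(kid_ages))
    return Chronogram(topology=topo, ages=ages)


def write_newick(topology: Topology, chronogram: Chronogram | None = None,
                 precision: int = 8) -> str:
    """Serialize a topology, optionally with ages as branch lengths in Ma."""
    if chronogram is not None and chronogram.topology is not topology:
        if not topology.same_shape(chronogram.topology):
            raise TreeError("chronogram does not match topology")

    def bl(node: int) -> str:
        if chronogram is None:
            return ""
        p = topology.parent[node]
        if p < 0:
            return ""
        return ":%.*g" % (precision, chronogram.ages[p] - chronogram.ages[node])

    out = io.StringIO()

    def emit(node: int) -> None:
        kids = topology.children[node]
        if kids:
            out.write("(")
            for k, c in enumerate(kids):
                if k:
                    out.write(",")
                emit(c)
            out.write(")")
        else:
            out.write(topology.labels[node])
        out.write(bl(node))

    emit(topology.root)
    out.write(";")
    return out.getvalue()


def mrca(topology: Topology, taxon_a: str, taxon_b: str) -> int:
    """Most recent common ancestor (node id) of two leaf labels."""
    a = topology.node_of(taxon_a)
    b = topology.node_of(taxon_b)
    ancestors = set()
    v = a
    while v >= 0:
        ancestors.add(v)
        v = topology.parent[v]
    v = b
    while v not in ancestors:
        v = topology.parent[v]
    return int(v)
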