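"""Dated-tree and richness-table ingestion, validation and output.

A :class:`Chronogram` is a rooted, binary, ultrametric tree stored as node
ages (Myr before present) rather than branch lengths; all extant terminals sit
at age 0.  Node ids are assigned deterministically — post-order after sorting
children by their smallest descendant label — so two reads of the same file
address nodes identically, and downstream results can reference clades by id
or by leafset interchangeably.

Parsing and serialisation of Newick/NEXUS go through dendropy; the classes
here add the validation the diversification analyses rely on (ultrametricity,
positive branch spans, unique labels) and the join with per-terminal extant
species richness.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Chronogram",
    "RichnessTable",
    "RichnessTree",
    "TreeValidationError",
    "read_chronogram",
    "read_richness",
    "join",
    "write_annotated_tree",
]

ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    pass


@dataclass
class _Node:
    id: int
    parent: int | None
    children: tuple[int, ...]
    label: str | None
    age: float


def _clean_label(raw: str | None) -> str:
    if raw is None:
        return ""
    return raw.strip().strip("'\"").strip()


class Chronogram:
    """Rooted ultrametric dated tree with stable integer node ids."""

    def __init__(self, nodes: list[_Node], root_id: int):
        self.nodes = {n.id: n for n in nodes}
        self.root_id = root_id
        self.tip_ids = tuple(i for i in sorted(self.nodes) if not self.nodes[i].children)
        self.internal_ids = tuple(i for i in sorted(self.nodes) if self.nodes[i].children)
        self._leafsets: dict[int, frozenset[str]] = {}

    # -- construction ---------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, ultrametric_rtol: float = ULTRAMETRIC_RTOL) -> "Chronogram":
        tree = tree.clone(depth=1)
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise TreeValidationError("tree has a branch without a length")
        polytomies = sum(1 for nd in tree.preorder_node_iter() if len(nd.child_nodes()) > 2)
        if polytomies:
            warnings.warn(
                f"{polytomies} polytomies resolved arbitrarily into zero-length branches",
                stacklevel=2,
            )
            tree.resolve_polytomies()

        # root-down depths, then snap tips to age 0 within tolerance
        depth = {tree.seed_node: 0.0}
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            depth[nd] = depth[nd.parent_node] + nd.edge.length
        leaves = [nd for nd in tree.leaf_node_iter()]
        max_depth = max(depth[nd] for nd in leaves)
        if max_depth <= 0:
            raise TreeValidationError("tree has zero total depth")
        worst = max(leaves, key=lambda nd: abs(depth[nd] - max_depth))
        rel = abs(depth[worst] - max_depth) / max_depth
        if rel > ultrametric_rtol:
            raise TreeValidationError(
                f"tree is not ultrametric: tip {_clean_label(worst.taxon.label if worst.taxon else None)!r} "
                f"deviates from the root-to-tip depth by a relative {rel:.3g} "
                f"(tolerance {ultrametric_rtol:.3g})"
            )

        # deterministic ordering: children sorted by smallest descendant label
        minlab: dict = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                lab = _clean_label(nd.taxon.label if nd.taxon else nd.label)
                if not lab:
                    raise TreeValidationError("terminal with empty label")
                minlab[nd] = lab
            else:
                minlab[nd] = min(minlab[c] for c in nd.child_nodes())

        nodes: list[_Node] = []
        ids: dict = {}

        def build(nd, parent_id):
            children_sorted = sorted(nd.child_nodes(), key=lambda c: minlab[c])
            child_ids = []
            for c in children_sorted:
                child_ids.append(build(c, None))
            nid = len(nodes)
            age = 0.0 if nd.is_leaf() else max_depth - depth[nd]
            label = _clean_label(nd.taxon.label if nd.taxon else nd.label) if nd.is_leaf() else None
            nodes.append(_Node(id=nid, parent=None, children=tuple(child_ids), label=label, age=age))
            for cid in child_ids:
                nodes[cid].parent = nid
            return nid

        root_id = build(tree.seed_node, None)
        chrono = cls(nodes, root_id)
        chrono.validate(ultrametric_rtol=ultrametric_rtol)
        return chrono

    # -- basic accessors ------------------------------------------------------

    @property
    def root_age(self) -> float:
        return self.nodes[self.root_id].age

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def age(self, node_id: int) -> float:
        return self.nodes[node_id].age

    def parent(self, node_id: int) -> int | None:
        return self.nodes[node_id].parent

    def children(self, node_id: int) -> tuple[int, ...]:
        return self.nodes[node_id].children

    def label(self, node_id: int) -> str | None:
        return self.nodes[node_id].label

    def tip_labels(self) -> list[str]:
        return [self.nodes[i].label for i in self.tip_ids]

    def branch_length(self, node_id: int) -> float:
        p = self.nodes[node_id].parent
        if p is None:
            return 0.0
        return self.nodes[p].age - self.nodes[node_id].age

    def postorder(self):
        """Node ids in post-order (children before parents)."""
        order, stack = [], [(self.root_id, False)]
        while stack:
            nid, expanded = stack.pop()
            if expanded:
                order.append(nid)
            else:
                stack.append((nid, True))
                for c in reversed(self.nodes[nid].children):
                    stack.append((c, False))
        return order

    def subtree_ids(self, node_id: int) -> list[int]:
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.nodes[nid].children)
        return out

    def leafset(self, node_id: int) -> frozenset[str]:
        """Labels of terminals descending from (or at) ``node_id`` (cached)."""
        if node_id not in self._leafsets:
            for nid in self.postorder():
                nd = self.nodes[nid]
                if not nd.children:
                    self._leafsets[nid] = frozenset([nd.label])
                else:
                    self._leafsets[nid] = frozenset().union(*(self._leafsets[c] for c in nd.children))
        return self._leafsets[node_id]

    def mrca(self, labels) -> int:
        """Id of the most recent common ancestor of the given terminal labels."""
        want = frozenset(_clean_label(l) for l in labels)
        unknown = want - set(self.tip_labels())
        if unknown:
            raise KeyError(f"labels not in tree: {sorted(unknown)}")
        best = self.root_id
        for nid in self.postorder():
            ls = self.leafset(nid)
            if want <= ls and len(ls) < len(self.leafset(best)):
                best = nid
        return best

    def validate(self, ultrametric_rtol: float = ULTRAMETRIC_RTOL) -> None:
        root_age = self.root_age
        if root_age <= 0:
            raise TreeValidationError("root age must be positive")
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate terminal labels: {dupes}")
        if any(not l for l in labels):
            raise TreeValidationError("terminal with empty label")
        for nid, nd in self.nodes.items():
            if nd.parent is not None:
                page = self.nodes[nd.parent].age
                if page <= nd.age - ultrametric_rtol * root_age:
                    raise TreeValidationError(
                        f"node {nid} (age {nd.age}) not younger than its parent (age {page})"
                    )
            if nd.children and len(nd.children) != 2:
                raise TreeValidationError(f"node {nid} is not binary after reading")
            if not nd.children and abs(nd.age) > ultrametric_rtol * root_age:
                raise TreeValidationError(f"terminal {nd.label!r} not at age 0")

    # -- serialisation --------------------------------------------------------

    def to_dendropy(self, annotations: dict[int, dict] | None = None) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)

        def build(nid, parent_dnode):
            nd = self.nodes[nid]
            if parent_dnode is None:
                dnode = tree.seed_node
            else:
                dnode = parent_dnode.new_child()
            if nd.parent is not None:
                dnode.edge.length = self.nodes[nd.parent].age - nd.age
            if not nd.children:
                dnode.taxon = taxa.new_taxon(label=nd.label)
            if annotations and nid in annotations:
                for k, v in annotations[nid].items():
                    dnode.annotations.add_new(k, v)
            for c in nd.children:
                build(c, dnode)

        build(self.root_id, None)
        return tree

    def write(self, path, schema: str = "nexus", annotations: dict[int, dict] | None = None) -> None:
        tree = self.to_dendropy(annotations=annotations)
        kwargs = {"suppress_annotations": False} if schema == "nexus" else {}
        tree.write(path=str(path), schema=schema, suppress_rooting=False, **kwargs)

    def newick(self) -> str:
        buf = io.StringIO()
        self.to_dendropy().write(file=buf, schema="newick", suppress_rooting=True)
        return buf.getvalue().strip()

    def with_ages(self, new_ages: dict[int, float]) -> "Chronogram":
        """Copy with internal node ages replaced (labels/topology untouched)."""
        nodes = [
            _Node(id=n.id, parent=n.parent, children=n.children, label=n.label,
                  age=new_ages.get(n.id, n.age))
            for n in self.nodes.values()
        ]
        out = Chronogram(nodes, self.root_id)
        out.validate()
        return out


def read_chronogram(path, schema: str | None = None,
                    ultrametric_rtol: float = ULTRAMETRIC_RTOL) -> Chronogram:
    """Read a dated tree from a Newick or NEXUS file.

    ``schema`` defaults to a guess from the file suffix (.nex/.nexus -> nexus,
    otherwise newick).
    """
    path = str(path)
    if schema is None:
        schema = "nexus" if path.lower().endswith((".nex", ".nexus", ".tre.nex")) else "newick"
    try:
        tree = dendropy.Tree.get(path=path, schema=schema)
    except dendropy.utility.error.DataParseError as err:
        raise TreeValidationError(f"could not parse tree file {path}: {err}") from err
    return Chronogram.from_dendropy(tree, ultrametric_rtol=ultrametric_rtol)


def read_tree_ensemble(path, schema: str | None = None) -> list[Chronogram]:
    """Read every tree in a multi-tree Newick/NEXUS file."""
    path = str(path)
    if schema is None:
        schema = "nexus" if path.lower().endswith((".nex", ".nexus")) else "newick"
    trees = dendropy.TreeList.get(path=path, schema=schema)
    return [Chronogram.from_dendropy(t) for t in trees]


@dataclass
class RichnessTable:
    """Mapping terminal label -> extant species count (integers >= 1)."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for label, n in self.counts.items():
            lab = _clean_label(label)
            if lab in clean:
                raise ValueError(f"duplicate richness label {lab!r}")
            if not float(n).is_integer() or int(n) < 1:
                raise ValueError(f"richness for {lab!r} must be an integer >= 1, got {n}")
            clean[lab] = int(n)
        self.counts = clean

    def __len__(self):
        return len(self.counts)

    def __getitem__(self, label):
        return self.counts[_clean_label(label)]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def read_richness(path, sep: str | None = None) -> RichnessTable:
    """Read a two-column delimited table ``label<TAB>richness`` (header optional)."""
    df = pd.read_csv(path, sep=sep or r"[\t,;]", engine="python", header=None,
                     comment="#", skip_blank_lines=True, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("richness table must have two columns: label, count")
    first = str(df.iloc[0, 1]).strip()
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]  # header row
    labels = [str(x) for x in df.iloc[:, 0]]
    counts = []
    for lab, raw in zip(labels, df.iloc[:, 1]):
        val = float(str(raw).strip())
        if not val.is_integer() or val < 1:
            raise ValueError(f"richness for {lab!r} must be an integer >= 1, got {raw}")
        counts.append(int(val))
    if len(set(_clean_label(l) for l in labels)) != len(labels):
        seen, dupes = set(), set()
        for l in labels:
            c = _clean_label(l)
            (dupes if c in seen else seen).add(c)
        raise ValueError(f"duplicate labels in richness table: {sorted(dupes)}")
    return RichnessTable(dict(zip(labels, counts)))


class RichnessTree:
    """A chronogram joined with terminal richness counts and stem ages."""

    def __init__(self, chronogram: Chronogram, richness: RichnessTable):
        tree_labels = set(chronogram.tip_labels())
        table_labels = set(richness.counts)
        if tree_labels != table_labels:
            only_tree = sorted(tree_labels - table_labels)
            only_table = sorted(table_labels - tree_labels)
            raise ValueError(
                f"tree and richness labels differ; only in tree: {only_tree[:10]}"
                f"{'...' if len(only_tree) > 10 else ''}; only in table: {only_table[:10]}"
                f"{'...' if len(only_table) > 10 else ''}"
            )
        self.chronogram = chronogram
        self.richness = richness
        self.tip_richness = {
            tid: richness[chronogram.label(tid)] for tid in chronogram.tip_ids
        }
        self.stem_age = {
            tid: chronogram.age(chronogram.parent(tid)) for tid in chronogram.tip_ids
        }
        for tid, sa in self.stem_age.items():
            if not sa > 0:
                raise TreeValidationError(
                    f"terminal {chronogram.label(tid)!r} has non-positive stem age {sa}"
                )

    @property
    def total_richness(self) -> int:
        return self.richness.total

    @property
    def n_terminals(self) -> int:
        return self.chronogram.n_tips

    def with_chronogram(self, chronogram: Chronogram) -> "RichnessTree":
        return RichnessTree(chronogram, self.richness)


def join(chronogram: Chronogram, richness: RichnessTable) -> RichnessTree:
    """Join a chronogram with a richness table (label sets must match exactly)."""
    return RichnessTree(chronogram, richness)


def write_annotated_tree(richness_tree: RichnessTree, path,
                         annotations: dict[int, dict] | None = None) -> None:
    """Write a dated NEXUS tree with per-node ``[&key=value]`` comment blocks.

    Annotation keys are indexed by node id; unknown ids are an error.  Node
    ages round-trip through the written branch lengths.
    """
    chrono = richness_tree.chronogram
    if annotations:
        unknown = set(annotations) - set(chrono.nodes)
        if unknown:
            raise KeyError(f"annotation on unknown node ids: {sorted(unknown)}")
    chrono.write(path, schema="nexus", annotations=annotations)
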