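"""Alignment and tree data model plus FASTA/Newick/TSV input-output.

The :class:`Tree` here is a deliberately small rooted-tree structure tuned for
the pruning-style algorithms in the rest of the package.  Newick parsing and
writing are delegated to :mod:`dendropy`; FASTA goes through Biopython.

Conventions
-----------
* Branch lengths are expected substitutions/site on the edge *above* a node.
* Internal-node labels that parse as numbers in ``[0, 1]`` are interpreted as
  SH-like aLRT support values (the FastTree/RAxML dialect).
* Node ids: leaves use their label; internal nodes get stable ``N<k>`` ids
  assigned in preorder (``N0`` is the root).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlphabetError,
    DomainError,
    DuplicateLeafError,
    PairingError,
    TreeError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AMBIGUOUS = "X"
ALPHABET = frozenset(AMINO_ACIDS + GAP + AMBIGUOUS)


# ---------------------------------------------------------------------------
# MSA
# ---------------------------------------------------------------------------

@dataclass
class MSA:
    """Aligned amino-acid sequences over the 20 letters plus '-' and 'X'."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentError("names and rows differ in count")
        if not self.rows:
            raise AlignmentError("empty alignment")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate sequence names")
        normalized = []
        length = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            row = row.upper().replace(".", GAP)
            if len(row) != length:
                raise AlignmentError(
                    f"ragged alignment: sequence {name!r} has length "
                    f"{len(row)}, expected {length}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"illegal character(s) {sorted(bad)} in sequence {name!r}"
                )
            normalized.append(row)
        self.rows = normalized

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def sequence(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise PairingError(f"no sequence named {name!r}") from None

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)


def read_alignment(path) -> MSA:
    """Read a FASTA alignment; lowercase and '.' are normalized."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return MSA([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(msa: MSA, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.names, msa.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

class Node:
    """One node of a rooted tree."""

    __slots__ = ("id", "label", "length", "support", "children", "parent")

    def __init__(self, id=None, label=None, length=0.0, support=None):
        self.id = id
        self.label = label
        self.length = float(length)
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.id} {kind} len={self.length:g}>"


class Tree:
    """Rooted tree with branch lengths and optional support values."""

    def __init__(self, root: Node):
        self.root = root
        self._assign_ids()

    # -- construction ------------------------------------------------------

    def _assign_ids(self) -> None:
        counter = 0
        seen: set[str] = set()
        for node in self.preorder():
            if node.is_leaf:
                if node.label is None:
                    raise TreeError("leaf without label")
                node.id = node.label
            else:
                node.id = f"N{counter}"
                counter += 1
            if node.id in seen:
                raise DuplicateLeafError(f"duplicate node id {node.id!r}")
            seen.add(node.id)

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def nodes(self) -> list[Node]:
        return list(self.preorder())

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def node(self, node_id: str) -> Node:
        for n in self.preorder():
            if n.id == node_id:
                return n
        raise PairingError(f"no node with id {node_id!r}")

    def leafset(self, node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        out: set = set()
        for child in node.children:
            out |= self.leafset(child)
        return frozenset(out)

    # -- copying / export --------------------------------------------------

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(label=node.label, length=node.length, support=node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def to_newick(self, support_as_label: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                core = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                lab = ""
                if support_as_label and node.support is not None:
                    lab = f"{node.support:g}"
                elif node.label is not None:
                    lab = node.label
                core = f"({inner}){lab}"
            if node.parent is None:
                return core
            return f"{core}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {len(self.leaves())} leaves>"


def _from_dendropy(dtree: dendropy.Tree) -> tuple[Tree, int]:
    n_missing = 0

    def convert(dnode) -> Node:
        nonlocal n_missing
        label = None
        support = None
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            raw = dnode.label
            if raw is not None:
                try:
                    val = float(raw)
                    if 0.0 <= val <= 1.0:
                        support = val
                    else:
                        label = raw
                except ValueError:
                    label = raw
        length = dnode.edge.length
        if length is None and dnode.parent_node is not None:
            n_missing += 1
        node = Node(label=label, length=0.0 if length is None else length,
                    support=support)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    return Tree(root), n_missing


def read_tree(path_or_string, support_from_comments: bool = False) -> Tree:
    """Parse a single Newick tree.

    Numeric internal-node labels in ``[0, 1]`` become support values; with
    ``support_from_comments`` the bracketed-comment dialect is used instead.
    Missing branch lengths default to 0 with a warning.
    """
    text = str(path_or_string)
    if "(" in text and ";" in text:
        source = {"data": text}
    else:
        with open(text) as fh:
            source = {"data": fh.read()}
    try:
        dtree = dendropy.Tree.get(
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=support_from_comments,
            **source,
        )
    except Exception as exc:
        if "Duplicate" in type(exc).__name__ or "duplicate" in str(exc).lower():
            raise DuplicateLeafError(f"duplicate leaf labels: {exc}") from exc
        raise TreeError(f"Newick parse failure: {exc}") from exc
    if support_from_comments:
        for dnode in dtree.preorder_node_iter():
            if not dnode.is_leaf() and dnode.label is None:
                posterior = dnode.annotations.get_value("posterior", None)
                if posterior is not None:
                    dnode.label = str(posterior)
    tree, n_missing = _from_dendropy(dtree)
    leaf_labels = tree.leaf_names
    if len(set(leaf_labels)) != len(leaf_labels):
        dupes = sorted({x for x in leaf_labels if leaf_labels.count(x) > 1})
        raise DuplicateLeafError(f"duplicate leaf label(s): {dupes}")
    if n_missing:
        warnings.warn(
            f"{n_missing} branch length(s) missing; defaulting to 0",
            stacklevel=2,
        )
    for n in tree.preorder():
        if n.length < 0:
            raise TreeError(f"negative branch length on node {n.id}")
    return tree


def write_tree(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def collapse_low_support(tree: Tree, threshold: float) -> Tree:
    """Contract internal edges whose child-node support is below ``threshold``.

    The contracted edge's length is discarded; children keep their own
    lengths.  The root is never collapsed.  Idempotent at fixed threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise DomainError(f"threshold must be in [0, 1], got {threshold}")
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(out.preorder()):
            if node.parent is None or node.is_leaf:
                continue
            if node.support is not None and node.support < threshold:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children.pop(idx)
                for i, child in enumerate(node.children):
                    child.parent = parent
                    parent.children.insert(idx + i, child)
                changed = True
                break
    return Tree(out.root)


def midpoint_root(tree: Tree) -> Tree:
    """Reroot at the midpoint of the longest leaf-to-leaf path.

    Never applied implicitly anywhere in the package.
    """
    dtree = dendropy.Tree.get(
        data=tree.to_newick(support_as_label=False), schema="newick",
        suppress_internal_node_taxa=True,
    )
    dtree.reroot_at_midpoint(update_bipartitions=False)
    return _from_dendropy(dtree)[0]


def reroot_at_edge(tree: Tree, child_id: str, fraction: float = 0.5) -> Tree:
    """Reroot on the edge above ``child_id``, placing the new root a
    ``fraction`` of the edge length above the child."""
    if not 0.0 < fraction < 1.0:
        raise DomainError("fraction must be in (0, 1)")
    work = tree.copy()
    child = work.node(child_id)
    if child.parent is None:
        raise DomainError("cannot reroot on the root's (nonexistent) edge")
    below = child.length * fraction
    above = child.length - below

    new_root = Node()
    old_parent = child.parent
    old_parent.children.remove(child)
    child.parent = None
    child.length = below
    new_root.add_child(child)

    # walk from old_parent back to the old root, reversing parent links
    def hang(node: Node, onto: Node, edge_len: float) -> None:
        parent = node.parent
        my_len = node.length
        node.parent = None
        node.length = edge_len
        onto.add_child(node)
        if parent is not None:
            parent.children.remove(node)
            hang(parent, node, my_len)

    hang(old_parent, new_root, above)

    # remove any internal node left with exactly one child (the old root)
    def splice(node: Node) -> None:
        for c in list(node.children):
            splice(c)
        if node.parent is not None and len(node.children) == 1:
            only = node.children[0]
            only.length += node.length
            grand = node.parent
            idx = grand.children.index(node)
            grand.children[idx] = only
            only.parent = grand

    splice(new_root)
    return Tree(new_root)


# ---------------------------------------------------------------------------
# NodeTable
# ---------------------------------------------------------------------------

@dataclass
class NodeTable:
    """Per-node records keyed by node id, pairable with a :class:`Tree`."""

    records: dict[str, dict] = field(default_factory=dict)

    def validate_against(self, tree: Tree) -> None:
        ids = {n.id for n in tree.preorder()}
        unknown = set(self.records) - ids
        if unknown:
            raise PairingError(f"node ids absent from tree: {sorted(unknown)}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.records, orient="index")
        df.index.name = "node_id"
        return df.reset_index()

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "NodeTable":
        df = pd.read_csv(path, sep="\t")
        if "node_id" not in df.columns:
            raise PairingError("node table TSV must have a node_id column")
        records = {
            str(row["node_id"]): {
                k: row[k] for k in df.columns if k != "node_id"
            }
            for _, row in df.iterrows()
        }
        return cls(records)
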