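"""Clade presence-absence (MRP) coding and majority-rule consensus trees."""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .core_io import Node, Tree
from .errors import DomainError, PairingError

__all__ = ["CladeMatrix", "mrp_matrix", "majority_consensus"]


@dataclass
class CladeMatrix:
    """Taxa-by-clades 0/1/? matrix for supertree input (MRP coding)."""

    taxa: list[str]
    columns: list[dict[str, str]]   # taxon -> '0' | '1' | '?'
    sources: list[int]              # input-tree index per column

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.taxa), len(self.columns)

    def entry(self, taxon: str, column: int) -> str:
        return self.columns[column].get(taxon, "?")

    def to_frame(self) -> pd.DataFrame:
        data = {
            f"clade_{i}": [col.get(t, "?") for t in self.taxa]
            for i, col in enumerate(self.columns)
        }
        return pd.DataFrame(data, index=self.taxa)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "taxon"
        df.to_csv(path, sep="\t")

    def write_phylip(self, path) -> None:
        """Relaxed-PHYLIP export with 0/1/? characters."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)} {len(self.columns)}\n")
            for taxon in self.taxa:
                chars = "".join(col.get(taxon, "?") for col in self.columns)
                fh.write(f"{taxon}  {chars}\n")


def _nontrivial_clades(tree: Tree) -> list[frozenset]:
    """Leaf sets of internal non-root edges, in postorder."""
    out = []
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        out.append(tree.leafset(node))
    return out


def mrp_matrix(trees: list[Tree]) -> CladeMatrix:
    """One column per non-trivial clade of each input tree; taxa absent from
    a tree are scored '?' in that tree's columns."""
    if not trees:
        raise DomainError("need at least one tree")
    usable = []
    for i, tree in enumerate(trees):
        if len(tree.leaves()) < 3:
            warnings.warn(f"tree {i} has < 3 taxa; skipped", stacklevel=2)
            continue
        usable.append((i, tree))
    if not usable:
        raise DomainError("no usable trees (all < 3 taxa)")
    taxa = sorted({name for _, t in usable for name in t.leaf_names})
    columns, sources = [], []
    for i, tree in usable:
        present = set(tree.leaf_names)
        for clade in _nontrivial_clades(tree):
            col = {}
            for taxon in taxa:
                if taxon not in present:
                    col[taxon] = "?"
                elif taxon in clade:
                    col[taxon] = "1"
                else:
                    col[taxon] = "0"
            columns.append(col)
            sources.append(i)
    return CladeMatrix(taxa, columns, sources)


def majority_consensus(trees: list[Tree], min_freq: float = 0.5) -> Tree:
    """Majority-rule consensus: clades occurring in > ``min_freq`` of the
    trees are retained, with their frequency recorded as support.

    Trees with unequal taxon sets are pruned to the common intersection
    first (with a warning).  With ``min_freq`` >= 0.5 retained clades are
    mutually compatible by construction.
    """
    if not trees:
        raise DomainError("need at least one tree")
    if not 0.5 <= min_freq <= 1.0:
        raise DomainError("min_freq must be in [0.5, 1]")
    taxon_sets = [frozenset(t.leaf_names) for t in trees]
    common = frozenset.intersection(*taxon_sets)
    if not common:
        raise PairingError("no taxa shared by all trees")
    if any(s != common for s in taxon_sets):
        warnings.warn("taxon sets differ; pruned to intersection",
                      stacklevel=2)
    counts: Counter = Counter()
    for tree in trees:
        seen = set()
        for node in tree.postorder():
            if node.parent is None or node.is_leaf:
                continue
            clade = frozenset(tree.leafset(node) & common)
            if len(clade) < 2 or clade == common:
                continue
            if clade not in seen:   # polytomy-safe: count once per tree
                counts[clade] += 1
                seen.add(clade)
    n = len(trees)
    kept = {c: f / n for c, f in counts.items() if f / n > min_freq}

    # assemble by nesting: larger clades first, each child under the smallest
    # strictly-containing kept clade (or the root)
    root = Node()
    clade_nodes: dict[frozenset, Node] = {frozenset(common): root}
    for clade in sorted(kept, key=len, reverse=True):
        container = min(
            (c for c in clade_nodes if clade < c), key=len)
        node = Node(support=kept[clade], length=0.0)
        clade_nodes[container].add_child(node)
        clade_nodes[clade] = node
    for taxon in sorted(common):
        container = min(
            (c for c in clade_nodes if taxon in c), key=len)
        clade_nodes[container].add_child(Node(label=taxon, length=0.0))
    return Tree(root)
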