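"""Rooted tree structures shared across the pipeline.

Two thin wrappers over a common node type are exposed: :class:`TimeTree`
for the time-calibrated species tree (branch lengths in My, ultrametric)
and :class:`GeneTree` for gene phylogenies carrying bootstrap-style
support values and a leaf-to-species mapping.

Newick text is parsed with dendropy; internal node labels that are
numeric and within [0, 100] are interpreted as support percentages (the
common IQ-TREE dialect), other labels are preserved as plain names.
"""

from __future__ import annotations

import io
from typing import Callable, Iterator, Optional

import dendropy

__all__ = ["Node", "Tree", "TimeTree", "GeneTree", "default_species_of"]


class Node:
    """One node of a rooted tree.

    ``length`` is the length of the branch above the node (0.0 for the
    root); ``support`` is an optional percentage in [0, 100] attached to
    internal nodes.
    """

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: float = 0.0,
        support: Optional[float] = None,
    ) -> None:
        self.name = name
        self.length = float(length)
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Node({self.name!r}, len={self.length}, nchild={len(self.children)})"


class Tree:
    """A rooted tree with branch lengths and optional support values."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse one Newick string.

        Raises ``ValueError`` on malformed input (e.g. unbalanced
        parentheses).
        """
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        root = cls._convert(dtree.seed_node)
        return cls(root)

    @staticmethod
    def _convert(dnode) -> Node:
        if dnode.taxon is not None:
            name = dnode.taxon.label
            support = None
        else:
            label = dnode.label
            support = _parse_support(label)
            name = None if support is not None else label
        node = Node(
            name=name,
            length=dnode.edge.length if dnode.edge.length is not None else 0.0,
            support=support,
        )
        for child in dnode.child_nodes():
            node.add_child(Tree._convert(child))
        return node

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._write(self.root, buf, is_root=True)
        buf.write(";")
        return buf.getvalue()

    def _write(self, node: Node, buf: io.StringIO, is_root: bool = False) -> None:
        if node.children:
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                self._write(child, buf)
            buf.write(")")
            if node.support is not None:
                buf.write(_fmt_num(node.support))
            elif node.name:
                buf.write(node.name)
        else:
            buf.write(node.name or "")
        if not is_root:
            buf.write(f":{_fmt_num(node.length)}")

    # ------------------------------------------------------------ queries

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def depths(self) -> dict[Node, float]:
        """Distance from the root to every node."""
        out: dict[Node, float] = {}
        for node in self.preorder():
            out[node] = node.length + (out[node.parent] if node.parent else 0.0)
        return out

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = self.depths()
        tip_depths = [depths[leaf] for leaf in self.leaves()]
        top = max(tip_depths)
        if top == 0:
            return True
        return (top - min(tip_depths)) <= rel_tol * top

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder() if n.children or n.parent is None)

    def copy(self) -> "Tree":
        return type(self)(_copy_node(self.root))

    def __len__(self) -> int:
        return len(self.leaves())


def _copy_node(node: Node) -> Node:
    new = Node(node.name, node.length, node.support)
    for child in node.children:
        new.add_child(_copy_node(child))
    return new


def _parse_support(label: Optional[str]) -> Optional[float]:
    if label is None:
        return None
    try:
        value = float(label)
    except ValueError:
        return None
    return value if 0.0 <= value <= 100.0 else None


def _fmt_num(x: float) -> str:
    x = float(x)
    if x == int(x):
        return str(int(x))
    return repr(x)


class TimeTree(Tree):
    """Time-calibrated species tree; branch lengths in My.

    ``validate`` checks rootedness, non-negative branch lengths, and,
    when ``require_ultrametric``, equal root-to-tip path lengths within
    1e-6 relative tolerance.
    """

    def validate(self, require_ultrametric: bool = True, require_binary: bool = False) -> None:
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names in species tree")
        for node in self.postorder():
            if node.length < 0:
                raise ValueError(f"negative branch length at {node.name!r}")
        if require_ultrametric and not self.is_ultrametric():
            raise ValueError("species tree is not ultrametric")
        if require_binary and not self.is_binary():
            raise ValueError("species tree has polytomies; a binary tree is required")

    def crown_age(self) -> float:
        depths = self.depths()
        return max(depths[leaf] for leaf in self.leaves())


def default_species_of(leaf_name: str) -> str:
    """Map a gene leaf label to its species: the prefix before the first ``|``.

    Gene leaves are labelled ``<species>|<gene id>``; a bare label with no
    separator is taken to be the species itself (one gene per species).
    """
    return leaf_name.split("|", 1)[0]


class GeneTree(Tree):
    """Gene phylogeny with supports and a leaf-to-species mapping."""

    def __init__(self, root: Node, species_of: Callable[[str], str] = default_species_of) -> None:
        super().__init__(root)
        self.species_of = species_of

    def species_map(self) -> dict[str, str]:
        return {leaf.name: self.species_of(leaf.name) for leaf in self.leaves()}

    def validate_against(self, species_tree: Tree) -> None:
        known = set(species_tree.leaf_names())
        for leaf, species in self.species_map().items():
            if species not in known:
                raise ValueError(f"gene leaf {leaf!r} maps to unknown species {species!r}")
        for node in self.postorder():
            if node.support is not None and not (0.0 <= node.support <= 100.0):
                raise ValueError(f"support {node.support} outside [0, 100]")
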