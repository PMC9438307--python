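"""Gene tree - species tree reconciliation under duplication-loss parsimony.

The model has no transfers: each gene-tree node maps to the last common
ancestor (LCA) of its descendants' species, a node is a duplication when
a child maps to the same species node, and losses are read off the
species-tree path crossed by each gene edge. Losses land on the specific
species branch they cross (the off-path child at each traversed
speciation), so per-branch tabulation is well defined. Duplications are
attributed to the branch above their mapped species node.

``root_and_reconcile`` searches all root edges and, for polytomies of at
most ``exhaustive_max`` children, all binary resolutions; larger
polytomies are resolved greedily (deepest species-LCA pair first) with a
logged warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .trees import GeneTree, Node, TimeTree, Tree

logger = logging.getLogger(__name__)

ROOT_STEM = "ROOT_STEM"


def collapse_low_support(gene_tree: GeneTree, threshold: float = 90.0) -> GeneTree:
    """Contract internal nodes whose support is below ``threshold``.

    Nodes with no support value are kept (treated as resolved); the
    boundary is strict: support exactly equal to the threshold survives.
    Children of a collapsed node are spliced into its parent with their
    depths preserved.
    """
    tree = gene_tree.copy()
    for node in list(tree.postorder()):
        if node.parent is None or not node.children:
            continue
        if node.support is not None and node.support < threshold:
            parent = node.parent
            idx = parent.children.index(node)
            for child in node.children:
                child.length += node.length
                child.parent = parent
            parent.children[idx:idx + 1] = node.children
    return tree


@dataclass
class Reconciliation:
    gene_tree: GeneTree
    species_tree: TimeTree
    mapping: dict            # gene node -> species node
    events: dict             # gene node -> 'speciation' | 'duplication' | 'leaf'
    loss_branches: dict      # species node -> loss count on the branch above it
    dup_branches: dict = field(default_factory=dict)  # species node -> dup count

    @property
    def duplications(self) -> int:
        return sum(self.dup_branches.values())

    @property
    def losses(self) -> int:
        return sum(self.loss_branches.values())

    @property
    def cost(self) -> int:
        return self.duplications + self.losses


def _species_index(species_tree: Tree):
    order = {}
    for i, node in enumerate(species_tree.postorder()):
        order[node] = i
    depth = {}
    for node in species_tree.preorder():
        depth[node] = 0 if node.parent is None else depth[node.parent] + 1
    return order, depth


def _lca(a: Node, b: Node, depth: dict) -> Node:
    while a is not b:
        if depth[a] >= depth[b]:
            a = a.parent
        else:
            b = b.parent
    return a


def lca_reconcile(gene_tree: GeneTree, species_tree: TimeTree) -> Reconciliation:
    """Reconcile a rooted gene tree by LCA mapping.

    The gene tree may be non-binary; a polytomy child mapping to the same
    species node as its parent is counted as a duplication there. For
    binary trees the duplication + loss total is the parsimony minimum
    for the given rooted topology.
    """
    species_leaves = {leaf.name: leaf for leaf in species_tree.leaves()}
    _, depth = _species_index(species_tree)

    mapping: dict = {}
    events: dict = {}
    loss_branches: dict = {}
    dup_branches: dict = {}

    for gnode in gene_tree.postorder():
        if gnode.is_leaf:
            sp = gene_tree.species_of(gnode.name)
            if sp not in species_leaves:
                raise ValueError(f"gene leaf {gnode.name!r} maps to unknown species {sp!r}")
            mapping[gnode] = species_leaves[sp]
            events[gnode] = "leaf"
        else:
            m = mapping[gnode.children[0]]
            for child in gnode.children[1:]:
                m = _lca(m, mapping[child], depth)
            mapping[gnode] = m
            is_dup = any(mapping[c] is m for c in gnode.children)
            events[gnode] = "duplication" if is_dup else "speciation"
            if is_dup:
                dup_branches[m] = dup_branches.get(m, 0) + (
                    len([c for c in gnode.children if mapping[c] is m]) - 1
                    if len(gnode.children) > 2
                    else 1
                )

    # losses: walk each gene edge's species path and charge off-path children.
    # For edge (u, v) the lineage descends from M(u) to M(v); every species
    # node it passes through is a speciation with no sampled descendant on
    # the other side, so one loss lands on that off-path child branch. When
    # u is a duplication the lineage starts above M(u) and crosses M(u) too;
    # when u is a speciation the count is one fewer (the classic d-1 rule).
    for gnode in gene_tree.postorder():
        if gnode.parent is None:
            continue
        top = mapping[gnode.parent]
        bottom = mapping[gnode]
        if top is bottom:
            continue
        path = []  # bottom, ..., child-of-top
        cursor = bottom
        while cursor is not top:
            path.append(cursor)
            cursor = cursor.parent
        crossed = [(path[i], path[i - 1]) for i in range(1, len(path))]
        if events[gnode.parent] == "duplication":
            crossed.append((top, path[-1]))
        for snode, on_path_child in crossed:
            for child in snode.children:
                if child is not on_path_child:
                    loss_branches[child] = loss_branches.get(child, 0) + 1
    return Reconciliation(
        gene_tree=gene_tree,
        species_tree=species_tree,
        mapping=mapping,
        events=events,
        loss_branches=loss_branches,
        dup_branches=dup_branches,
    )


# --------------------------------------------------------------- rooting


def _copy_subtree(node: Node) -> Node:
    new = Node(node.name, node.length, node.support)
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


def _suppress_unary(node: Node) -> Node:
    while len(node.children) == 1:
        child = node.children[0]
        child.length += node.length
        child.parent = node.parent
        node = child
    node.children = [_suppress_unary(c) for c in node.children]
    for c in node.children:
        c.parent = node
    return node


def _reroot_on_edge(tree: Tree, edge_index: int) -> Node:
    """Root a copy of ``tree`` on the branch above the ``edge_index``-th
    non-root node (preorder). Returns the new root node."""
    root = _copy_subtree(tree.root)
    non_root = [n for n in Node.preorder(root) if n.parent is not None]
    target = non_root[edge_index]

    def hang_upward(node: Node, exclude: Node) -> Node:
        out = Node(node.name, node.length, node.support)
        for child in node.children:
            if child is not exclude:
                out.add_child(child)
        if node.parent is not None:
            out.add_child(hang_upward(node.parent, node))
        return out

    parent = target.parent
    parent.children = [c for c in parent.children if c is not target]
    target.parent = None
    new_root = Node()
    new_root.add_child(target)
    new_root.add_child(hang_upward(parent, None))
    return _suppress_unary(new_root)


def _binary_joins(items: list[Node]):
    """All rooted binary trees over the given subtrees (each yielded once).

    Subtree objects are shared between yields; deep-copy before use.
    """
    joints: set[int] = set()

    def gen(items: list[Node]):
        if len(items) == 1:
            yield items[0]
            return
        first, rest = items[0], items[1:]
        for skeleton in gen(rest):
            # insert `first` on every branch of the skeleton over the items
            # (and above its root). Items are atomic: the traversal descends
            # only through join nodes created here, never into an item's own
            # subtree. Parents are tracked explicitly because skeletons are
            # wired by direct children assignment.
            spots: list[tuple[Node, Node | None, int | None]] = []
            stack: list[tuple[Node, Node | None, int | None]] = [(skeleton, None, None)]
            while stack:
                node, par, idx = stack.pop()
                spots.append((node, par, idx))
                if id(node) in joints:
                    for ci, ch in enumerate(node.children):
                        stack.append((ch, node, ci))
            for node, par, idx in spots:
                joint = Node()
                joints.add(id(joint))
                joint.children = [node, first]
                if par is None:
                    yield joint
                else:
                    par.children[idx] = joint
                    yield skeleton
                    par.children[idx] = node
                joints.discard(id(joint))

    yield from gen(list(items))


def _count_resolutions(k: int) -> int:
    out = 1
    for i in range(3, 2 * k - 2, 2):
        out *= i
    return out


def _fix_parents(node: Node) -> Node:
    for child in node.children:
        child.parent = node
        _fix_parents(child)
    return node


def _resolve_greedy(node: Node, mapping_depth) -> None:
    """Resolve one polytomy in place by joining the deepest species-LCA pair."""
    while len(node.children) > 2:
        best = None
        for i, j in itertools.combinations(range(len(node.children)), 2):
            d = mapping_depth(node.children[i], node.children[j])
            if best is None or d > best[0]:
                best = (d, i, j)
        _, i, j = best
        joint = Node()
        joint.add_child(node.children[i])
        joint.add_child(node.children[j])
        node.children = [c for k, c in enumerate(node.children) if k not in (i, j)]
        node.add_child(joint)


def _iter_binary_resolutions(root: Node, species_tree: TimeTree, species_of,
                             exhaustive_max: int, max_candidates: int):
    """Yield fully binary deep copies of ``root``; exhaustive for small
    polytomies, greedy for oversize ones."""
    _, depth = _species_index(species_tree)
    species_leaves = {leaf.name: leaf for leaf in species_tree.leaves()}

    def subtree_map(node: Node) -> Node:
        leaves = [n for n in Node.preorder(node) if not n.children]
        m = species_leaves[species_of(leaves[0].name)]
        for leaf in leaves[1:]:
            m = _lca(m, species_leaves[species_of(leaf.name)], depth)
        return m

    def pair_depth(a: Node, b: Node) -> int:
        return depth[_lca(subtree_map(a), subtree_map(b), depth)]

    work = _copy_subtree(root)
    polys = [n for n in Node.preorder(work) if len(n.children) > 2]
    total = 1
    for p in sorted(polys, key=lambda n: len(n.children), reverse=True):
        k = len(p.children)
        count = _count_resolutions(k)
        if k > exhaustive_max or total * count > max_candidates:
            logger.warning(
                "polytomy with %d children resolved greedily", k
            )
            _resolve_greedy(p, pair_depth)
        else:
            total *= count

    def recurse(node: Node):
        """Yield binary versions of the subtree at ``node`` (objects shared
        across yields; the caller deep-copies)."""
        if not node.children:
            yield node
            return
        child_sets = [list(recurse(c)) for c in node.children]
        for combo in itertools.product(*child_sets):
            if len(combo) <= 2:
                out = Node(node.name, node.length, node.support)
                out.children = list(combo)
                yield out
            else:
                for joined in _binary_joins(list(combo)):
                    out = Node(node.name, node.length, node.support)
                    out.children = list(joined.children)
                    # _binary_joins rewires its skeleton between yields, and
                    # these results may be materialized into lists upstream:
                    # snapshot now.
                    yield _copy_subtree(out)

    for candidate in recurse(work):
        yield _fix_parents(_copy_subtree(candidate))


def root_and_reconcile(
    gene_tree: GeneTree,
    species_tree: TimeTree,
    exhaustive_max: int = 7,
    max_candidates: int = 20000,
) -> Reconciliation:
    """Minimum duplication+loss reconciliation over rootings and resolutions.

    Every branch of the input tree is tried as a root position (plus the
    input rooting itself); polytomies are resolved exhaustively up to
    ``exhaustive_max`` children. Ties are broken by fewer duplications,
    then fewer losses, then the first candidate in enumeration order, so
    reruns are stable.
    """
    if len(gene_tree.leaves()) < 3:
        return lca_reconcile(_as_binary(gene_tree, species_tree, exhaustive_max,
                                        max_candidates), species_tree)

    n_edges = sum(1 for n in gene_tree.preorder() if n.parent is not None)
    rootings = []
    if len(gene_tree.root.children) == 2:
        rootings.append(_copy_subtree(gene_tree.root))
    for edge_index in range(n_edges):
        rootings.append(_reroot_on_edge(gene_tree, edge_index))

    best: Reconciliation | None = None
    seen_newick = set()
    for rooted in rootings:
        key = _topology_key(rooted)
        if key in seen_newick:
            continue
        seen_newick.add(key)
        for resolved in _iter_binary_resolutions(
            rooted, species_tree, gene_tree.species_of, exhaustive_max, max_candidates
        ):
            candidate = GeneTree(resolved, species_of=gene_tree.species_of)
            rec = lca_reconcile(candidate, species_tree)
            # minimize total cost; break ties by fewer duplications, then
            # fewer losses, then first candidate in enumeration order
            if best is None or (rec.cost, rec.duplications, rec.losses) < (
                best.cost, best.duplications, best.losses
            ):
                best = rec
    return best


def _as_binary(gene_tree: GeneTree, species_tree: TimeTree,
               exhaustive_max: int, max_candidates: int) -> GeneTree:
    for resolved in _iter_binary_resolutions(
        gene_tree.root, species_tree, gene_tree.species_of,
        exhaustive_max, max_candidates,
    ):
        return GeneTree(resolved, species_of=gene_tree.species_of)
    return gene_tree


def _topology_key(root: Node) -> str:
    if not root.children:
        return root.name or ""
    return "(" + ",".join(sorted(_topology_key(c) for c in root.children)) + ")"


# ------------------------------------------------------------ tabulation


def tabulate_branch_events(
    reconciliations_by_family: dict[str, list[Reconciliation]],
    species_tree: TimeTree,
    origin: str = "mapped",
) -> "pd.DataFrame":
    """Per species-branch gains, losses, and copy numbers, per family.

    Duplications mapped to species node s count as gains on the branch
    above s; duplications (and gene-tree origins) mapped to the species
    root go to a synthetic root stem with branch length 0. Each gene
    tree's root contributes one origin gain on the stem of its mapped
    node so that copy-number bookkeeping (N_child = N_parent + G - L)
    closes over the whole table.

    ``origin`` controls where a gene tree is assumed to arise: "mapped"
    places it at its root's LCA mapping (nothing is inferred above);
    "root" asserts the family was present at the species root, so a gene
    tree mapping below the root implies one loss on every off-path
    branch between the species root and the mapped node. The receptor
    families all predate the sampled radiation, so "root" is the right
    choice when estimating death rates.
    """
    import pandas as pd

    from .simulate.species import label_internal_nodes

    if origin not in ("mapped", "root"):
        raise ValueError("origin must be 'mapped' or 'root'")
    label_internal_nodes(species_tree)
    rows = []
    for family, recs in reconciliations_by_family.items():
        gains: dict = {}
        dup_gains: dict = {}
        origin_gains: dict = {}
        losses: dict = {}
        for rec in recs:
            for snode, k in rec.dup_branches.items():
                dup_gains[snode] = dup_gains.get(snode, 0) + k
            for snode, k in rec.loss_branches.items():
                losses[snode] = losses.get(snode, 0) + k
            top = rec.mapping[rec.gene_tree.root]
            if origin == "root":
                # presence asserted at the species root: charge one loss on
                # each off-path branch while walking up to the root
                cursor = top
                while cursor.parent is not None:
                    for sibling in cursor.parent.children:
                        if sibling is not cursor:
                            losses[sibling] = losses.get(sibling, 0) + 1
                    cursor = cursor.parent
                top = cursor
            origin_gains[top] = origin_gains.get(top, 0) + 1
        for snode in set(dup_gains) | set(origin_gains):
            gains[snode] = dup_gains.get(snode, 0) + origin_gains.get(snode, 0)

        counts: dict = {}
        # stem row: everything attributed to the species root
        root = species_tree.root
        stem_gain = gains.get(root, 0)
        counts[root] = stem_gain
        rows.append(
            {
                "family": family,
                "branch": ROOT_STEM,
                "parent": "",
                "t_my": 0.0,
                "gains": stem_gain,
                "dup_gains": dup_gains.get(root, 0),
                "origin_gains": origin_gains.get(root, 0),
                "losses": 0,
                "n_parent": 0,
                "n_child": counts[root],
            }
        )
        for node in species_tree.preorder():
            if node.parent is None:
                continue
            g = gains.get(node, 0)
            l = losses.get(node, 0)
            counts[node] = counts[node.parent] + g - l
            rows.append(
                {
                    "family": family,
                    "branch": node.name,
                    "parent": node.parent.name,
                    "t_my": node.length,
                    "gains": g,
                    "dup_gains": dup_gains.get(node, 0),
                    "origin_gains": origin_gains.get(node, 0),
                    "losses": l,
                    "n_parent": counts[node.parent],
                    "n_child": counts[node],
                }
            )
    table = pd.DataFrame(rows)
    _check_table(table)
    return table


def _check_table(table) -> None:
    bad = table[table["n_child"] != table["n_parent"] + table["gains"] - table["losses"]]
    if len(bad):
        raise AssertionError("branch-event bookkeeping violated")
    if (table["n_child"] < 0).any():
        raise AssertionError("negative ancestral copy number implied")
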