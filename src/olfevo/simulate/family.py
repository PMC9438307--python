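"""Birth-death gene-family evolution along a species tree.

Events are simulated branch by branch with exact next-event (Gillespie)
sampling at total rate N * (b + d) * m, where m is an optional per-branch
rate multiplier shared across families to induce coordinated expansions
and contractions. Every individual gene lineage is tracked, so the true
gene tree (pruned to surviving copies) can be extracted for downstream
reconciliation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..trees import GeneTree, Node, TimeTree, default_species_of

FAMILIES = ("OR", "TAAR", "OlfC", "ORA")


class GNode:
    """A node of the (unpruned) gene lineage forest.

    kind: 'pending' while alive on a branch, then one of
    'dup' | 'loss' | 'spec' | 'tip'.
    ``branch`` is the species node whose parent edge the event lies on
    (for tips/speciations: the species node itself); ``time`` is the age
    from the species root.
    """

    __slots__ = ("kind", "branch", "time", "children", "name")

    def __init__(self, kind: str = "pending", branch=None, time: float = 0.0) -> None:
        self.kind = kind
        self.branch = branch
        self.time = time
        self.children: list[GNode] = []
        self.name: Optional[str] = None

    def survives(self) -> bool:
        if self.kind == "tip":
            return True
        return any(c.survives() for c in self.children)


@dataclass
class Event:
    kind: str  # 'gain' | 'loss'
    time: float


@dataclass
class FamilyHistory:
    """Complete record of one simulated gene family."""

    family: str
    tree: TimeTree
    birth: float
    death: float
    root_count: int
    multipliers: dict  # species node -> multiplier on the branch above it
    counts: dict       # species node -> copy number at the node
    events: dict       # species node -> events on the branch above it
    origins: list = field(default_factory=list)  # root GNodes

    def gains(self, node) -> int:
        return sum(1 for e in self.events.get(node, []) if e.kind == "gain")

    def losses(self, node) -> int:
        return sum(1 for e in self.events.get(node, []) if e.kind == "loss")

    def tip_counts(self) -> dict[str, int]:
        return {leaf.name: self.counts[leaf] for leaf in self.tree.leaves()}

    def total_events(self) -> tuple[int, int]:
        g = sum(self.gains(n) for n in self.events)
        l = sum(self.losses(n) for n in self.events)
        return g, l

    def check_bookkeeping(self) -> None:
        """Assert child count = parent count + gains - losses on every branch."""
        for node in self.tree.preorder():
            if node.parent is None:
                continue
            expected = self.counts[node.parent] + self.gains(node) - self.losses(node)
            if self.counts[node] != expected or self.counts[node] < 0:
                raise AssertionError(
                    f"bookkeeping violated on branch above {node.name!r}: "
                    f"{self.counts[node]} != {self.counts[node.parent]} + "
                    f"{self.gains(node)} - {self.losses(node)}"
                )

    # -------------------------------------------------------- gene trees

    def gene_trees(self) -> list[GeneTree]:
        """Pruned gene trees of surviving root lineages, one per origin.

        Dead subtrees are removed and unary nodes suppressed; leaves are
        named ``<species>|<family>_g<i>`` so the default leaf-to-species
        mapping applies. Branch lengths are in My.
        """
        counters: dict[str, int] = {}
        trees = []
        for origin in self.origins:
            root = self._prune(origin, counters)
            if root is not None:
                trees.append(GeneTree(root, species_of=default_species_of))
        return trees

    def _prune(self, gnode: GNode, counters: dict[str, int]) -> Optional[Node]:
        if gnode.kind == "loss":
            return None
        if gnode.kind == "tip":
            sp = gnode.branch.name
            idx = counters.setdefault(sp, 0)
            counters[sp] = idx + 1
            leaf = Node(name=f"{sp}|{self.family}_g{idx}")
            leaf.length = 0.0
            return leaf
        kids = [self._prune(c, counters) for c in gnode.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += 0.0  # lengths fixed up below via times
            return kids[0]
        node = Node()
        for k in kids:
            node.add_child(k)
        node.length = 0.0
        return node


def simulate_family_counts(
    tree: TimeTree,
    b: float,
    d: float,
    root_count: int,
    rate_multipliers: Optional[dict] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    family: str = "OR",
) -> FamilyHistory:
    """Simulate one gene family along ``tree`` by exact event sampling."""
    if b < 0 or d < 0:
        raise ValueError("birth and death rates must be >= 0")
    if root_count < 0:
        raise ValueError("root_count must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    multipliers = dict(rate_multipliers) if rate_multipliers else {}

    depths = tree.depths()
    counts: dict = {tree.root: root_count}
    events: dict = {}
    origins = [GNode("pending") for _ in range(root_count)]

    def at_node(snode, live: list[GNode]) -> None:
        if snode.is_leaf:
            for g in live:
                g.kind = "tip"
                g.branch = snode
                g.time = depths[snode]
            return
        for g in live:
            g.kind = "spec"
            g.branch = snode
            g.time = depths[snode]
            g.children = [GNode("pending") for _ in snode.children]
        for idx, child in enumerate(snode.children):
            run_branch(child, [g.children[idx] for g in live])

    def run_branch(snode, live: list[GNode]) -> None:
        mult = multipliers.get(snode, 1.0)
        mb, md = mult if isinstance(mult, tuple) else (mult, mult)
        b_eff, d_eff = b * mb, d * md
        t0, t1 = depths[snode.parent], depths[snode]
        evs: list[Event] = []
        t = t0
        live = list(live)
        total_rate_unit = b_eff + d_eff
        while live and total_rate_unit > 0:
            rate = len(live) * total_rate_unit
            t = t + rng.exponential(1.0 / rate)
            if t >= t1:
                break
            i = int(rng.integers(len(live)))
            if rng.random() < b_eff / (b_eff + d_eff):
                g = live[i]
                g.kind = "dup"
                g.branch = snode
                g.time = t
                g.children = [GNode("pending"), GNode("pending")]
                live[i] = g.children[0]
                live.append(g.children[1])
                evs.append(Event("gain", t))
            else:
                g = live.pop(i)
                g.kind = "loss"
                g.branch = snode
                g.time = t
                evs.append(Event("loss", t))
        events[snode] = evs
        counts[snode] = len(live)
        at_node(snode, live)

    at_node(tree.root, origins)
    history = FamilyHistory(
        family=family,
        tree=tree,
        birth=b,
        death=d,
        root_count=root_count,
        multipliers=multipliers,
        counts=counts,
        events=events,
        origins=origins,
    )
    history.check_bookkeeping()
    return history


def simulate_coevolving_families(
    tree: TimeTree,
    base_rates: Optional[dict[str, tuple[float, float]]] = None,
    root_counts: Optional[dict[str, int]] = None,
    shared_multiplier_sd: float = 0.0,
    ora_dampening: float = 0.3,
    multiplier_clip: tuple[float, float] = (0.25, 4.0),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, FamilyHistory]:
    """Simulate the four receptor families with shared branch-rate noise.

    One log-normal multiplier m per species-tree branch is shared by OR,
    TAAR, and OlfC and applied asymmetrically — birth rate times m, death
    rate divided by m — so that m > 1 branches expand all three families
    together and m < 1 branches contract them together. ORA feels a
    dampened version of the same multiplier (``m ** ora_dampening``;
    dampening 0 pins ORA to 1). log m has mean 0, so m and 1/m are
    identically distributed and families with b = d stay neutral in
    expectation.
    """
    if shared_multiplier_sd < 0:
        raise ValueError("shared_multiplier_sd must be >= 0")
    if not (0.0 <= ora_dampening <= 1.0):
        raise ValueError("ora_dampening must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if base_rates is None:
        base_rates = {
            "OR": (0.0071, 0.0071),
            "TAAR": (0.0101, 0.0079),
            "OlfC": (0.0059, 0.0069),
            "ORA": (0.0018, 0.0047),
        }
    if root_counts is None:
        root_counts = {"OR": 12, "TAAR": 8, "OlfC": 6, "ORA": 6}

    sd = shared_multiplier_sd
    multipliers: dict = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        if sd == 0.0:
            multipliers[node] = 1.0
        else:
            m = float(np.exp(rng.normal(0.0, sd)))
            # clip so a run of lucky branches cannot blow a family up to
            # astronomically many copies (and the simulation to a crawl)
            multipliers[node] = min(max(m, multiplier_clip[0]), multiplier_clip[1])

    histories = {}
    for fam in FAMILIES:
        damp = ora_dampening if fam == "ORA" else 1.0
        fam_mult = {
            n: (m ** damp, m ** -damp) for n, m in multipliers.items()
        }
        bd = base_rates[fam]
        histories[fam] = simulate_family_counts(
            tree,
            bd[0],
            bd[1],
            root_counts[fam],
            rate_multipliers=fam_mult,
            rng=rng,
            family=fam,
        )
    return histories
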