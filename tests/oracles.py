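"""Brute-force reference implementations used only by the test suite.

These deliberately share no code with the package: plain-Python Gotoh
local alignment, exhaustive exon/intron enumeration, and a
species-node-assignment DP for duplication-loss reconciliation.
"""

from __future__ import annotations

import functools

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = set(_BLOSUM.alphabet)

NEG = -(10 ** 9)


def sw_protein(q: str, t: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Plain-python affine-gap local alignment score (gap cost open+ext*L)."""
    m, n = len(q), len(t)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            if q[i - 1] in _ALPHA and t[j - 1] in _ALPHA:
                s = _BLOSUM[q[i - 1], t[j - 1]]
            else:
                s = -1
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def translated_sw(dna: str, protein: str) -> int:
    """Best protein-vs-six-frame-translation local alignment score."""
    best = 0
    for strand_seq in (dna, str(Seq(dna).reverse_complement())):
        for off in range(3):
            usable = (len(strand_seq) - off) // 3
            if usable <= 0:
                continue
            aa = str(Seq(strand_seq[off:off + usable * 3]).translate())
            best = max(best, sw_protein(protein, aa))
    return best


def spliced_score(
    prot: str,
    dna: str,
    penalties: dict,
    codon_aa,
    stop_aa: int,
    blosum,
    encode_protein,
    encode_dna,
) -> int:
    """Exhaustive exon/intron enumeration oracle for the spliced aligner.

    Enumerates every set of pairwise non-overlapping GT..AG introns of
    length >= min_intron, splices each set out, aligns the protein to the
    spliced DNA with a junction-aware recursive DP using the same move
    costs, and returns the best total score.
    """
    q = encode_protein(prot)
    n = len(dna)
    min_i = penalties["min_intron"]
    donors = [i for i in range(n - 1) if dna[i:i + 2] == "GT"]
    acceptors = [j for j in range(2, n + 1) if dna[j - 2:j] == "AG"]
    introns = sorted(
        (a, b) for a in donors for b in acceptors if b - a >= min_i
    )
    intron_sets: list[list[tuple[int, int]]] = []

    def rec(start: int, current: list) -> None:
        intron_sets.append(list(current))
        for k in range(start, len(introns)):
            a, b = introns[k]
            if all(a >= e or b <= s for s, e in current):
                current.append((a, b))
                rec(k + 1, current)
                current.pop()

    rec(0, [])

    best = 0
    for chosen in intron_sets:
        chosen = sorted(chosen)
        pieces, junctions = [], set()
        prev = acc = 0
        for a, b in chosen:
            pieces.append(dna[prev:a])
            acc += len(pieces[-1])
            junctions.add(acc)
            prev = b
        pieces.append(dna[prev:])
        spliced = "".join(pieces)
        sq = encode_dna(spliced)
        m, nn = len(q), len(spliced)

        def crosses(lo: int, hi: int) -> bool:
            return any(lo < x < hi for x in junctions)

        @functools.lru_cache(maxsize=None)
        def best_end(i: int, j: int) -> int:
            cands = [0]
            if i > 0 and j >= 3 and not crosses(j - 3, j):
                a_, b_, c_ = int(sq[j - 3]), int(sq[j - 2]), int(sq[j - 1])
                if a_ < 4 and b_ < 4 and c_ < 4:
                    aa = codon_aa[a_ * 25 + b_ * 5 + c_]
                    sc = penalties["stop_readthrough"] if aa == stop_aa else int(blosum[q[i - 1], aa])
                else:
                    sc = -1
                cands.append(max(0, best_end(i - 1, j - 3)) + sc)
            if i > 0 and j >= 2 and not crosses(j - 2, j):
                cands.append(max(0, best_end(i - 1, j - 2)) + penalties["frameshift"])
            if i > 0 and j >= 4 and not crosses(j - 4, j):
                cands.append(max(0, best_end(i - 1, j - 4)) + penalties["frameshift"])
            if i > 0:
                cands.append(max(0, best_end(i - 1, j)) + penalties["residue_skip"])
            if j >= 3 and not crosses(j - 3, j):
                cands.append(max(0, best_end(i, j - 3)) + penalties["extra_codon"])
            return max(cands)

        local_best = 0
        for i in range(m + 1):
            for j in range(nn + 1):
                local_best = max(local_best, best_end(i, j))
        best_end.cache_clear()
        best = max(best, local_best + len(chosen) * penalties["intron"])
    return best


# ------------------------------------------------- reconciliation oracle
#
# Gene trees are handled as nested tuples (leaf = species-tagged name
# string, internal node = tuple of child structures), fully independent of
# the package's Node machinery.


def tree_to_struct(node):
    if not node.children:
        return node.name
    return tuple(tree_to_struct(c) for c in node.children)


def _canonical(struct):
    if isinstance(struct, str):
        return struct
    return "(" + ",".join(sorted(_canonical(c) for c in struct)) + ")"


def enumerate_rootings(root_struct):
    """Every rooting of the unrooted version of ``root_struct``.

    Builds an explicit undirected graph and re-roots on each edge; the
    input rooting itself is included when its root is binary.
    """
    counter = [0]
    adj: dict = {}

    def add_edge(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def build(struct):
        if isinstance(struct, str):
            return ("leaf", struct)
        counter[0] += 1
        me = ("int", counter[0])
        for child in struct:
            add_edge(me, build(child))
        return me

    top = build(root_struct)

    def hang(node, parent):
        kids = [n for n in adj[node] if n != parent]
        if not kids:
            return node[1]
        parts = [hang(k, node) for k in kids]
        if len(parts) == 1:
            return parts[0]
        return tuple(parts)

    out = []
    if isinstance(root_struct, tuple) and len(root_struct) == 2:
        out.append(root_struct)
    seen_edges = set()
    for a in adj:
        for b in adj[a]:
            key = frozenset((a, b))
            if key in seen_edges:
                continue
            seen_edges.add(key)
            out.append((hang(a, b), hang(b, a)))
    return out


def binary_resolutions(struct):
    """All fully binary refinements of a rooted (multifurcating) structure."""
    if isinstance(struct, str):
        return [struct]
    child_variants = [binary_resolutions(c) for c in struct]
    import itertools

    results = {}

    def join_all(items):
        if len(items) == 1:
            return [items[0]]
        out = {}
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                merged = (items[i], items[j])
                rest = [it for k, it in enumerate(items) if k not in (i, j)]
                for t in join_all(rest + [merged]):
                    out[_canonical(t)] = t
        return list(out.values())

    for combo in itertools.product(*child_variants):
        for t in join_all(list(combo)):
            results[_canonical(t)] = t
    return list(results.values())


def dl_cost_struct(struct, stree, species_of) -> int:
    """Duplication+loss cost of one rooted binary gene tree, by a DP over
    all species-node assignments (independent of LCA reasoning)."""
    snodes = list(stree.postorder())
    depth = {}
    for s in stree.preorder():
        depth[s] = 0 if s.parent is None else depth[s.parent] + 1
    anc = {}
    for s in snodes:
        a, cur = set(), s
        while cur is not None:
            a.add(cur)
            cur = cur.parent
        anc[s] = a
    leaves = {l.name: l for l in stree.leaves()}
    INF = 10 ** 9

    def lca(a, b):
        while a is not b:
            if depth[a] >= depth[b]:
                a = a.parent
            else:
                b = b.parent
        return a

    def cost(g):
        if isinstance(g, str):
            s = leaves[species_of(g)]
            return {t: (0 if t is s else INF) for t in snodes}
        assert len(g) == 2, "oracle expects binary structures"
        c1, c2 = cost(g[0]), cost(g[1])
        out = {}
        for s in snodes:
            best = INF
            below = [t for t in snodes if s in anc[t]]
            for s1 in below:
                if c1[s1] >= INF:
                    continue
                for s2 in below:
                    if c2[s2] >= INF:
                        continue
                    join = lca(s1, s2)
                    if join is s and s1 is not s and s2 is not s:
                        c = (depth[s1] - depth[s]) - 1 + (depth[s2] - depth[s]) - 1
                    else:
                        c = 1 + (depth[s1] - depth[s]) + (depth[s2] - depth[s])
                    total = c1[s1] + c2[s2] + c
                    if total < best:
                        best = total
            out[s] = best
        return out

    return min(cost(struct).values())


def min_dl_over_rootings(gene_tree, stree, species_of) -> int:
    """Exhaustive minimum DL cost over all rootings x binary resolutions."""
    struct = tree_to_struct(gene_tree.root)
    best = 10 ** 9
    seen = set()
    for rooting in enumerate_rootings(struct):
        key = _canonical(rooting)
        if key in seen:
            continue
        seen.add(key)
        for resolved in binary_resolutions(rooting):
            best = min(best, dl_cost_struct(resolved, stree, species_of))
    return best


def losses_cleanly_visible(history) -> bool:
    """True when every simulated death is recoverable by reconciliation.

    Requires each root lineage to survive on both sides of the species
    root (so its pruned gene tree maps to the root) and every
    non-surviving side of any speciation to consist of a death on that
    very branch, not a deeper extinct subtree.
    """
    for origin in history.origins:
        if origin.kind != "spec":
            return False
        if not all(c.survives() for c in origin.children):
            return False
        stack = list(origin.children)
        while stack:
            g = stack.pop()
            if g.kind == "spec":
                for c in g.children:
                    if not c.survives() and c.kind != "loss":
                        return False
                    stack.append(c)
            elif g.kind == "dup":
                stack.extend(g.children)
    return True
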