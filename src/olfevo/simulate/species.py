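"""Random ultrametric species trees."""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..trees import Node, TimeTree


def simulate_species_tree(
    n_taxa: int,
    crown_age_my: float = 100.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> TimeTree:
    """Simulate a rooted, binary, ultrametric species tree.

    Tips sit at age 0; the crown (root) node sits at exactly
    ``crown_age_my``. Internal node ages are drawn uniformly on
    (0, crown_age_my) and lineages are joined at random, which yields a
    valid ultrametric topology without constraining its shape.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if crown_age_my <= 0:
        raise ValueError("crown_age_my must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    width = len(str(n_taxa))
    lineages: list[tuple[Node, float]] = [
        (Node(name=f"sp{i + 1:0{width}d}"), 0.0) for i in range(n_taxa)
    ]
    ages = np.sort(rng.uniform(0.0, crown_age_my, size=n_taxa - 2)) if n_taxa > 2 else np.empty(0)
    ages = np.concatenate([ages, [crown_age_my]])

    for age in ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, age_a), (b, age_b) = lineages[i], lineages[j]
        parent = Node()
        a.length = age - age_a
        b.length = age - age_b
        parent.add_child(a)
        parent.add_child(b)
        del lineages[j], lineages[i]
        lineages.append((parent, float(age)))

    root = lineages[0][0]
    tree = TimeTree(root)
    label_internal_nodes(tree)
    tree.validate(require_ultrametric=True, require_binary=True)
    return tree


def label_internal_nodes(tree, prefix: str = "n") -> None:
    """Assign stable names (preorder numbering) to unnamed internal nodes."""
    counter = 0
    for node in tree.preorder():
        if node.children and not node.name:
            node.name = f"{prefix}{counter}"
            counter += 1
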