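"""Lamellae trait simulation and trait-table validation."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from ..trees import TimeTree

FLAT_MAX_LAMELLAE = 2  # epithelium is "flat" iff lamellae <= 2


def epithelium_class(lamellae: int) -> str:
    return "flat" if lamellae <= FLAT_MAX_LAMELLAE else "multilamellar"


def brownian_deviates(
    tree: TimeTree, sigma: float, rng: np.random.Generator
) -> dict[str, float]:
    """Tip values of a Brownian motion (root value 0, rate sigma^2 per My)."""
    values: dict = {tree.root: 0.0}
    for node in tree.preorder():
        if node.parent is None:
            continue
        step = rng.normal(0.0, sigma * np.sqrt(node.length)) if node.length > 0 else 0.0
        values[node] = values[node.parent] + step
    return {leaf.name: values[leaf] for leaf in tree.leaves()}


def simulate_lamellae(
    tree: TimeTree,
    total_gene_counts: dict[str, int],
    intercept: float = 0.0,
    slope: float = 0.1,
    bm_sigma: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Lamellae counts linearly tied to repertoire size plus Brownian noise.

    lamellae = max(0, round(intercept + slope * count + BM deviate)).
    """
    if not np.isfinite(slope) or not np.isfinite(bm_sigma):
        raise ValueError("slope and bm_sigma must be finite")
    species = set(tree.leaf_names())
    missing = species.symmetric_difference(total_gene_counts)
    if missing:
        raise ValueError(f"species mismatch between tree and counts: {sorted(missing)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = brownian_deviates(tree, bm_sigma, rng)
    rows = []
    for sp in tree.leaf_names():
        raw = intercept + slope * total_gene_counts[sp] + noise[sp]
        lam = max(0, int(round(raw)))
        rows.append(
            {
                "species": sp,
                "total_genes": int(total_gene_counts[sp]),
                "lamellae": lam,
                "epithelium": epithelium_class(lam),
            }
        )
    table = pd.DataFrame(rows)
    validate_trait_table(table)
    return table


def validate_trait_table(table: pd.DataFrame) -> None:
    """Enforce the trait-table invariants.

    Species unique; count columns are non-negative integers; when both
    columns are present, epithelium equals 'flat' exactly when
    lamellae <= 2.
    """
    if "species" not in table.columns:
        raise ValueError("trait table must have a 'species' column")
    if table["species"].duplicated().any():
        raise ValueError("duplicate species in trait table")
    for col in table.columns:
        if col in ("species", "epithelium"):
            continue
        values = table[col].dropna()
        if (values < 0).any():
            raise ValueError(f"negative values in trait column {col!r}")
    if "epithelium" in table.columns and "lamellae" in table.columns:
        expected = table["lamellae"].map(epithelium_class)
        mask = table["epithelium"].notna()
        if not (table.loc[mask, "epithelium"] == expected[mask]).all():
            raise ValueError("epithelium class inconsistent with lamellae <= 2 rule")
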