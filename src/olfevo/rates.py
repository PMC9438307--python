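"""Birth and death rates per gene per million years from branch events.

Per retained branch, b = G / (N_parent * t) and d = L / (N_parent * t).
Branches shorter than ``min_branch_my`` (default 2 My) or with no
ancestral copies are excluded with an explicit reason. The family-level
estimate pools events over gene-time: b = sum(G) / sum(N_parent * t); the
per-branch simple mean is reported alongside as a secondary column.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["branch_rates", "family_mean_rates"]


def branch_rates(table: pd.DataFrame, min_branch_my: float = 2.0) -> pd.DataFrame:
    """Annotate a branch-event table with per-branch rates and exclusions.

    Expects columns family, branch, t_my, gains, losses, n_parent.
    Adds gene_time, b, d, excluded, exclude_reason.
    """
    if (table["t_my"] < 0).any():
        raise ValueError("negative branch length in event table")
    out = table.copy()
    out["gene_time"] = out["n_parent"].astype(float) * out["t_my"].astype(float)

    reasons = np.full(len(out), "", dtype=object)
    short = out["t_my"] < min_branch_my
    no_parent = out["n_parent"] == 0
    reasons[no_parent.to_numpy()] = "no_ancestral_copies"
    reasons[short.to_numpy()] = "short_branch"
    out["excluded"] = (short | no_parent).to_numpy()
    out["exclude_reason"] = reasons

    with np.errstate(divide="ignore", invalid="ignore"):
        b = out["gains"] / out["gene_time"]
        d = out["losses"] / out["gene_time"]
    out["b"] = np.where(out["excluded"], np.nan, b)
    out["d"] = np.where(out["excluded"], np.nan, d)
    return out


def family_mean_rates(branch_table: pd.DataFrame) -> pd.DataFrame:
    """Pooled and per-branch-mean family rates from an annotated table.

    Families whose branches are all excluded get NaN rates and a warning:
    an undefined estimate is not a zero rate.
    """
    rows = []
    for family, group in branch_table.groupby("family", sort=True):
        kept = group[~group["excluded"]]
        gene_time = float(kept["gene_time"].sum())
        if len(kept) == 0 or gene_time <= 0:
            warnings.warn(
                f"family {family!r}: all branches excluded; rates undefined",
                stacklevel=2,
            )
            rows.append(
                {
                    "family": family,
                    "n_branches": len(group),
                    "n_retained": int(len(kept)),
                    "gene_time": gene_time,
                    "b_pooled": np.nan,
                    "d_pooled": np.nan,
                    "b_branch_mean": np.nan,
                    "d_branch_mean": np.nan,
                }
            )
            continue
        rows.append(
            {
                "family": family,
                "n_branches": len(group),
                "n_retained": int(len(kept)),
                "gene_time": gene_time,
                "b_pooled": float(kept["gains"].sum()) / gene_time,
                "d_pooled": float(kept["losses"].sum()) / gene_time,
                "b_branch_mean": float(kept["b"].mean()),
                "d_branch_mean": float(kept["d"].mean()),
            }
        )
    return pd.DataFrame(rows)
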