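"""Locus status classification, family assignment, and deduplication."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .search import bit_score, smith_waterman_protein
from .splice import GeneModel

STATUSES = ("gene", "pseudogene", "truncated", "edge")


def classify_locus(
    model: GeneModel,
    distance_to_contig_border: int,
    edge_distance: int = 30,
    completeness_fraction: float = 0.8,
) -> str:
    """Apply the four-way status rule.

    A model is complete when it covers at least ``completeness_fraction``
    of its reference, begins with Met, and is followed by a stop codon.
    Any loss-of-function event makes the locus a pseudogene regardless of
    completeness; an incomplete, LOF-free locus is "edge" only when it
    lies closer than ``edge_distance`` bp to a contig border.
    """
    if model.lof_events:
        return "pseudogene"
    complete = (
        model.coverage >= completeness_fraction
        and model.has_start
        and model.has_terminal_stop
    )
    if complete:
        return "gene"
    if distance_to_contig_border < edge_distance:
        return "edge"
    return "truncated"


@dataclass(frozen=True)
class FamilyCall:
    family: str       # OR | TAAR | OlfC | ORA | non-olfactory
    subfamily: str
    best_id: str
    score: int
    bits: float
    ambiguous: bool   # top two panel scores closer than the bit margin


def assign_family(
    candidate_protein: str,
    panel,
    margin_bits: float = 5.0,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> FamilyCall:
    """Label a candidate by its best-scoring panel member.

    The panel must contain at least one decoy so that non-receptor GPCRs
    have somewhere better to land; a best-matching decoy yields family
    "non-olfactory". Ambiguity is flagged when the top two scores are
    within ``margin_bits`` bits.
    """
    if not candidate_protein:
        raise ValueError("empty candidate protein")
    if not any(m.is_decoy for m in panel):
        raise ValueError("panel must contain at least one decoy")
    scored = []
    for member in panel:
        s = smith_waterman_protein(
            candidate_protein, member.protein, gap_open, gap_extend
        )
        scored.append((s, member))
    scored.sort(key=lambda t: (-t[0], t[1].name))
    best_score, best = scored[0]
    ambiguous = False
    if len(scored) > 1:
        second_score, second = scored[1]
        if (
            second.family != best.family
            and bit_score(best_score) - bit_score(second_score) < margin_bits
        ):
            ambiguous = True
    family = "non-olfactory" if best.is_decoy else best.family
    subfamily = "" if best.is_decoy else best.subfamily
    return FamilyCall(
        family=family,
        subfamily=subfamily,
        best_id=best.name,
        score=int(best_score),
        bits=bit_score(best_score),
        ambiguous=ambiguous,
    )


def dedup_identical(loci: Sequence) -> tuple[list, int]:
    """Collapse exact nucleotide-duplicate CDSs within one genome.

    Keeps the first locus in (contig, start) order for each distinct CDS;
    returns (survivors, number removed). Input order does not matter.
    """
    ordered = sorted(loci, key=lambda rec: (rec.contig, rec.start, rec.end))
    seen: dict[str, object] = {}
    removed = 0
    for rec in ordered:
        key = rec.model.cds.upper()
        if key in seen:
            removed += 1
        else:
            seen[key] = rec
    return list(seen.values()), removed


def nearest_panel_neighbor(
    candidate_protein: str,
    panel,
    panel_distances: Optional[np.ndarray] = None,
):
    """Panel member closest to the candidate on a neighbor-joining tree.

    Builds an NJ tree over the candidate plus the panel from pairwise
    alignment-score distances and returns the panel leaf with the
    shortest path to the candidate. This replaces by-eye tree curation
    with a reproducible check.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    names = ["__candidate__"] + [m.name for m in panel]
    k = len(panel)
    dm = np.zeros((k + 1, k + 1))
    if panel_distances is None:
        panel_distances = panel_distance_matrix(panel)
    dm[1:, 1:] = panel_distances
    self_cand = smith_waterman_protein(candidate_protein, candidate_protein)
    for idx, member in enumerate(panel):
        d = _score_distance(
            smith_waterman_protein(candidate_protein, member.protein),
            self_cand,
            smith_waterman_protein(member.protein, member.protein),
        )
        dm[0, idx + 1] = dm[idx + 1, 0] = d
    tree = nj(DistanceMatrix(dm, ids=names))
    cand_tip = tree.find("__candidate__")
    best_name, best_dist = None, np.inf
    for tip in tree.tips():
        if tip.name == "__candidate__":
            continue
        d = cand_tip.distance(tip)
        if d < best_dist or (d == best_dist and tip.name < best_name):
            best_name, best_dist = tip.name, d
    return next(m for m in panel if m.name == best_name)


def panel_distance_matrix(panel) -> np.ndarray:
    k = len(panel)
    selfs = [smith_waterman_protein(m.protein, m.protein) for m in panel]
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s = smith_waterman_protein(panel[i].protein, panel[j].protein)
            dm[i, j] = dm[j, i] = _score_distance(s, selfs[i], selfs[j])
    return dm


def _score_distance(s_ab: int, s_aa: int, s_bb: int) -> float:
    """Score-based distance in [0, 1]: 1 - normalized alignment score."""
    denom = min(s_aa, s_bb)
    if denom <= 0:
        return 1.0
    return float(max(0.0, 1.0 - s_ab / denom))
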