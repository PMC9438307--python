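"""End-to-end mining of one genome: search, extend, align, label, classify."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from ..config import RunConfig
from ..io import FastaRecord
from .classify import (
    assign_family,
    classify_locus,
    dedup_identical,
    nearest_panel_neighbor,
    panel_distance_matrix,
)
from .search import Hit, merge_hit_regions, translated_search
from .splice import GeneModel, spliced_align

logger = logging.getLogger(__name__)


@dataclass
class LocusRecord:
    locus_id: str
    contig: str
    start: int
    end: int
    strand: str
    family: str
    subfamily: str
    status: str
    ambiguous: bool
    model: GeneModel

    def to_row(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "contig": self.contig,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
            "family": self.family,
            "subfamily": self.subfamily,
            "status": self.status,
            "ambiguous": self.ambiguous,
            "n_exons": len(self.model.exons),
            "n_lof": len(self.model.lof_events),
            "coverage": round(self.model.coverage, 4),
            "score": self.model.score,
            "cds": self.model.cds,
        }


def _cluster_hits(hits: list[Hit], gap: int = 2000) -> list[list[Hit]]:
    """Group same-strand hits whose intervals lie within ``gap`` bp."""
    clusters: list[list[Hit]] = []
    hi = -1
    for h in sorted(hits, key=lambda h: (h.start, h.end)):
        if clusters and h.start <= hi + gap:
            clusters[-1].append(h)
            hi = max(hi, h.end)
        else:
            clusters.append([h])
            hi = h.end
    return clusters


def default_queries(panel) -> list[tuple[str, str]]:
    """One exemplar protein per family, in panel order."""
    seen: dict[str, tuple[str, str]] = {}
    for member in panel:
        if not member.is_decoy and member.family not in seen:
            seen[member.family] = (member.name, member.protein)
    return list(seen.values())


def mine_genome(
    contigs: Sequence[FastaRecord],
    panel,
    config: Optional[RunConfig] = None,
    queries: Optional[list[tuple[str, str]]] = None,
    species: str = "",
) -> tuple[list[LocusRecord], pd.DataFrame]:
    """Recover and classify receptor loci from one genome.

    Returns the retained locus records and a tidy table (one row per
    locus). Candidates whose best panel match is a decoy are discarded;
    when ``config.tree_curation`` is on, a neighbor-joining placement
    against the panel must also put the candidate next to an olfactory
    member.
    """
    if config is None:
        config = RunConfig()
    config.validate()
    if queries is None:
        queries = default_queries(panel)
    panel_by_name = {m.name: m for m in panel}
    query_proteins = {qid: prot for qid, prot in queries}

    panel_dm = panel_distance_matrix(panel) if config.tree_curation else None

    records: list[LocusRecord] = []
    serial = 0
    for contig in contigs:
        n = len(contig.seq)
        hits = translated_search(
            contig.seq,
            queries,
            e_threshold=config.e_value_threshold,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
            contig_id=contig.id,
        )
        for strand in ("+", "-"):
            strand_hits = [h for h in hits if h.strand == strand]
            regions = merge_hit_regions(strand_hits, n, flank=config.flank)
            # one extended region can span several well-separated loci when
            # their flanks touch; align one model per hit cluster instead of
            # one per region so no locus is swallowed by a neighbour.
            windows = []
            for rlo, rhi in regions:
                in_region = [h for h in strand_hits if h.start < rhi and h.end > rlo]
                for cluster in _cluster_hits(in_region):
                    lo = max(rlo, cluster[0].start - config.flank)
                    hi = min(rhi, max(h.end for h in cluster) + config.flank)
                    windows.append((lo, hi, cluster))
            for lo, hi, cluster in windows:
                best_hit = max(cluster, key=lambda h: (h.score, h.query_id))
                ref_protein = query_proteins[best_hit.query_id]
                region = contig.seq[lo:hi]
                if strand == "-":
                    region = str(Seq(region).reverse_complement())
                model = spliced_align(
                    ref_protein, region, ref_id=best_hit.query_id, strand=strand
                )
                if model is None:
                    continue
                call = assign_family(
                    model.protein, panel, margin_bits=config.margin_bits
                )
                if call.family != "non-olfactory" and call.best_id != model.ref_id:
                    # re-align against the best-matching panel member: the
                    # seeding query is one exemplar per family, which can be
                    # too far from the locus to anchor short terminal exons,
                    # and completeness is judged against the best match.
                    refined = spliced_align(
                        panel_by_name[call.best_id].protein,
                        region,
                        ref_id=call.best_id,
                        strand=strand,
                    )
                    if refined is not None and refined.score >= model.score:
                        model = refined
                        call = assign_family(
                            model.protein, panel, margin_bits=config.margin_bits
                        )
                if strand == "+":
                    exons = [(lo + s, lo + e) for s, e in model.exons]
                else:
                    exons = sorted((hi - e, hi - s) for s, e in model.exons)
                model.exons = exons
                span_start = exons[0][0]
                span_end = exons[-1][1]

                if call.family == "non-olfactory":
                    logger.debug("discarding decoy-matching locus at %s:%d", contig.id, span_start)
                    continue
                if config.tree_curation:
                    neighbor = nearest_panel_neighbor(model.protein, panel, panel_dm)
                    if neighbor.is_decoy:
                        logger.debug("tree curation rejected locus at %s:%d", contig.id, span_start)
                        continue
                border = min(span_start, n - span_end)
                status = classify_locus(
                    model,
                    border,
                    edge_distance=config.edge_distance,
                    completeness_fraction=config.completeness_fraction,
                )
                serial += 1
                records.append(
                    LocusRecord(
                        locus_id=f"{species or 'genome'}_m{serial:04d}",
                        contig=contig.id,
                        start=span_start,
                        end=span_end,
                        strand=strand,
                        family=call.family,
                        subfamily=call.subfamily,
                        status=status,
                        ambiguous=call.ambiguous,
                        model=model,
                    )
                )

    records = _drop_overlapping(records)
    records, removed = dedup_identical(records)
    if removed:
        logger.info("removed %d identical duplicate CDS(s)", removed)
    table = pd.DataFrame([r.to_row() for r in records])
    return records, table


def _drop_overlapping(records: list[LocusRecord]) -> list[LocusRecord]:
    """Keep the best-scoring model where spans overlap on one strand."""
    kept: list[LocusRecord] = []
    for rec in sorted(records, key=lambda r: (-r.model.score, r.contig, r.start)):
        clash = any(
            k.contig == rec.contig
            and k.strand == rec.strand
            and k.start < rec.end
            and k.end > rec.start
            for k in kept
        )
        if not clash:
            kept.append(rec)
    kept.sort(key=lambda r: (r.contig, r.start))
    return kept


def repertoire_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Family x status locus counts with row totals."""
    from .classify import STATUSES

    if table.empty:
        return pd.DataFrame(columns=list(STATUSES) + ["total"])
    pivot = (
        table.pivot_table(
            index="family", columns="status", aggfunc="size", fill_value=0
        )
        .reindex(columns=list(STATUSES), fill_value=0)
    )
    pivot.columns.name = None
    pivot["total"] = pivot.sum(axis=1)
    return pivot


def evaluate_against_truth(
    table: pd.DataFrame, truth: pd.DataFrame, min_overlap: float = 0.5
) -> dict:
    """Recall / family / status agreement of mined loci vs planted truth.

    A truth locus is recovered when a mined locus on the same contig and
    strand overlaps at least ``min_overlap`` of it. Family and status
    accuracy are measured on recovered loci; status additionally only on
    rows not flagged ambiguous in the truth.
    """
    n_truth = len(truth)
    matched = 0
    fam_ok = 0
    status_total = 0
    status_ok = 0
    for row in truth.itertuples(index=False):
        if table.empty:
            continue
        cand = table[
            (table["contig"] == row.contig) & (table["strand"] == row.strand)
        ]
        overlap = (
            cand["end"].clip(upper=row.end) - cand["start"].clip(lower=row.start)
        )
        cand = cand[overlap >= min_overlap * (row.end - row.start)]
        if cand.empty:
            continue
        best = cand.iloc[0]
        matched += 1
        if best["family"] == row.family:
            fam_ok += 1
        if not row.ambiguous:
            status_total += 1
            if best["status"] == row.status:
                status_ok += 1
    return {
        "n_truth": n_truth,
        "n_recovered": matched,
        "recall": matched / n_truth if n_truth else float("nan"),
        "family_accuracy": fam_ok / matched if matched else float("nan"),
        "status_accuracy": status_ok / status_total if status_total else float("nan"),
    }
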