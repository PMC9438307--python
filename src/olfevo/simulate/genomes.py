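"""Emit sequence-level synthetic genomes with known receptor locus states.

Every tip of every simulated family history becomes one genomic locus
derived from a reference exemplar of its family: point-mutated, optionally
pseudogenized (premature stops / 1-bp frameshifts), truncated, or cut by a
contig border, then interleaved with random intergenic DNA. The returned
truth table records exactly what was planted where.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ..io import FastaRecord
from .family import FamilyHistory
from .panel import FAMILY_SHAPES, STOP_CODONS, PanelMember, mutate_cds

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUTH_COLUMNS = [
    "locus_id", "species", "contig", "start", "end", "strand",
    "family", "subfamily", "status", "n_lof", "lof_kinds", "cut_side",
    "ambiguous",
]


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


@dataclass
class _PlannedLocus:
    family: str
    subfamily: str
    status: str
    dna: str          # locus DNA in gene orientation (exons + introns)
    strand: str
    n_lof: int
    lof_kinds: str
    cut_side: str     # '', '5p', '3p'
    exon_spans: list  # (start, end) within dna, gene orientation


def _inject_lof(
    cds: str, rng: np.random.Generator, margin: int = 30, min_spacing: int = 60
) -> tuple[str, list[str]]:
    """Plant 1-3 loss-of-function events in the CDS interior.

    Events are kept at least ``min_spacing`` bp apart: two compensating
    frameshifts right next to each other can silently restore the reading
    frame, which would make the planted pseudogene undetectable in
    principle, not just in practice.
    """
    n_events = int(rng.integers(1, 4))
    lo, hi = margin, len(cds) - margin
    if hi - lo < 3:
        return cds, []
    positions: list[int] = []
    for _ in range(n_events):
        for _attempt in range(20):
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - p) >= min_spacing for p in positions):
                positions.append(pos)
                break
    kinds: list[str] = []
    for pos in sorted(positions, reverse=True):  # high-to-low keeps offsets valid
        u = rng.random()
        if u < 0.5:
            codon_pos = (pos // 3) * 3
            cds = cds[:codon_pos] + "TAA" + cds[codon_pos + 3:]
            kinds.append("premature_stop")
        elif u < 0.75:
            base = "ACGT"[int(rng.integers(4))]
            cds = cds[:pos] + base + cds[pos:]
            kinds.append("frameshift_ins")
        else:
            cds = cds[:pos] + cds[pos + 1:]
            kinds.append("frameshift_del")
    return cds, list(reversed(kinds))


def _truncate(cds: str, rng: np.random.Generator) -> tuple[str, str]:
    """Drop >= 25% of the CDS from one end, cutting at a codon boundary."""
    frac = rng.uniform(0.25, 0.5)
    n_codons = len(cds) // 3
    cut_codons = max(1, int(round(frac * n_codons)))
    if rng.random() < 0.5:
        return cds[cut_codons * 3:], "5p"
    return cds[:len(cds) - cut_codons * 3], "3p"


def _insert_introns(
    dna: str, n_introns: int, rng: np.random.Generator, margin: int = 90
) -> tuple[str, list[tuple[int, int]]]:
    """Insert GT..AG introns at codon boundaries; returns (dna, exon spans)."""
    positions: list[int] = []
    candidates = [p for p in range(margin, len(dna) - margin) if p % 3 == 0]
    rng.shuffle(candidates)
    for p in candidates:
        if len(positions) >= n_introns:
            break
        if all(abs(p - q) >= margin for q in positions):
            positions.append(int(p))
    positions.sort()
    out = []
    exon_spans = []
    prev = 0
    offset = 0
    for pos in positions:
        out.append(dna[prev:pos])
        exon_spans.append((prev + offset, pos + offset))
        intron = "GT" + _random_dna(int(rng.integers(100, 250)), rng) + "AG"
        out.append(intron)
        offset += len(intron)
        prev = pos
    out.append(dna[prev:])
    exon_spans.append((prev + offset, len(dna) + offset))
    return "".join(out), exon_spans


def _check_gene_orf(exon_spans: list, dna: str) -> None:
    cds = "".join(dna[s:e] for s, e in exon_spans)
    if not cds.startswith("ATG"):
        raise AssertionError("emitted 'gene' locus does not start with ATG")
    if cds[-3:] not in STOP_CODONS:
        raise AssertionError("emitted 'gene' locus lacks a terminal stop")
    for i in range(0, len(cds) - 3, 3):
        if cds[i:i + 3] in STOP_CODONS:
            raise AssertionError("emitted 'gene' locus contains an internal stop")


def emit_genomes(
    histories: dict[str, FamilyHistory],
    panel: list[PanelMember],
    subst_rate: float = 0.10,
    pseudo_fraction: float = 0.0,
    truncated_fraction: float = 0.0,
    edge_fraction: float = 0.0,
    flank: int = 5000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[FastaRecord]], pd.DataFrame]:
    """Build one genome per species plus the matching truth table.

    Loci are separated by at least ``2 * flank`` bp of random intergenic
    sequence; "edge" loci get their own contig with the cut end of the
    gene less than 30 bp from the border.
    """
    fractions = (pseudo_fraction, truncated_fraction, edge_fraction)
    if any(f < 0 or f > 1 for f in fractions) or sum(fractions) > 1:
        raise ValueError("status fractions must lie in [0,1] and sum to <= 1")
    olfactory = [m for m in panel if not m.is_decoy]
    if not olfactory:
        raise ValueError("reference panel has no olfactory members")
    if rng is None:
        rng = np.random.default_rng(seed)

    by_family: dict[str, list[PanelMember]] = {}
    for m in olfactory:
        by_family.setdefault(m.family, []).append(m)

    species_list = [leaf.name for leaf in next(iter(histories.values())).tree.leaves()]
    genomes: dict[str, list[FastaRecord]] = {}
    truth_rows = []
    locus_serial = 0

    for sp in species_list:
        planned: list[_PlannedLocus] = []
        for fam, history in histories.items():
            count = history.tip_counts().get(sp, 0)
            exemplars = by_family.get(fam)
            if count and not exemplars:
                raise ValueError(f"no panel exemplar for family {fam!r}")
            _, intron_range = FAMILY_SHAPES.get(fam, (None, (0, 0)))
            for _ in range(count):
                member = exemplars[int(rng.integers(len(exemplars)))]
                cds = mutate_cds(member.cds, subst_rate, rng)
                u = rng.random()
                if u < pseudo_fraction:
                    status = "pseudogene"
                elif u < pseudo_fraction + truncated_fraction:
                    status = "truncated"
                elif u < sum(fractions):
                    status = "edge"
                else:
                    status = "gene"
                n_lof, lof_kinds, cut_side = 0, "", ""
                if status == "pseudogene":
                    cds, kinds = _inject_lof(cds, rng)
                    n_lof, lof_kinds = len(kinds), ",".join(kinds)
                elif status in ("truncated", "edge"):
                    cds, cut_side = _truncate(cds, rng)
                n_introns = int(rng.integers(intron_range[0], intron_range[1] + 1))
                dna, exon_spans = _insert_introns(cds, n_introns, rng)
                if status == "gene":
                    _check_gene_orf(exon_spans, dna)
                strand = "+" if rng.random() < 0.5 else "-"
                planned.append(
                    _PlannedLocus(
                        family=fam,
                        subfamily=member.subfamily,
                        status=status,
                        dna=dna,
                        strand=strand,
                        n_lof=n_lof,
                        lof_kinds=lof_kinds,
                        cut_side=cut_side,
                        exon_spans=exon_spans,
                    )
                )

        order = rng.permutation(len(planned))
        mid = [planned[i] for i in order if planned[i].status != "edge"]
        edge = [planned[i] for i in order if planned[i].status == "edge"]

        contigs: list[FastaRecord] = []
        sp_rows = []

        pieces = [_random_dna(flank + int(rng.integers(0, 1000)), rng)]
        offset = len(pieces[0])
        contig_name = f"{sp}_ctg1"
        for locus in mid:
            placed = locus.dna if locus.strand == "+" else _revcomp(locus.dna)
            start, end = offset, offset + len(placed)
            pieces.append(placed)
            spacer = _random_dna(2 * flank + 500 + int(rng.integers(0, 1000)), rng)
            pieces.append(spacer)
            offset = end + len(spacer)
            locus_serial += 1
            sp_rows.append((locus, contig_name, start, end, locus_serial))
        contigs.append(FastaRecord(id=contig_name, seq="".join(pieces)))

        for k, locus in enumerate(edge, start=2):
            contig_name = f"{sp}_ctg{k}"
            placed = locus.dna if locus.strand == "+" else _revcomp(locus.dna)
            border_gap = _random_dna(int(rng.integers(0, 25)), rng)
            body = _random_dna(2 * flank, rng)
            # put the truncated end of the gene at the contig border
            cut_left = (locus.cut_side == "5p") == (locus.strand == "+")
            if cut_left:
                seq = border_gap + placed + body
                start = len(border_gap)
            else:
                seq = body + placed + border_gap
                start = len(body)
            end = start + len(placed)
            locus_serial += 1
            sp_rows.append((locus, contig_name, start, end, locus_serial))
            contigs.append(FastaRecord(id=contig_name, seq=seq))

        genomes[sp] = contigs
        for locus, contig_name, start, end, serial in sp_rows:
            truth_rows.append(
                {
                    "locus_id": f"L{serial:05d}",
                    "species": sp,
                    "contig": contig_name,
                    "start": start,
                    "end": end,
                    "strand": locus.strand,
                    "family": locus.family,
                    "subfamily": locus.subfamily,
                    "status": locus.status,
                    "n_lof": locus.n_lof,
                    "lof_kinds": locus.lof_kinds,
                    "cut_side": locus.cut_side,
                    "ambiguous": False,
                }
            )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    _verify_truth(histories, truth)
    return genomes, truth


def _verify_truth(histories: dict[str, FamilyHistory], truth: pd.DataFrame) -> None:
    """Locus counts per species and family must equal the simulated tip counts."""
    for fam, history in histories.items():
        for sp, n in history.tip_counts().items():
            emitted = int(((truth["species"] == sp) & (truth["family"] == fam)).sum())
            if emitted != n:
                raise AssertionError(
                    f"{sp}/{fam}: emitted {emitted} loci but simulated tip count is {n}"
                )
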