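"""Spliced protein-to-genome alignment.

A local dynamic programme aligns a reference protein to a genomic region
with five kinds of moves: codon match (stop codons allowed with a
readthrough penalty and recorded as premature stops), single-residue
frameshifts consuming 2 or 4 nt, residue skips, extra codons, and
introns that must start with GT, end with AG, and span at least
``min_intron`` nt. Introns sit between codons (phase 0), matching how
the synthetic genomes are emitted. Frameshifts and in-frame stops
traversed by the optimal alignment are reported as loss-of-function
events with their CDS positions.

The matrix fill is numba-compiled; the traceback is plain Python.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .scoring import (
    AA_ALPHABET,
    BLOSUM62,
    CODON_AA,
    STOP_AA,
    encode_dna,
    encode_protein,
)

# move codes in the traceback matrix
_NONE, _MATCH, _FS2, _FS4, _DEL, _INS, _INTRON = 0, 1, 2, 3, 4, 5, 6

DEFAULT_PENALTIES = {
    "frameshift": -25,
    "stop_readthrough": -15,
    "residue_skip": -12,
    "extra_codon": -12,
    "intron": -40,
    "min_intron": 30,
}


@dataclass(frozen=True)
class LofEvent:
    kind: str      # 'premature_stop' | 'frameshift'
    cds_pos: int   # 0-based offset in the reconstructed CDS


@dataclass
class GeneModel:
    exons: list            # (start, end) in the aligned sequence, ordered
    strand: str
    cds: str
    protein: str
    ref_id: str
    coverage: float        # aligned fraction of the reference protein
    lof_events: list = field(default_factory=list)
    has_start: bool = False
    has_terminal_stop: bool = False
    score: int = 0
    q_start: int = 0
    q_end: int = 0


@njit(cache=True)
def _spliced_fill(q, dna, subst, codon_aa, stop_aa,
                  fs_pen, stop_pen, del_pen, ins_pen, intron_pen, min_intron):
    m = q.shape[0]
    n = dna.shape[0]
    M = np.zeros((m + 1, n + 1), dtype=np.int32)
    P = np.zeros((m + 1, n + 1), dtype=np.int8)
    D = np.full((m + 1, n + 1), -1, dtype=np.int32)
    donor_val = np.full(m + 1, -1000000000, dtype=np.int64)
    donor_pos = np.full(m + 1, -1, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for j in range(n + 1):
        k = j - min_intron
        if k >= 0 and k + 1 < n and dna[k] == 2 and dna[k + 1] == 3:  # GT
            for i in range(m + 1):
                v = M[i, k] + intron_pen
                if v > donor_val[i]:
                    donor_val[i] = v
                    donor_pos[i] = k
        is_ag = j >= 2 and dna[j - 2] == 0 and dna[j - 1] == 2  # ..AG
        for i in range(m + 1):
            s = 0
            mv = 0
            dp = -1
            if i > 0:
                if j >= 3:
                    a = dna[j - 3]
                    b = dna[j - 2]
                    c = dna[j - 1]
                    if a < 4 and b < 4 and c < 4:
                        aa = codon_aa[a * 25 + b * 5 + c]
                        if aa == stop_aa:
                            sc = stop_pen
                        else:
                            sc = subst[q[i - 1], aa]
                    else:
                        sc = -1
                    v = M[i - 1, j - 3] + sc
                    if v > s:
                        s = v
                        mv = _MATCH
                if j >= 2:
                    v = M[i - 1, j - 2] + fs_pen
                    if v > s:
                        s = v
                        mv = _FS2
                if j >= 4:
                    v = M[i - 1, j - 4] + fs_pen
                    if v > s:
                        s = v
                        mv = _FS4
                v = M[i - 1, j] + del_pen
                if v > s:
                    s = v
                    mv = _DEL
            if j >= 3:
                v = M[i, j - 3] + ins_pen
                if v > s:
                    s = v
                    mv = _INS
            if is_ag and donor_val[i] > s:
                s = np.int32(donor_val[i])
                mv = _INTRON
                dp = donor_pos[i]
            M[i, j] = s
            P[i, j] = mv
            D[i, j] = dp
            if s > best:
                best = s
                bi = i
                bj = j
    return M, P, D, best, bi, bj


_STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))


def spliced_align(
    reference_protein: str,
    region_sequence: str,
    ref_id: str = "ref",
    strand: str = "+",
    score_floor: int = 40,
    penalties: Optional[dict] = None,
) -> Optional[GeneModel]:
    """Align ``reference_protein`` to ``region_sequence``.

    Returns the best-scoring gene model, or None when nothing reaches
    ``score_floor``.
    """
    pen = dict(DEFAULT_PENALTIES)
    if penalties:
        pen.update(penalties)
    q = encode_protein(reference_protein)
    dna = encode_dna(region_sequence)
    if len(q) == 0 or len(dna) == 0:
        return None
    M, P, D, best, bi, bj = _spliced_fill(
        q, dna, BLOSUM62, CODON_AA, np.int8(STOP_AA),
        pen["frameshift"], pen["stop_readthrough"], pen["residue_skip"],
        pen["extra_codon"], pen["intron"], pen["min_intron"],
    )
    if best < score_floor:
        return None

    moves = []
    i, j = bi, bj
    while P[i, j] != _NONE:
        mv = int(P[i, j])
        moves.append((mv, i, j, int(D[i, j])))
        if mv == _MATCH:
            i, j = i - 1, j - 3
        elif mv == _FS2:
            i, j = i - 1, j - 2
        elif mv == _FS4:
            i, j = i - 1, j - 4
        elif mv == _DEL:
            i = i - 1
        elif mv == _INS:
            j = j - 3
        elif mv == _INTRON:
            j = int(moves[-1][3])
    q_start, dna_start = i, j
    moves.reverse()

    cds_parts: list[str] = []
    prot_parts: list[str] = []
    events: list[LofEvent] = []
    segments: list[list[int]] = []
    cds_len = 0

    def consume(lo: int, hi: int) -> None:
        nonlocal cds_len
        cds_parts.append(region_sequence[lo:hi])
        if segments and segments[-1][1] == lo:
            segments[-1][1] = hi
        else:
            segments.append([lo, hi])
        cds_len += hi - lo

    for mv, mi, mj, md in moves:
        if mv == _MATCH:
            codon = region_sequence[mj - 3:mj]
            if codon.upper() in _STOP_CODONS:
                events.append(LofEvent("premature_stop", cds_len))
                prot_parts.append("*")
            else:
                aa = _translate_codon(codon)
                prot_parts.append(aa)
            consume(mj - 3, mj)
        elif mv in (_FS2, _FS4):
            width = 2 if mv == _FS2 else 4
            events.append(LofEvent("frameshift", cds_len))
            prot_parts.append("X")
            consume(mj - width, mj)
        elif mv == _DEL:
            pass
        elif mv == _INS:
            codon = region_sequence[mj - 3:mj]
            if codon.upper() in _STOP_CODONS:
                events.append(LofEvent("premature_stop", cds_len))
                prot_parts.append("*")
            else:
                prot_parts.append(_translate_codon(codon))
            consume(mj - 3, mj)
        elif mv == _INTRON:
            pass

    cds = "".join(cds_parts)
    q_end = bi
    m = len(reference_protein)
    coverage = (q_end - q_start) / m if m else 0.0
    # Local alignment may trim a few mismatched residues at either end of a
    # genuinely full-length gene; project the trimmed residues back onto the
    # genome in frame and look for the start / stop codon there.
    slack = 15
    start_pos = dna_start - 3 * q_start
    has_start = (
        q_start <= slack
        and start_pos >= 0
        and region_sequence[start_pos:start_pos + 3].upper() == "ATG"
    )
    stop_pos = bj + 3 * (m - q_end)
    has_terminal_stop = (
        (m - q_end) <= slack
        and region_sequence[stop_pos:stop_pos + 3].upper() in _STOP_CODONS
    )
    return GeneModel(
        exons=[(lo, hi) for lo, hi in segments],
        strand=strand,
        cds=cds,
        protein="".join(prot_parts),
        ref_id=ref_id,
        coverage=coverage,
        lof_events=events,
        has_start=has_start,
        has_terminal_stop=has_terminal_stop,
        score=int(best),
        q_start=int(q_start),
        q_end=int(q_end),
    )


def _translate_codon(codon: str) -> str:
    dna = encode_dna(codon)
    if (dna > 3).any():
        return "X"
    aa_idx = CODON_AA[int(dna[0]) * 25 + int(dna[1]) * 5 + int(dna[2])]
    return AA_ALPHABET[aa_idx]
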