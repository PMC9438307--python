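"""Shared alphabet encodings and BLOSUM62 scoring tables.

Amino acids are encoded over a 25-letter alphabet (the BLOSUM62 alphabet
from biopython, including '*' for stop and 'X' for unknown); DNA over
ACGT plus N. Codon translation is precomputed as a flat lookup of size
5^3 so that whole frames translate with one fancy-indexing pass.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

_blosum = substitution_matrices.load("BLOSUM62")
AA_ALPHABET = "".join(_blosum.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_AA = len(AA_ALPHABET)
STOP_AA = AA_INDEX["*"]
UNKNOWN_AA = AA_INDEX["X"]

BLOSUM62 = np.asarray(_blosum, dtype=np.int16)

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

_DNA_INDEX = np.full(256, 4, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _DNA_INDEX[ord(base)] = i
    _DNA_INDEX[ord(base.lower())] = i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N

CODON_AA = np.full(125, UNKNOWN_AA, dtype=np.int8)
for codon, aa in standard_dna_table.forward_table.items():
    if set(codon) <= set("ACGT"):
        idx = ("ACGT".index(codon[0]) * 25 + "ACGT".index(codon[1]) * 5
               + "ACGT".index(codon[2]))
        CODON_AA[idx] = AA_INDEX[aa]
for codon in standard_dna_table.stop_codons:
    idx = ("ACGT".index(codon[0]) * 25 + "ACGT".index(codon[1]) * 5
           + "ACGT".index(codon[2]))
    CODON_AA[idx] = STOP_AA


def encode_dna(seq: str) -> np.ndarray:
    return _DNA_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_encoded(dna: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[dna[::-1]]


def encode_protein(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, aa in enumerate(seq):
        out[i] = AA_INDEX.get(aa.upper(), UNKNOWN_AA)
    return out


def translate_encoded(dna: np.ndarray, offset: int = 0) -> np.ndarray:
    """Translate one reading frame of an encoded DNA array to aa indices."""
    usable = (len(dna) - offset) // 3
    if usable <= 0:
        return np.empty(0, dtype=np.int8)
    codons = dna[offset:offset + usable * 3].reshape(usable, 3).astype(np.int32)
    return CODON_AA[codons[:, 0] * 25 + codons[:, 1] * 5 + codons[:, 2]]


def codon_index(dna: np.ndarray, pos: int) -> int:
    """Flat codon index for dna[pos:pos+3]; -1 when any base is ambiguous."""
    a, b, c = int(dna[pos]), int(dna[pos + 1]), int(dna[pos + 2])
    if a > 3 or b > 3 or c > 3:
        return -1
    return a * 25 + b * 5 + c
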