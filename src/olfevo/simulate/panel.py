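"""Reference receptor panels: labelled exemplar proteins plus decoy GPCRs.

Each of the four families gets one random ancestral coding sequence;
subfamily exemplars are diverged copies of that ancestor, so that
within-family hits outscore cross-family hits by a wide margin. Decoys
are unrelated GPCR-like proteins used to absorb non-olfactory matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from ..io import FastaRecord

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
STOP_CODONS = ("TAA", "TAG", "TGA")

# (length in codons, intron count range) per family; OR is single-exon.
FAMILY_SHAPES = {
    "OR": (306, (0, 0)),
    "TAAR": (334, (1, 2)),
    "OlfC": (442, (1, 2)),
    "ORA": (318, (1, 2)),
}

SUBFAMILIES = {
    "OR": ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta"),
    "TAAR": ("taarA", "taarB", "taarC"),
    "OlfC": ("olfcA", "olfcB", "olfcC"),
    "ORA": tuple(f"ORA{i}" for i in range(1, 9)),
}


@dataclass(frozen=True)
class PanelMember:
    name: str
    family: str  # OR | TAAR | OlfC | ORA | non-olfactory
    subfamily: str
    is_decoy: bool
    cds: str

    @property
    def protein(self) -> str:
        return str(Seq(self.cds[:-3]).translate())


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random open reading frame: ATG + sense codons + TAA."""
    interior = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in interior) + "TAA"


def mutate_cds(cds: str, divergence: float, rng: np.random.Generator) -> str:
    """Jukes-Cantor style point substitutions preserving the reading frame.

    Substitutions hit each site independently with probability
    ``divergence``; the initial ATG and terminal stop are restored and any
    interior codon that becomes a stop is reverted, so the product stays a
    clean ORF.
    """
    bases = list(cds)
    alphabet = "ACGT"
    n = len(bases)
    hit = rng.random(n) < divergence
    for i in np.flatnonzero(hit):
        choices = [c for c in alphabet if c != bases[i]]
        bases[i] = choices[int(rng.integers(3))]
    # repair: keep start codon, terminal stop, and no interior stops
    bases[0:3] = "ATG"
    bases[n - 3:n] = "TAA"
    for i in range(3, n - 3, 3):
        codon = "".join(bases[i:i + 3])
        if codon in STOP_CODONS:
            bases[i:i + 3] = cds[i:i + 3]
    return "".join(bases)


def make_reference_panel(
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    subfamily_divergence: float = 0.12,
    n_decoys: int = 5,
    decoy_codons: int = 330,
) -> list[PanelMember]:
    if rng is None:
        rng = np.random.default_rng(seed)
    members: list[PanelMember] = []
    for family, (n_codons, _introns) in FAMILY_SHAPES.items():
        ancestor = random_cds(n_codons, rng)
        for sub in SUBFAMILIES[family]:
            cds = mutate_cds(ancestor, subfamily_divergence, rng)
            members.append(
                PanelMember(
                    name=f"{family}_{sub}_ref",
                    family=family,
                    subfamily=sub,
                    is_decoy=False,
                    cds=cds,
                )
            )
    for i in range(n_decoys):
        members.append(
            PanelMember(
                name=f"gpcr_decoy{i + 1}",
                family="non-olfactory",
                subfamily="decoy",
                is_decoy=True,
                cds=random_cds(decoy_codons, rng),
            )
        )
    return members


def panel_to_records(panel: list[PanelMember], as_protein: bool = False) -> list[FastaRecord]:
    records = []
    for m in panel:
        desc = f"family={m.family} subfamily={m.subfamily} decoy={int(m.is_decoy)}"
        seq = m.protein if as_protein else m.cds
        records.append(FastaRecord(id=m.name, seq=seq, description=desc))
    return records


def panel_from_records(records: list[FastaRecord]) -> list[PanelMember]:
    members = []
    for rec in records:
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        members.append(
            PanelMember(
                name=rec.id,
                family=fields.get("family", "non-olfactory"),
                subfamily=fields.get("subfamily", ""),
                is_decoy=fields.get("decoy", "0") == "1",
                cds=rec.seq,
            )
        )
    return members
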