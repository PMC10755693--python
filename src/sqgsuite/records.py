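"""Protein sequence records and FASTA I/O.

``ProteinRecord`` is the unit passed between the alignment, profile-search and
network modules: a sequence plus the metadata (taxonomy, source genome,
pathway context) used to colour network nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted on input; X is the ambiguity code (scored 0 in alignments)
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its network-node metadata."""

    id: str
    seq: str
    taxonomy: str | None = None
    genome_id: str | None = None
    pathway_context: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.seq) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-protein characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrap), metadata in the description."""
    seqrecords = []
    for rec in records:
        desc_parts = []
        if rec.taxonomy:
            desc_parts.append(f"taxonomy={rec.taxonomy}")
        if rec.genome_id:
            desc_parts.append(f"genome={rec.genome_id}")
        if rec.description:
            desc_parts.append(rec.description)
        seqrecords.append(
            SeqRecord(Seq(rec.seq), id=rec.id, description=" ".join(desc_parts))
        )
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; ``taxonomy=``/``genome=`` description tokens are
    recovered into the corresponding fields."""
    out = []
    for sr in SeqIO.parse(str(path), "fasta"):
        taxonomy = genome = None
        extra: list[str] = []
        for token in sr.description.split()[1:]:
            if token.startswith("taxonomy="):
                taxonomy = token[len("taxonomy="):]
            elif token.startswith("genome="):
                genome = token[len("genome="):]
            else:
                extra.append(token)
        out.append(
            ProteinRecord(
                id=sr.id,
                seq=str(sr.seq).upper(),
                taxonomy=taxonomy,
                genome_id=genome,
                description=" ".join(extra),
            )
        )
    return out
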