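"""Thin FASTA dict helpers (Biopython-backed, 60-column wrapping)."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta_dict(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta_dict(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
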