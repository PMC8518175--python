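"""Physicochemical properties of proteins, ProtParam-style.

The three quantities a gene-family survey typically tabulates per protein are
its length in residues (derivable from the ORF length), its average molecular
weight, and its theoretical isoelectric point.  Both the mass table (average,
isotope-abundance-weighted residue masses) and the pKa set (Bjellqvist, as
used by the Expasy ProtParam server) are shipped as data files rather than
hard-coded, so the conventions this module follows are inspectable.

Charge model for the pI: Henderson–Hasselbalch over the free N-terminus
(residue-specific pKa where the Bjellqvist set defines one), the free
C-terminus (likewise), and the D/E/C/Y/H/K/R side chains.  Net charge is
strictly decreasing in pH, so the root is unique and found by bisection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _load_data(name: str) -> dict:
    with resources.files("camtakit.data").joinpath(name).open() as fh:
        return json.load(fh)


_MASSES = _load_data("residue_masses.json")
_PKA = _load_data("pka_bjellqvist.json")
WATER_MASS = _MASSES["water"]
RESIDUE_MASS = _MASSES["residues"]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier plus uppercase canonical amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty protein sequence")
        if not self.sequence.isupper():
            raise ValueError(f"{self.id}: sequence must be uppercase")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical letters {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PhysChemSummary:
    """Length (aa), average molecular weight (Da), theoretical pI."""

    length: int
    molecular_weight: float
    isoelectric_point: float

    def __post_init__(self):
        assert self.length >= 1
        assert self.molecular_weight > 0
        assert 0.0 < self.isoelectric_point < 14.0


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA; the first whitespace-delimited
    header token becomes the record id."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
    return records


def protein_length_from_orf(orf_length: int) -> int:
    """Protein length implied by an ORF length in bp.

    The ORF includes the terminal stop codon, which does not encode a
    residue, hence ``orf_length / 3 - 1``.
    """
    if orf_length % 3 != 0:
        raise ValueError(
            f"ORF length {orf_length} not divisible by 3 (remainder {orf_length % 3})"
        )
    if orf_length <= 3:
        raise ValueError(f"ORF length {orf_length} leaves no coding codon")
    return orf_length // 3 - 1


def molecular_weight(p: ProteinRecord) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water.

    Rejects any non-canonical letter (including X) rather than guessing a
    mass.  Reported to 2 decimals, matching the convention of the reference
    calculator.
    """
    mass = WATER_MASS + sum(RESIDUE_MASS[aa] for aa in p.sequence)
    return round(mass, 2)


def _charge_at(sequence: str, ph: float) -> float:
    pos = _PKA["positive"]
    neg = _PKA["negative"]
    nterm_pka = _PKA["nterm_by_residue"].get(sequence[0], pos["Nterm"])
    cterm_pka = _PKA["cterm_by_residue"].get(sequence[-1], neg["Cterm"])
    charge = 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    charge -= 1.0 / (1.0 + 10 ** (cterm_pka - ph))
    for aa, pka in pos.items():
        if aa == "Nterm":
            continue
        charge += sequence.count(aa) / (1.0 + 10 ** (ph - pka))
    for aa, pka in neg.items():
        if aa == "Cterm":
            continue
        charge -= sequence.count(aa) / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(p: ProteinRecord) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The bracket is narrowed below 5e-4 pH units (tighter than the 2-decimal
    reporting precision).
    """
    lo, hi = 0.0, 14.0
    while hi - lo > 5e-4:
        mid = 0.5 * (lo + hi)
        if _charge_at(p.sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def net_charge(p: ProteinRecord, ph: float) -> float:
    """Net charge of the protein at a given pH (Henderson–Hasselbalch)."""
    return _charge_at(p.sequence, ph)


def physchem_summary(p: ProteinRecord) -> PhysChemSummary:
    return PhysChemSummary(
        length=len(p),
        molecular_weight=molecular_weight(p),
        isoelectric_point=round(isoelectric_point(p), 2),
    )


def property_table(proteins: list[ProteinRecord]) -> pd.DataFrame:
    """Per-protein property report mirroring the classic family-survey table."""
    rows = []
    for p in proteins:
        s = physchem_summary(p)
        rows.append(
            {
                "protein": p.id,
                "length_aa": s.length,
                "orf_bp": (s.length + 1) * 3,
                "mw_da": s.molecular_weight,
                "pi": s.isoelectric_point,
            }
        )
    return pd.DataFrame(rows)


def load_family_reference() -> pd.DataFrame:
    """Published reference annotation of the ten durian CAMTA genes
    (NCBI accessions, ORF lengths, protein lengths, MW, pI, exon counts)."""
    with resources.as_file(
        resources.files("camtakit.data").joinpath("durian_camta_reference.tsv")
    ) as path:
        return pd.read_csv(Path(path), sep="\t")
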