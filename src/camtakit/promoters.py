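"""IUPAC degenerate motif scanning of promoters and Fisher enrichment.

Scans are position-exact and strand-aware: reverse-strand hits are found by
scanning the reverse complement and reported at forward coordinates with
strand '-'.  Overlapping occurrences are all counted.  Enrichment between
two gene sets contrasts motif occurrences against scanned positions in a
2x2 Fisher's exact test (two-sided).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .fastaio import revcomp

IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class IupacMotif:
    name: str
    pattern: str

    def __post_init__(self):
        if not self.pattern:
            raise ValueError(f"motif {self.name}: empty pattern")
        bad = [c for c in self.pattern if c not in IUPAC_SETS]
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC letter {bad[0]!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def degeneracy(self) -> int:
        deg = 1
        for c in self.pattern:
            deg *= len(IUPAC_SETS[c])
        return deg


@dataclass
class MotifHit:
    gene_id: str
    motif_name: str
    strand: str
    start: int  # 0-based forward coordinate


@dataclass
class EnrichmentResult:
    motif_name: str
    hits_a: int
    scanned_a: int
    hits_b: int
    scanned_b: int
    odds_ratio: float
    p_two_sided: float

    def __post_init__(self):
        assert 0 <= self.p_two_sided <= 1
        assert self.hits_a <= self.scanned_a and self.hits_b <= self.scanned_b


def expand_iupac(m: IupacMotif) -> set[str]:
    """Cartesian expansion into the set of concrete DNA words."""
    choices = [IUPAC_SETS[c] for c in m.pattern]
    return {"".join(w) for w in itertools.product(*choices)}


def _forward_hits(seq: str, m: IupacMotif) -> list[int]:
    k = len(m)
    sets = [IUPAC_SETS[c] for c in m.pattern]
    out = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if all(b in s for b, s in zip(window, sets)):
            out.append(i)
    return out


def scan(
    promoter: str, m: IupacMotif, gene_id: str = "", strands: str = "both"
) -> list[MotifHit]:
    """Sliding-window IUPAC match at every offset; N in the promoter never
    matches.  ``strands`` is "forward" or "both"."""
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    promoter = promoter.upper()
    hits = [MotifHit(gene_id, m.name, "+", i) for i in _forward_hits(promoter, m)]
    if strands == "both":
        rc = revcomp(promoter)
        k, L = len(m), len(promoter)
        for i in _forward_hits(rc, m):
            hits.append(MotifHit(gene_id, m.name, "-", L - k - i))
    return hits


def count_motif_library(
    promoters: dict[str, str], library: list[IupacMotif], strands: str = "both"
) -> pd.DataFrame:
    """Per-gene, per-motif, per-strand occurrence table (zero rows included).

    Columns: gene_id, motif_name, strand, count, positions (0-based forward
    starts, comma-joined).
    """
    names = [m.name for m in library]
    if len(set(names)) != len(names):
        raise ValueError("duplicate motif names in library")
    strand_values = ("+",) if strands == "forward" else ("+", "-")
    rows = []
    for gene, seq in promoters.items():
        for m in library:
            hits = scan(seq, m, gene_id=gene, strands=strands)
            by_strand: dict[str, list[int]] = {s: [] for s in strand_values}
            for h in hits:
                by_strand[h.strand].append(h.start)
            for s in strand_values:
                pos = sorted(by_strand[s])
                rows.append(
                    {
                        "gene_id": gene,
                        "motif_name": m.name,
                        "strand": s,
                        "count": len(pos),
                        "positions": ",".join(map(str, pos)),
                    }
                )
    return pd.DataFrame(rows)


def scanned_positions(promoters: dict[str, str], k: int, strands: str = "both") -> int:
    """Total number of scanned windows: sum over promoters of (L - k + 1)
    per scanned strand."""
    per_strand = sum(max(0, len(s) - k + 1) for s in promoters.values())
    return per_strand * (2 if strands == "both" else 1)


def fisher_enrichment(
    counts_a: tuple[int, int], counts_b: tuple[int, int], motif_name: str = ""
) -> EnrichmentResult:
    """Two-sided Fisher's exact test on [[hits_a, scanned_a - hits_a],
    [hits_b, scanned_b - hits_b]].

    The odds ratio is the sample (cross-product) odds ratio, with the
    Haldane 0.5 continuity correction applied when any cell is zero.
    """
    (ha, na), (hb, nb) = counts_a, counts_b
    if min(ha, na, hb, nb) < 0 or ha > na or hb > nb:
        raise ValueError("counts must satisfy 0 <= hits <= scanned")
    table = [[ha, na - ha], [hb, nb - hb]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    cells = [float(c) for row in table for c in row]
    if 0 in cells:
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    odds = (a * d) / (b * c)
    return EnrichmentResult(
        motif_name=motif_name,
        hits_a=ha,
        scanned_a=na,
        hits_b=hb,
        scanned_b=nb,
        odds_ratio=odds,
        p_two_sided=float(p),
    )


def read_motif_library(path) -> list[IupacMotif]:
    """Two-column TSV (name, IUPAC pattern) -> motif list."""
    df = pd.read_csv(path, sep="\t")
    return [IupacMotif(str(r["name"]), str(r["pattern"])) for _, r in df.iterrows()]


def default_cis_element_library() -> list[IupacMotif]:
    """Bundled example library of plant cis-element consensi (ABRE, ERE,
    G-box, GT-1, CGTCA/TGACG, ...) plus the CAMTA recognition cores
    MCGCGB and MCGTGT."""
    from importlib import resources

    with resources.as_file(
        resources.files("camtakit.data").joinpath("cis_element_library.tsv")
    ) as p:
        return read_motif_library(p)
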