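"""Paralog detection, codon alignment, NG86 Ka/Ks, and divergence dating.

Paralogous pairs are found by reciprocal best hit (RBH) under deterministic
Needleman-Wunsch global alignment (BLOSUM62, affine gaps) with the family-
survey thresholds: identity > 70% and coverage > 70% of the longer sequence.
Global alignment scores replace database-search e-values for best-hit
ranking, which keeps the procedure reproducible without a reference
database while preserving the stated thresholds exactly.

Ka/Ks follows Nei & Gojobori (1986): fractional synonymous/nonsynonymous
site counts per codon averaged over the two sequences; codon pairs differing
at more than one position averaged over all substitution orderings (pathways
through stop codons excluded when an alternative exists); proportions
corrected with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).
Duplication age in million years is T = Ks / (2 lambda) with the eudicot
clock lambda = 6.1e-9 substitutions per site per year.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import Seq

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    GENETIC_CODE[_stop] = "*"

DEFAULT_CLOCK_RATE = 6.1e-9  # synonymous substitutions per site per year


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    coverage_pct: float

    def __post_init__(self):
        assert len(self.aligned_a) == len(self.aligned_b)
        assert 0 <= self.identity_pct <= 100
        assert 0 <= self.coverage_pct <= 100


@dataclass
class ParalogPair:
    gene_a: str
    gene_b: str
    identity_pct: float
    coverage_pct: float
    ka: float | None = None
    ks: float | None = None
    ratio: float | None = None
    divergence_mya: float | None = None
    selection: str | None = None


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a, b, gap_open: float = 11.0, gap_extend: float = 1.0
) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment on BLOSUM62 with affine gaps.

    Identity is the percentage of identical columns over all aligned columns;
    coverage is the percentage of the longer sequence inside the aligned
    (non-terminal-gap) span.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a.sequence, b.sequence)[0]
    sa, sb = str(aln[0]), str(aln[1])
    ncols = len(sa)
    ident = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    first = next(i for i in range(ncols) if sa[i] != "-" and sb[i] != "-")
    last = next(i for i in range(ncols - 1, -1, -1) if sa[i] != "-" and sb[i] != "-")
    longer = max(len(a.sequence), len(b.sequence))
    longer_seq = sa if len(a.sequence) >= len(b.sequence) else sb
    covered = sum(
        1 for i in range(first, last + 1) if longer_seq[i] != "-"
    )
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        aligned_a=sa,
        aligned_b=sb,
        score=float(aln.score),
        identity_pct=100.0 * ident / ncols,
        coverage_pct=100.0 * covered / longer,
    )


def reciprocal_best_pairs(
    proteins: list,
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[list[ParalogPair], dict[tuple[str, str], PairwiseAlignment]]:
    """All-vs-all global alignment and reciprocal-best-hit pairing.

    A pair (a, b) is reported iff each is the other's best-scoring partner
    (ties broken toward the lexicographically smaller id) and both the
    identity and coverage thresholds hold.  RBH pairs are disjoint by
    construction.  The output is independent of input order.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    prots = sorted(proteins, key=lambda p: p.id)
    alignments: dict[tuple[str, str], PairwiseAlignment] = {}
    for pa, pb in itertools.combinations(prots, 2):
        alignments[(pa.id, pb.id)] = global_align(pa, pb, gap_open, gap_extend)

    def get(x: str, y: str) -> PairwiseAlignment:
        return alignments[(x, y)] if (x, y) in alignments else alignments[(y, x)]

    best: dict[str, str] = {}
    for p in prots:
        partners = [q.id for q in prots if q.id != p.id]
        best[p.id] = max(partners, key=lambda q: (get(p.id, q).score, q))

    pairs = []
    for p in prots:
        q = best[p.id]
        if p.id < q and best[q] == p.id:
            aln = get(p.id, q)
            if aln.identity_pct > min_identity and aln.coverage_pct > min_coverage:
                pairs.append(
                    ParalogPair(
                        gene_a=p.id,
                        gene_b=q,
                        identity_pct=aln.identity_pct,
                        coverage_pct=aln.coverage_pct,
                    )
                )
    return pairs, alignments


def translate_cds(cds: str) -> str:
    """Translate a CDS, dropping one terminal stop codon if present."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def codon_align(
    aln: PairwiseAlignment, cds_a: str, cds_b: str
) -> tuple[str, str]:
    """Back-thread a protein alignment onto the two CDSs (PAL2NAL-style).

    Each aligned amino-acid column maps to one codon column; protein gaps
    become ``---`` triplets.  The CDSs must translate to the ungapped
    proteins (terminal stops ignored).
    """
    out = []
    for name, gapped, cds in ((aln.id_a, aln.aligned_a, cds_a), (aln.id_b, aln.aligned_b, cds_b)):
        protein = gapped.replace("-", "")
        translated = translate_cds(cds)
        if translated != protein:
            bad = next(
                (i for i, (x, y) in enumerate(zip(translated, protein)) if x != y),
                min(len(translated), len(protein)),
            )
            raise ValueError(
                f"{name}: CDS does not translate to the aligned protein "
                f"(first discordant residue at position {bad + 1})"
            )
        codons = [cds[3 * i : 3 * i + 3] for i in range(len(protein))]
        row = []
        k = 0
        for aa in gapped:
            if aa == "-":
                row.append("---")
            else:
                row.append(codons[k])
                k += 1
        out.append("".join(row))
    return out[0], out[1]


def _synonymous_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible point mutations at ``pos`` that are
    synonymous; mutations to stop codons count as nonsynonymous."""
    aa = GENETIC_CODE[codon]
    syn = 0
    for base in "ACGT":
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if GENETIC_CODE[alt] == aa and GENETIC_CODE[alt] != "*":
            syn += 1
    return syn / 3.0


def codon_sites(codon: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) site counts of one codon."""
    s = sum(_synonymous_fraction(codon, pos) for pos in range(3))
    return s, 3.0 - s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts over all
    substitution orderings between two codons; orderings that pass through a
    stop codon are excluded when any stop-free ordering exists."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                through_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[current] and GENETIC_CODE[nxt] != "*":
                sd += 1
            else:
                nd += 1
            current = nxt
        paths.append((sd, nd, through_stop))
    clean = [(sd, nd) for sd, nd, ts in paths if not ts]
    use = clean if clean else [(sd, nd) for sd, nd, _ in paths]
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a raw proportion of differences."""
    import math

    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: substitution saturation")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(codon_aln: tuple[str, str]) -> tuple[float, float, float | None]:
    """Nei-Gojobori (1986) Ka, Ks and Ka/Ks from a codon alignment.

    Codon columns containing gaps or non-ACGT letters are dropped (pairwise
    deletion).  Returns (Ka, Ks, ratio); the ratio is None when Ks = 0.
    """
    seq_a, seq_b = codon_aln
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    s_sites_a = s_sites_b = 0.0
    n_sites_a = n_sites_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if set(ca + cb) - set("ACGT"):
            continue
        if GENETIC_CODE[ca] == "*" or GENETIC_CODE[cb] == "*":
            continue
        n_codons += 1
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_sites_a += sa
        n_sites_a += na
        s_sites_b += sb
        n_sites_b += nb
        dsd, dnd = _pathway_counts(ca, cb)
        sd += dsd
        nd += dnd
    if n_codons == 0:
        raise ValueError("no complete codon columns after pairwise deletion")
    s_sites = 0.5 * (s_sites_a + s_sites_b)
    n_sites = 0.5 * (n_sites_a + n_sites_b)
    if s_sites == 0:
        raise ValueError("zero synonymous sites")
    ps = sd / s_sites
    pn = nd / n_sites
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    ratio = ka / ks if ks > 0 else None
    return ka, ks, ratio


def divergence_time(ks: float, lam: float = DEFAULT_CLOCK_RATE) -> float:
    """Duplication age in million years: T = Ks / (2 lambda)."""
    if ks < 0:
        raise ValueError(f"negative Ks: {ks}")
    return ks / (2.0 * lam) / 1e6


def classify_selection(ratio: float, tol: float = 1e-9) -> str:
    """Ka/Ks < 1: purifying; > 1: positive; = 1 (within tol): neutral."""
    if ratio < 0:
        raise ValueError("Ka/Ks ratio cannot be negative")
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def paralog_report(
    proteins: list,
    cds_by_id: dict[str, str],
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
    lam: float = DEFAULT_CLOCK_RATE,
) -> list[ParalogPair]:
    """RBH pairing followed by codon-level divergence for each pair."""
    pairs, alignments = reciprocal_best_pairs(proteins, min_identity, min_coverage)
    for pair in pairs:
        aln = alignments[(pair.gene_a, pair.gene_b)]
        caln = codon_align(aln, cds_by_id[pair.gene_a], cds_by_id[pair.gene_b])
        ka, ks, ratio = ng86_kaks(caln)
        pair.ka, pair.ks, pair.ratio = ka, ks, ratio
        pair.divergence_mya = divergence_time(ks, lam)
        pair.selection = classify_selection(ratio) if ratio is not None else None
    return pairs
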