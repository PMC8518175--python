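"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study conditions of a small-family genome survey:
a ten-gene family laid out as five paralog pairs on draft-genome scaffolds,
12-13 exons per gene, 1 kb promoters, paralog synonymous divergence
calibrated to the 14.64-17.95 MYA duplication window (Ks 0.179-0.219 at
lambda = 6.1e-9 per site per year) with Ka/Ks < 1, promoters with planted
IUPAC motif occurrences, count matrices with planted hub-partner
correlations (target r 0.97, 30 samples) plus per-sample library-size and
composition offsets, and Ct tables with known fold changes.

Background base composition is uniform over A/C/G/T, which keeps the
rejection sampling that scrubs accidental motif occurrences tractable.  All
randomness flows from one seeded generator passed explicitly; substitutions
are classified (synonymous / nonsynonymous) against the universal code at
the moment they are introduced, which makes realized Ka/Ks well defined for
recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .duplication import GENETIC_CODE, codon_sites, jukes_cantor
from .fastaio import revcomp, write_fasta_dict
from .genestruct import GeneModel, write_gff3
from .promoters import IUPAC_SETS, IupacMotif, expand_iupac

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
STOP_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa == "*")
BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ParalogSpec:
    target_ka: float
    target_ks: float

    def __post_init__(self):
        if self.target_ka < 0 or self.target_ks < 0:
            raise ValueError("substitution targets must be >= 0")


@dataclass
class MotifPlantSpec:
    gene_set: str  # label resolved against a gene-set mapping ("all" = every gene)
    motif: str
    per_promoter: int
    strand: str = "+"

    def __post_init__(self):
        IupacMotif("planted", self.motif)  # validates the IUPAC letters
        if self.per_promoter < 0:
            raise ValueError("occurrences per promoter must be >= 0")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass
class ExpressionSpec:
    n_hubs: int = 2
    n_partners_pos: int = 30
    n_partners_neg: int = 30
    n_noise: int = 440
    n_samples_per_group: int = 15
    target_r: float = 0.97
    library_size_factors: list[float] | None = None
    partner_noise_sd: float | None = None  # None: calibrated from target_r
    base_log2: float = 8.0
    group_shift: float = 2.0
    hub_sd: float = 1.0
    noise_sd: float = 0.7
    groups: tuple[str, str] = ("mature", "ripe")

    def __post_init__(self):
        if not -1.0 < self.target_r < 1.0:
            raise ValueError("|target_r| must be < 1")
        if self.n_samples_per_group < 3:
            raise ValueError("need >= 3 samples per group")


@dataclass
class QpcrSpec:
    true_folds: dict[str, float] = field(
        default_factory=lambda: {"M": 1.0, "MR": 2.0, "R": 4.0}
    )
    calibrator: str = "M"
    ct_sd: float = 0.2
    n_bio: int = 3
    n_tech: int = 3
    reference_gene: str = "EF1a"
    target_gene: str = "DzCAMTA3"
    reference_ct: float = 20.0
    target_base_ct: float = 26.0

    def __post_init__(self):
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be >= 0")
        if not self.reference_gene:
            raise ValueError("a reference gene is required")
        if self.calibrator not in self.true_folds:
            raise ValueError("calibrator group missing from true_folds")


def _default_paralog_specs() -> list[ParalogSpec]:
    # Five pairs whose synonymous divergence spans the family's published
    # duplication window (14.64-17.95 MYA at lambda = 6.1e-9/site/year),
    # all under purifying selection (Ka/Ks ~ 0.3).
    ks_values = [0.17861, 0.18870, 0.19880, 0.20890, 0.21899]
    return [ParalogSpec(target_ka=round(0.3 * ks, 5), target_ks=ks) for ks in ks_values]


@dataclass
class SynthesisConfig:
    seed: int
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (12, 13)
    scaffold_count: int = 8
    promoter_len: int = 1000
    cds_codons: int = 300
    intron_len: tuple[int, int] = (80, 400)
    scaffold_len: int | None = None  # autosized when None
    paralog_specs: list[ParalogSpec] = field(default_factory=_default_paralog_specs)
    motif_plant_specs: list[MotifPlantSpec] = field(default_factory=list)
    expression_spec: ExpressionSpec = field(default_factory=ExpressionSpec)
    qpcr_spec: QpcrSpec = field(default_factory=QpcrSpec)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required: no hidden global randomness")
        if self.exons_per_gene[0] < 1:
            raise ValueError("exon counts must be >= 1")
        if self.promoter_len <= 0:
            raise ValueError("promoter_len must be > 0")
        if self.cds_codons < 3:
            raise ValueError("need at least start + one sense codon + stop")
        if len(self.paralog_specs) * 2 > self.n_genes:
            raise ValueError("more paralog pairs than genes can host")


# ---------------------------------------------------------------------------
# truth records


@dataclass
class RealizedCounts:
    """Substitutions actually introduced into a paralog, and the realized
    per-site divergence they imply (JC-corrected, NG86 site counts averaged
    over the two sequences)."""

    syn_subs: int
    nonsyn_subs: int
    syn_sites: float
    nonsyn_sites: float
    realized_ks: float
    realized_ka: float


@dataclass
class PairTruth:
    gene_a: str
    gene_b: str
    target_ka: float
    target_ks: float
    realized: RealizedCounts


@dataclass
class PlantedMotif:
    gene_id: str
    motif: str
    strand: str
    start: int  # 0-based within the promoter
    word: str


@dataclass
class ExpressionTruth:
    hub_partners: dict[str, list[tuple[str, str]]]  # hub -> [(gene, sign)]
    target_r: float
    groups: dict[str, str]  # sample -> group label
    library_size_factors: dict[str, float]


@dataclass
class TruthBundle:
    pairs: list[PairTruth] = field(default_factory=list)
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    expected_motif_hits: list[PlantedMotif] = field(default_factory=list)
    expression: ExpressionTruth | None = None
    qpcr_true_folds: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())


# ---------------------------------------------------------------------------
# sequence-level generators


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n-2) random sense codons + a random stop codon."""
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(STOP_CODONS)
    return "ATG" + "".join(body) + str(stop)


def _site_counts(cds: str, n_codons: int) -> tuple[float, float]:
    s = n = 0.0
    for i in range(n_codons):
        cs, cn = codon_sites(cds[3 * i : 3 * i + 3])
        s += cs
        n += cn
    return s, n


def mutate_paralog(
    cds: str, target_ka: float, target_ks: float, rng: np.random.Generator
) -> tuple[str, RealizedCounts]:
    """Derive a paralog by point substitutions until the realized per-site
    proportions meet the (Ka, Ks) targets within one substitution.

    Each chosen position is mutated at most once; a candidate substitution
    is classified against the codon state at the moment of introduction.
    The start codon and the stop codon are never touched, and no
    substitution may create a stop.  Infeasible targets raise, naming the
    limiting site class.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    n_codons = len(cds) // 3
    coding = n_codons - 1  # codons entering the divergence estimate (stop excluded)
    s_sites, n_sites = _site_counts(cds, coding)

    def needed(target: float, sites: float, label: str) -> int:
        p = 0.75 * (1.0 - math.exp(-4.0 * target / 3.0))
        if p >= 0.70:  # keeps the realized proportion clear of JC saturation
            raise ValueError(
                f"target {label} infeasible: implied substitution proportion "
                f"{p:.3f} approaches saturation of the "
                f"{'synonymous' if label == 'Ks' else 'nonsynonymous'} site class"
            )
        return int(round(p * sites))

    need_s = needed(target_ks, s_sites, "Ks")
    need_n = needed(target_ka, n_sites, "Ka")

    seq = list(cds)
    positions = [
        (ci, pos) for ci in range(1, n_codons - 1) for pos in range(3)
    ]
    rng.shuffle(positions)
    untouched = positions
    syn_done = nonsyn_done = 0
    progress = True
    while (need_s > syn_done or need_n > nonsyn_done) and progress:
        progress = False
        remaining = []
        for ci, pos in untouched:
            if need_s <= syn_done and need_n <= nonsyn_done:
                break
            codon = "".join(seq[3 * ci : 3 * ci + 3])
            aa = GENETIC_CODE[codon]
            syn_alts, nonsyn_alts = [], []
            for base in BASES:
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                alt_aa = GENETIC_CODE[alt]
                if alt_aa == "*":
                    continue
                (syn_alts if alt_aa == aa else nonsyn_alts).append(base)
            applied = None
            if need_s > syn_done and syn_alts:
                applied = rng.choice(syn_alts)
                syn_done += 1
            elif need_n > nonsyn_done and nonsyn_alts:
                applied = rng.choice(nonsyn_alts)
                nonsyn_done += 1
            if applied is not None:
                seq[3 * ci + pos] = str(applied)
                progress = True
            else:
                remaining.append((ci, pos))
        untouched = remaining
    if need_s > syn_done:
        raise ValueError(
            f"target Ks infeasible: only {syn_done} of {need_s} synonymous "
            f"substitutions fit the sequence"
        )
    if need_n > nonsyn_done:
        raise ValueError(
            f"target Ka infeasible: only {nonsyn_done} of {need_n} "
            f"nonsynonymous substitutions fit the sequence"
        )
    mutated = "".join(seq)
    s2, n2 = _site_counts(mutated, coding)
    s_avg, n_avg = 0.5 * (s_sites + s2), 0.5 * (n_sites + n2)
    realized = RealizedCounts(
        syn_subs=syn_done,
        nonsyn_subs=nonsyn_done,
        syn_sites=s_avg,
        nonsyn_sites=n_avg,
        realized_ks=jukes_cantor(syn_done / s_avg),
        realized_ka=jukes_cantor(nonsyn_done / n_avg),
    )
    return mutated, realized


# ---------------------------------------------------------------------------
# promoter motif planting


def _scrub(seq: list[str], forbidden: set[str], rng: np.random.Generator,
           locked: list[tuple[int, int]]) -> None:
    """Rewrite free (non-planted) bases until no forbidden word occurs
    outside the planted intervals.  Hits fully contained in a planted
    interval are the planted words themselves and are left alone."""
    lens = {len(w) for w in forbidden}

    def first_hit() -> tuple[int, int] | None:
        text = "".join(seq)
        for k in lens:
            for i in range(len(text) - k + 1):
                if text[i : i + k] in forbidden:
                    if any(s <= i and i + k <= e for s, e in locked):
                        continue  # the planted word itself
                    return i, k
        return None

    for _ in range(100_000):
        hit = first_hit()
        if hit is None:
            return
        i, k = hit
        free = [
            j
            for j in range(i, i + k)
            if not any(s <= j < e for s, e in locked)
        ]
        if not free:
            raise ValueError(
                "cannot scrub accidental motif occurrence overlapping planted sites"
            )
        j = int(rng.choice(free))
        seq[j] = str(rng.choice(list(BASES)))
    raise RuntimeError("motif scrubbing did not converge")


def plant_promoter_motifs(
    promoters: dict[str, str],
    specs: list[MotifPlantSpec],
    rng: np.random.Generator,
    gene_sets: dict[str, list[str]] | None = None,
) -> tuple[dict[str, str], list[PlantedMotif], list[PlantedMotif]]:
    """Plant motif occurrences into promoters on a scrubbed background.

    The background (everything outside planted intervals) is rejection-
    sampled to contain no occurrence of any planted motif on either strand,
    so scanner counts equal planted counts exactly.  Returns the rewritten
    promoters, the planted occurrences, and the full expected hit list
    (planted hits plus the reverse-orientation hits any planted word itself
    produces, e.g. for palindromic words).
    """
    gene_sets = gene_sets or {}
    motifs = {s.motif: IupacMotif(s.motif, s.motif) for s in specs}
    forbidden: set[str] = set()
    for m in motifs.values():
        words = expand_iupac(m)
        forbidden |= words
        forbidden |= {revcomp(w) for w in words}

    per_gene: dict[str, list[MotifPlantSpec]] = {g: [] for g in promoters}
    for spec in specs:
        genes = (
            list(promoters)
            if spec.gene_set == "all"
            else gene_sets.get(spec.gene_set, [])
        )
        for g in genes:
            if g in per_gene:
                per_gene[g].append(spec)

    out: dict[str, str] = {}
    planted: list[PlantedMotif] = []
    expected: list[PlantedMotif] = []
    for gene, seq in promoters.items():
        chars = list(seq)
        locked: list[tuple[int, int]] = []
        gene_plants: list[tuple[MotifPlantSpec, int, str]] = []
        for spec in per_gene[gene]:
            word_pool = sorted(expand_iupac(motifs[spec.motif]))
            k = len(spec.motif)
            for _ in range(spec.per_promoter):
                placed = False
                for _attempt in range(10_000):
                    start = int(rng.integers(0, len(chars) - k + 1))
                    if any(start < e and s < start + k for s, e in locked):
                        continue
                    word = str(rng.choice(word_pool))
                    insert = word if spec.strand == "+" else revcomp(word)
                    chars[start : start + k] = list(insert)
                    locked.append((start, start + k))
                    gene_plants.append((spec, start, word))
                    placed = True
                    break
                if not placed:
                    raise ValueError(
                        f"{gene}: cannot place {spec.per_promoter} non-overlapping "
                        f"occurrences of {spec.motif}"
                    )
        if forbidden:
            _scrub(chars, forbidden, rng, locked)
        new_seq = "".join(chars)
        out[gene] = new_seq
        for spec, start, word in gene_plants:
            planted.append(PlantedMotif(gene, spec.motif, spec.strand, start, word))
        # expected hits: every offset inside a planted interval checked
        # against every planted motif, in both orientations
        for _spec, start, _word in gene_plants:
            k = len(_spec.motif)
            for m in motifs.values():
                km = len(m)
                sets = [IUPAC_SETS[c] for c in m.pattern]
                for off in range(start, start + k - km + 1):
                    segment = new_seq[off : off + km]
                    if all(b in s for b, s in zip(segment, sets)):
                        expected.append(PlantedMotif(gene, m.name, "+", off, segment))
                    rc = revcomp(segment)
                    if all(b in s for b, s in zip(rc, sets)):
                        expected.append(PlantedMotif(gene, m.name, "-", off, segment))
    return out, planted, expected


def random_promoters(
    genes: list[str], length: int, rng: np.random.Generator
) -> dict[str, str]:
    return {
        g: "".join(rng.choice(list(BASES), size=length)) for g in genes
    }


# ---------------------------------------------------------------------------
# gene family on scaffolds


@dataclass
class FamilyBundle:
    scaffolds: dict[str, str]
    models: list[GeneModel]
    cds: dict[str, str]
    proteins: dict[str, str]
    truth: TruthBundle


def _translate(cds: str) -> str:
    prot = "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))
    return prot[:-1] if prot.endswith("*") else prot


def make_gene_family(config: SynthesisConfig, outdir: str | Path | None = None) -> FamilyBundle:
    """Generate a scaffolded gene family: genome FASTA, GFF3 gene models,
    CDS and protein FASTA, with paralog-pair divergence ground truth.

    Founder genes are drawn independently; each paralog spec duplicates one
    founder via :func:`mutate_paralog`.  Genes are laid out round-robin over
    scaffolds with margins wide enough for a full upstream promoter.  With
    ``outdir`` set, files (genome.fa, genes.gff3, cds.fa, proteins.fa,
    truth.json) are also written.
    """
    rng = np.random.default_rng(config.seed)
    n_pairs = len(config.paralog_specs)
    n_founders = config.n_genes - n_pairs

    truth = TruthBundle()
    cds_by_gene: dict[str, str] = {}
    order: list[str] = []
    for i in range(n_founders):
        gid = f"g{i + 1}"
        cds_by_gene[gid] = random_cds(config.cds_codons, rng)
        order.append(gid)
    for i, spec in enumerate(config.paralog_specs):
        founder = f"g{i + 1}"
        dup = f"{founder}d"
        mutated, realized = mutate_paralog(
            cds_by_gene[founder], spec.target_ka, spec.target_ks, rng
        )
        cds_by_gene[dup] = mutated
        order.append(dup)
        truth.pairs.append(
            PairTruth(founder, dup, spec.target_ka, spec.target_ks, realized)
        )

    lead = config.promoter_len + 200
    gap = config.promoter_len + 500
    scaffold_genes: dict[str, list[str]] = {
        f"scaffold{j + 1}": [] for j in range(config.scaffold_count)
    }
    names = sorted(scaffold_genes)
    for idx, gid in enumerate(order):
        scaffold_genes[names[idx % len(names)]].append(gid)

    scaffolds: dict[str, str] = {}
    models: list[GeneModel] = []
    for sc_name in names:
        cursor = lead
        pieces: list[str] = ["".join(rng.choice(list(BASES), size=lead))]
        for gid in scaffold_genes[sc_name]:
            cds = cds_by_gene[gid]
            k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            cuts = sorted(rng.choice(np.arange(1, len(cds)), size=k - 1, replace=False))
            bounds = [0, *map(int, cuts), len(cds)]
            exon_seqs = [cds[bounds[i] : bounds[i + 1]] for i in range(k)]
            intron_lens = rng.integers(
                config.intron_len[0], config.intron_len[1] + 1, size=k - 1
            )
            transcript_exons: list[tuple[int, int]] = []
            g_parts: list[str] = []
            off = 0
            for i, ex in enumerate(exon_seqs):
                transcript_exons.append((off, off + len(ex)))
                g_parts.append(ex)
                off += len(ex)
                if i < k - 1:
                    ilen = int(intron_lens[i])
                    g_parts.append("".join(rng.choice(list(BASES), size=ilen)))
                    off += ilen
            gseq = "".join(g_parts)
            strand = "+" if rng.random() < 0.5 else "-"
            span = len(gseq)
            start = cursor
            if strand == "+":
                exons = [(start + s, start + e) for s, e in transcript_exons]
                pieces.append(gseq)
            else:
                exons = [
                    (start + span - e, start + span - s) for s, e in transcript_exons
                ]
                pieces.append(revcomp(gseq))
            models.append(
                GeneModel(
                    gene_id=gid,
                    scaffold_id=sc_name,
                    strand=strand,
                    exons=exons,
                    cds_span=(start, start + span),
                )
            )
            cursor += span
            pieces.append("".join(rng.choice(list(BASES), size=gap)))
            cursor += gap
        pieces.append("".join(rng.choice(list(BASES), size=200)))
        seq = "".join(pieces)
        if config.scaffold_len is not None:
            if len(seq) > config.scaffold_len:
                raise ValueError(
                    f"{sc_name}: generated genes need {len(seq)} bp but "
                    f"scaffold_len is {config.scaffold_len}"
                )
            seq += "".join(rng.choice(list(BASES), size=config.scaffold_len - len(seq)))
        scaffolds[sc_name] = seq

    proteins = {gid: _translate(cds_by_gene[gid]) for gid in order}
    bundle = FamilyBundle(
        scaffolds=scaffolds,
        models=models,
        cds={g: cds_by_gene[g] for g in order},
        proteins=proteins,
        truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta_dict(scaffolds, outdir / "genome.fa")
        write_fasta_dict(bundle.cds, outdir / "cds.fa")
        write_fasta_dict(proteins, outdir / "proteins.fa")
        write_gff3(models, {k: len(v) for k, v in scaffolds.items()}, outdir / "genes.gff3")
        truth.save(outdir / "truth.json")
    return bundle


# ---------------------------------------------------------------------------
# expression counts


def simulate_counts(
    spec: ExpressionSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series, ExpressionTruth]:
    """Raw count matrix (genes x samples) with planted hub-partner structure.

    Each positive (negative) partner is a linear response to (the negation
    of) its hub's latent log2 signal plus Gaussian noise calibrated so the
    latent correlation equals ``target_r``; counts are Poisson samples of
    the exponentiated signal scaled by per-sample library factors.
    Non-partner genes are independent.  Returns (counts, sample groups,
    truth).
    """
    ga, gb = spec.groups
    samples = [f"{ga}_{i + 1}" for i in range(spec.n_samples_per_group)] + [
        f"{gb}_{i + 1}" for i in range(spec.n_samples_per_group)
    ]
    n_samples = len(samples)
    groups = pd.Series(
        [ga] * spec.n_samples_per_group + [gb] * spec.n_samples_per_group,
        index=samples,
        name="group",
    )
    lib = spec.library_size_factors
    if lib is None:
        lib = [1.0] * n_samples
    if len(lib) != n_samples:
        raise ValueError("library_size_factors length must match sample count")

    r = spec.target_r
    ln2 = math.log(2.0)

    def count_var(log2_var: float) -> float:
        # average log2-scale variance added by Poisson counting for a gene
        # whose log2-mean fluctuates with the given variance around the
        # working depth (E[1/mu] carries the lognormal Jensen factor)
        return math.exp(0.5 * log2_var * ln2**2) / (2.0**spec.base_log2 * ln2**2)

    rows: dict[str, np.ndarray] = {}
    hub_partners: dict[str, list[tuple[str, str]]] = {}
    group_ind = (groups == gb).to_numpy().astype(float)
    for h in range(spec.n_hubs):
        hub = f"hub{h + 1}"
        z = (
            spec.base_log2
            + spec.group_shift * (group_ind - 0.5)
            + rng.normal(0.0, spec.hub_sd, size=n_samples)
        )
        rows[hub] = z
        if spec.partner_noise_sd is not None:
            noise_sd = spec.partner_noise_sd
        else:
            vz = float(np.var(z))  # realized signal variance for this hub
            ve_hub = count_var(vz)
            v_noise = vz * (1.0 / r**2 - 1.0)  # latent-scale first guess
            for _ in range(3):  # fixed point: partner count noise depends on v_noise
                ve_p = count_var(vz + v_noise)
                v_noise = vz**2 / (r**2 * (vz + ve_hub)) - vz - ve_p
            noise_sd = math.sqrt(max(0.0, v_noise))
        partners = []
        for j in range(spec.n_partners_pos):
            gene = f"{hub}_pos{j + 1}"
            rows[gene] = z + rng.normal(0.0, noise_sd, size=n_samples)
            partners.append((gene, "+"))
        for j in range(spec.n_partners_neg):
            gene = f"{hub}_neg{j + 1}"
            rows[gene] = 2 * spec.base_log2 - z + rng.normal(0.0, noise_sd, size=n_samples)
            partners.append((gene, "-"))
        hub_partners[hub] = partners
    for j in range(spec.n_noise):
        base = rng.uniform(4.0, 10.0)
        rows[f"noise{j + 1}"] = base + rng.normal(0.0, spec.noise_sd, size=n_samples)

    genes = list(rows)
    mu = np.vstack([2.0 ** rows[g] for g in genes]) * np.asarray(lib)[None, :]
    counts = rng.poisson(mu)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = ExpressionTruth(
        hub_partners=hub_partners,
        target_r=r,
        groups=dict(groups),
        library_size_factors=dict(zip(samples, map(float, lib))),
    )
    return df, groups, truth


def simulate_composition_counts(
    n_genes: int,
    fraction_up: float,
    fold: float,
    rng: np.random.Generator,
    n_samples: int = 2,
    base_mean: float = 200.0,
) -> tuple[pd.DataFrame, float]:
    """Two-condition matrix where ``fraction_up`` of genes are ``fold``-times
    up in the last sample only: a pure composition shift.

    Returns the matrix and the analytic TMM factor ratio expected between
    the shifted and unshifted samples (the trimmed mean removes the shifted
    minority, so the factor absorbs the library inflation
    1 + fraction_up * (fold - 1))."""
    means = rng.uniform(0.5 * base_mean, 1.5 * base_mean, size=n_genes)
    mat = rng.poisson(means[:, None] * np.ones((n_genes, n_samples)))
    n_up = int(round(fraction_up * n_genes))
    up_idx = rng.choice(n_genes, size=n_up, replace=False)
    shifted = means.copy()
    shifted[up_idx] *= fold
    mat[:, -1] = rng.poisson(shifted)
    df = pd.DataFrame(
        mat,
        index=[f"gene{i + 1}" for i in range(n_genes)],
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )
    analytic = 1.0 / (1.0 + fraction_up * (fold - 1.0))
    return df, analytic


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(spec: QpcrSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Ct table (sample_group, biological_rep, technical_rep, gene_id, ct)
    with target Ct = base - log2(true fold) + noise and the calibrator group
    centered at ddCt = 0."""
    rows = []
    for group, fold in spec.true_folds.items():
        for bio in range(1, spec.n_bio + 1):
            for tech in range(1, spec.n_tech + 1):
                ref_ct = spec.reference_ct + rng.normal(0.0, spec.ct_sd)
                tgt_ct = (
                    spec.target_base_ct
                    - math.log2(fold / spec.true_folds[spec.calibrator])
                    + rng.normal(0.0, spec.ct_sd)
                )
                rows.append((group, bio, tech, spec.reference_gene, ref_ct))
                rows.append((group, bio, tech, spec.target_gene, tgt_ct))
    return pd.DataFrame(
        rows, columns=["sample_group", "biological_rep", "technical_rep", "gene_id", "ct"]
    )
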