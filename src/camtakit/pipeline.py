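"""Stage orchestration: run the whole family-survey workflow on one input
bundle and emit per-stage TSVs plus a JSON run summary and MANIFEST."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, coexpr, domains, duplication, genestruct, physchem
from . import promoters as promoters_mod
from . import qpcr as qpcr_mod
from .fastaio import read_fasta_dict
from .synthetic import SynthesisConfig, make_gene_family, simulate_counts, simulate_qpcr

ALL_STAGES = (
    "props",
    "domains",
    "structure",
    "paralogs",
    "phylo",
    "promoters",
    "coexpression",
    "qpcr",
)


@dataclass
class RunConfig:
    """Flat key-value configuration for a pipeline run.

    Paths may be None for disabled stages.  Numeric defaults reproduce the
    survey's stated settings: promoter length 1000 bp, RBH thresholds 70/70,
    clock rate 6.1e-9, correlation thresholds +/-0.95, bootstrap 1000.
    """

    outdir: str
    seed: int = 0
    proteins: str | None = None
    cds: str | None = None
    genome: str | None = None
    gff3: str | None = None
    domtblout: str | None = None
    counts: str | None = None
    groups: str | None = None
    ct_table: str | None = None
    motif_library: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    promoter_len: int = 1000
    min_identity: float = 70.0
    min_coverage: float = 70.0
    clock_rate: float = 6.1e-9
    r_pos: float = 0.95
    r_neg: float = -0.95
    bootstrap_reps: int = 200
    qpcr_target: str | None = None
    qpcr_reference: str = "EF1a"
    qpcr_calibrator: str | None = None
    hub_ids: tuple[str, ...] = ()

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _needs(config: RunConfig, stage: str, *paths: str | None) -> None:
    for p in paths:
        if p is None:
            raise ValueError(f"stage {stage!r} enabled but a required input is missing")
        if not Path(p).exists():
            raise FileNotFoundError(f"stage {stage!r}: input {p} does not exist")


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Each stage writes its TSV under ``outdir``; a JSON summary (version,
    parameters, warnings per stage) and a MANIFEST of completed stages are
    written even when a stage fails (the failure is re-raised afterwards).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if not k.startswith("_")
        },
        "stages": {},
    }
    completed: list[str] = []
    failure: Exception | None = None

    def finish():
        (out / "MANIFEST").write_text("\n".join(completed) + "\n")
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))

    try:
        for stage in [s for s in ALL_STAGES if s in config.stages]:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _run_stage(config, stage, out)
            summary["stages"][stage] = {
                "warnings": [str(w.message) for w in caught],
            }
            completed.append(stage)
    except Exception as exc:  # partial outputs retained
        failure = exc
        summary["error"] = f"{stage}: {exc}"
    finish()
    if failure is not None:
        raise failure
    return summary


def _run_stage(config: RunConfig, stage: str, out: Path) -> None:
    if stage == "props":
        _needs(config, stage, config.proteins)
        prots = physchem.read_protein_fasta(config.proteins)
        physchem.property_table(prots).to_csv(out / "protein_properties.tsv", sep="\t", index=False)
    elif stage == "domains":
        _needs(config, stage, config.proteins)
        prots = physchem.read_protein_fasta(config.proteins)
        anns = []
        if config.domtblout is not None:
            anns.extend(domains.read_domtblout(config.domtblout))
        for p in prots:
            anns.extend(domains.find_cambd(p))
            anns.extend(domains.find_iq(p))
            anns.extend(domains.find_bipartite_nls(p))
        rows = [
            {
                "protein": a.protein_id,
                "domain": a.domain_name,
                "start": a.start,
                "end": a.end,
                "evidence": a.evidence,
                "score": a.score,
            }
            for a in anns
        ]
        pd.DataFrame(rows).to_csv(out / "domain_annotations.tsv", sep="\t", index=False)
    elif stage == "structure":
        _needs(config, stage, config.gff3)
        models = genestruct.read_gff3(config.gff3)
        rows = []
        for m in models:
            st = genestruct.structure_stats(m)
            rows.append(
                {
                    "gene": m.gene_id,
                    "scaffold": m.scaffold_id,
                    "strand": m.strand,
                    "n_exons": st.n_exons,
                    "n_introns": st.n_introns,
                    "exon_bp": sum(st.exon_lengths),
                    "intron_bp": sum(st.intron_lengths),
                }
            )
        pd.DataFrame(rows).to_csv(out / "gene_structure.tsv", sep="\t", index=False)
    elif stage == "paralogs":
        _needs(config, stage, config.proteins, config.cds)
        prots = physchem.read_protein_fasta(config.proteins)
        cds = read_fasta_dict(config.cds)
        pairs = duplication.paralog_report(
            prots, cds, config.min_identity, config.min_coverage, config.clock_rate
        )
        pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
            out / "paralog_pairs.tsv", sep="\t", index=False
        )
    elif stage == "phylo":
        _needs(config, stage, config.proteins)
        from . import phylo as phylo_mod

        prots = physchem.read_protein_fasta(config.proteins)
        _, alns = duplication.reciprocal_best_pairs(prots)
        # distances straight from pairwise global alignments (no MSA step)
        import numpy as np

        taxa = sorted(p.id for p in prots)
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                key = (taxa[i], taxa[j])
                aln = alns[key] if key in alns else alns[(taxa[j], taxa[i])]
                p_dist = 1.0 - aln.identity_pct / 100.0
                d[i, j] = d[j, i] = -np.log(max(1e-9, 1.0 - p_dist))
        tree = phylo_mod.neighbor_joining(phylo_mod.DistanceMatrix(taxa, d))
        text = phylo_mod.write_newick(tree)
        (out / "family_tree.nwk").write_text(
            "# distance-based (NJ, Poisson-corrected pairwise identity)\n" + text + "\n"
        )
    elif stage == "promoters":
        _needs(config, stage, config.genome, config.gff3)
        models = genestruct.read_gff3(config.gff3)
        scaffolds = read_fasta_dict(config.genome)
        proms = genestruct.extract_promoters(models, scaffolds, config.promoter_len)
        library = (
            promoters_mod.read_motif_library(config.motif_library)
            if config.motif_library
            else promoters_mod.default_cis_element_library()
        )
        promoters_mod.count_motif_library(proms, library).to_csv(
            out / "promoter_motif_counts.tsv", sep="\t", index=False
        )
        pd.DataFrame(genestruct.promoter_bed(models, scaffolds, config.promoter_len)).to_csv(
            out / "promoter_intervals.tsv", sep="\t", index=False
        )
    elif stage == "coexpression":
        _needs(config, stage, config.counts)
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        factors = coexpr.tmm_factors(counts)
        norm = coexpr.normalize(counts, factors)
        factors.to_frame().to_csv(out / "tmm_factors.tsv", sep="\t")
        hubs = list(config.hub_ids) or list(counts.index[:1])
        results = coexpr.correlation_partners(
            norm, hubs, r_pos=config.r_pos, r_neg=config.r_neg
        )
        coexpr.edge_list(results).to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
    elif stage == "qpcr":
        _needs(config, stage, config.ct_table)
        df = qpcr_mod.read_ct_table(config.ct_table)
        target = config.qpcr_target or [
            g for g in df["gene_id"].unique() if g != config.qpcr_reference
        ][0]
        calibrator = config.qpcr_calibrator or df["sample_group"].iloc[0]
        results = qpcr_mod.delta_delta_ct(df, target, config.qpcr_reference, calibrator)
        qpcr_mod.fold_change_table(results).to_csv(
            out / "qpcr_fold_changes.tsv", sep="\t", index=False
        )


def make_demo(config: SynthesisConfig, outdir: str | Path) -> dict[str, str]:
    """Write a complete synthetic input set (genome, GFF3, CDS, proteins,
    counts, groups, Ct table, truth.json) for tutorials and smoke tests."""
    import numpy as np

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = make_gene_family(config, outdir)
    rng = np.random.default_rng(config.seed + 1)
    counts, groups, expr_truth = simulate_counts(config.expression_spec, rng)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    groups.to_frame().to_csv(outdir / "groups.tsv", sep="\t")
    ct = simulate_qpcr(config.qpcr_spec, rng)
    ct.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
    bundle.truth.expression = expr_truth
    bundle.truth.qpcr_true_folds = dict(config.qpcr_spec.true_folds)
    bundle.truth.save(outdir / "truth.json")
    return {
        "genome": str(outdir / "genome.fa"),
        "gff3": str(outdir / "genes.gff3"),
        "cds": str(outdir / "cds.fa"),
        "proteins": str(outdir / "proteins.fa"),
        "counts": str(outdir / "counts.tsv"),
        "groups": str(outdir / "groups.tsv"),
        "ct_table": str(outdir / "ct_table.tsv"),
        "truth": str(outdir / "truth.json"),
    }
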