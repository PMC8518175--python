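"""The ground-truth generator: determinism, postconditions, recoverability."""

import json
from pathlib import Path

import numpy as np
import pytest

from camtakit import synthetic
from camtakit.duplication import translate_cds
from camtakit.promoters import IupacMotif, scan
from camtakit.synthetic import (
    ExpressionSpec,
    MotifPlantSpec,
    QpcrSpec,
    SynthesisConfig,
    make_gene_family,
    mutate_paralog,
    plant_promoter_motifs,
    random_cds,
    random_promoters,
    simulate_counts,
    simulate_qpcr,
)


def test_config_validation():
    with pytest.raises(ValueError, match="promoter_len"):
        SynthesisConfig(seed=1, promoter_len=0)
    with pytest.raises(ValueError, match="exon"):
        SynthesisConfig(seed=1, exons_per_gene=(0, 2))
    with pytest.raises(ValueError, match="target_r"):
        ExpressionSpec(target_r=1.0)
    with pytest.raises(ValueError, match="reference"):
        QpcrSpec(reference_gene="")


def test_family_determinism(tmp_path):
    cfg = dict(seed=42, cds_codons=90, n_genes=4,
               paralog_specs=[synthetic.ParalogSpec(0.02, 0.1)] * 2)
    d1, d2, d3 = tmp_path / "a", tmp_path / "b", tmp_path / "c"
    make_gene_family(SynthesisConfig(**cfg), d1)
    make_gene_family(SynthesisConfig(**cfg), d2)
    make_gene_family(SynthesisConfig(**{**cfg, "seed": 43}), d3)
    for name in ("genome.fa", "genes.gff3", "cds.fa", "proteins.fa", "truth.json"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    assert (d1 / "genome.fa").read_bytes() != (d3 / "genome.fa").read_bytes()


def test_family_postconditions(small_family):
    for gid, cds in small_family.cds.items():
        assert len(cds) % 3 == 0
        assert cds.startswith("ATG")
        assert translate_cds(cds) == small_family.proteins[gid]
        assert "*" not in small_family.proteins[gid]
    # GFF3 coordinates consistent with scaffold lengths
    for m in small_family.models:
        L = len(small_family.scaffolds[m.scaffold_id])
        assert 0 <= m.span[0] < m.span[1] <= L


def test_fixed_exon_count():
    fam = make_gene_family(
        SynthesisConfig(seed=2, n_genes=3, cds_codons=80, exons_per_gene=(13, 13),
                        paralog_specs=[])
    )
    assert all(len(m.exons) == 13 for m in fam.models)


def test_oversized_gene_rejected():
    with pytest.raises(ValueError, match="scaffold_len"):
        make_gene_family(
            SynthesisConfig(seed=1, n_genes=2, paralog_specs=[], scaffold_len=2000,
                            scaffold_count=2)
        )


def test_mutate_paralog_zero_targets(rng):
    cds = random_cds(100, rng)
    out, realized = mutate_paralog(cds, 0.0, 0.0, rng)
    assert out == cds
    assert realized.syn_subs == realized.nonsyn_subs == 0


def test_mutate_paralog_synonymous_only_preserves_protein(rng):
    cds = random_cds(150, rng)
    out, realized = mutate_paralog(cds, 0.0, 0.3, rng)
    assert translate_cds(out) == translate_cds(cds)
    assert realized.syn_subs > 0 and realized.nonsyn_subs == 0


def test_mutate_paralog_infeasible_targets_name_class(rng):
    cds = random_cds(20, rng)
    with pytest.raises(ValueError, match="Ks infeasible"):
        mutate_paralog(cds, 0.0, 30.0, rng)
    with pytest.raises(ValueError, match="Ka infeasible"):
        mutate_paralog(cds, 30.0, 0.0, rng)


def test_planted_motifs_scanned_exactly(rng):
    proms = random_promoters(["g1", "g2", "g3"], 800, rng)
    specs = [MotifPlantSpec("setA", "MCGCGB", 3)]
    out, planted, expected = plant_promoter_motifs(
        proms, specs, rng, gene_sets={"setA": ["g1", "g2"]}
    )
    motif = IupacMotif("MCGCGB", "MCGCGB")
    for g in ("g1", "g2"):
        fwd = [h for h in scan(out[g], motif, strands="both") if h.strand == "+"]
        assert len(fwd) == 3
        assert sorted(h.start for h in fwd) == sorted(
            p.start for p in planted if p.gene_id == g
        )
    assert scan(out["g3"], motif, strands="both") == []
    # full both-strand hit list equals the recorded expectation
    for g in ("g1", "g2", "g3"):
        hits = {(h.strand, h.start) for h in scan(out[g], motif, strands="both")}
        exp = {(e.strand, e.start) for e in expected if e.gene_id == g}
        assert hits == exp


def test_plant_zero_occurrences(rng):
    proms = random_promoters(["g"], 500, rng)
    out, planted, _ = plant_promoter_motifs(
        proms, [MotifPlantSpec("all", "MCGTGT", 0)], rng
    )
    assert planted == []
    assert scan(out["g"], IupacMotif("m", "MCGTGT")) == []


def test_plant_reverse_strand(rng):
    proms = random_promoters(["g"], 600, rng)
    out, planted, _ = plant_promoter_motifs(
        proms, [MotifPlantSpec("all", "MCGTGT", 2, strand="-")], rng
    )
    motif = IupacMotif("m", "MCGTGT")
    assert scan(out["g"], motif, strands="forward") == []
    both = scan(out["g"], motif, strands="both")
    assert len(both) == 2 and all(h.strand == "-" for h in both)


def test_plant_rejects_bad_motif():
    with pytest.raises(ValueError):
        MotifPlantSpec("all", "MCGXGT", 1)


def test_counts_zero_noise_partners(rng):
    """With zero partner noise the latent correlation is 1; at n = 50
    samples per group the count-level correlation still exceeds 0.99."""
    spec = ExpressionSpec(
        n_hubs=1, n_partners_pos=3, n_partners_neg=3, n_noise=10,
        n_samples_per_group=25, partner_noise_sd=0.0,
    )
    counts, _, truth = simulate_counts(spec, rng)
    x = np.log2(counts.to_numpy() + 1.0)
    genes = list(counts.index)
    hub = x[genes.index("hub1")]
    for gene, sign in dict(truth.hub_partners)["hub1"]:
        r = np.corrcoef(hub, x[genes.index(gene)])[0, 1]
        assert abs(r) > 0.99
        assert (r > 0) == (sign == "+")


def test_counts_target_r_recovered_in_mean():
    """Mean empirical partner correlation within +/-0.03 of the planted
    r = 0.97 over 20 seeds (n = 30 samples)."""
    rs = []
    for seed in range(20):
        rng = np.random.default_rng(600 + seed)
        spec = ExpressionSpec(n_hubs=1, n_partners_pos=5, n_partners_neg=5, n_noise=5)
        counts, _, truth = simulate_counts(spec, rng)
        x = np.log2(counts.to_numpy() + 1.0)
        genes = list(counts.index)
        hub = x[genes.index("hub1")]
        for gene, sign in dict(truth.hub_partners)["hub1"]:
            r = np.corrcoef(hub, x[genes.index(gene)])[0, 1]
            rs.append(abs(r))
    assert np.mean(rs) == pytest.approx(0.97, abs=0.03)


def test_counts_library_factor_validation(rng):
    with pytest.raises(ValueError, match="length"):
        simulate_counts(ExpressionSpec(library_size_factors=[1.0]), rng)


def test_qpcr_exact_and_determinism():
    rng1 = np.random.default_rng(9)
    rng2 = np.random.default_rng(9)
    spec = QpcrSpec(true_folds={"M": 1.0, "R": 2.0}, ct_sd=0.1)
    t1 = simulate_qpcr(spec, rng1)
    t2 = simulate_qpcr(spec, rng2)
    assert t1.equals(t2)
    assert set(t1["gene_id"]) == {"EF1a", "DzCAMTA3"}


def test_truth_bundle_round_trip(tmp_path, small_family):
    path = tmp_path / "truth.json"
    small_family.truth.save(path)
    data = json.loads(Path(path).read_text())
    assert len(data["pairs"]) == len(small_family.truth.pairs)
    assert data["pairs"][0]["realized"]["syn_subs"] >= 0
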