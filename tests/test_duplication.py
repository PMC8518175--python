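"""RBH paralogy, codon alignment, NG86 Ka/Ks and dating."""

import itertools
import math
import random

import numpy as np
import pytest
from Bio.Data import CodonTable

from camtakit import duplication
from camtakit.duplication import (
    classify_selection,
    codon_align,
    divergence_time,
    global_align,
    ng86_kaks,
    reciprocal_best_pairs,
)
from camtakit.physchem import ProteinRecord
from camtakit.synthetic import mutate_paralog, random_cds

# ---------------------------------------------------------------------------
# independent oracles

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODE = dict(_TABLE.forward_table)
for _c in _TABLE.stop_codons:
    _CODE[_c] = "*"
SENSE = sorted(c for c, aa in _CODE.items() if aa != "*")


def _oracle_sites(codon):
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODE[alt] != "*" and _CODE[alt] == _CODE[codon]:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def _oracle_diffs(ca, cb):
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(pos):
        cur, sd, nd, stop = ca, 0, 0, False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if _CODE[nxt] == "*":
                stop = True
            if _CODE[nxt] == _CODE[cur] and _CODE[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, stop))
    ok = [(s, n) for s, n, st in results if not st]
    use = ok if ok else [(s, n) for s, n, _ in results]
    return sum(u[0] for u in use) / len(use), sum(u[1] for u in use) / len(use)


def oracle_ng86(seq_a, seq_b):
    """Direct NG86 computation (site fractions, pathway averaging, JC)."""
    S = N = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        sa, na = _oracle_sites(ca)
        sb, nb = _oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        d = _oracle_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return jc(nd / N), jc(sd / S)


def _score_all_alignments(a, b, matrix, gap_open, gap_extend):
    """Exhaustively enumerate every gapped alignment of a and b and return
    the best affine-gap BLOSUM62 score (gap of length L costs
    open + (L-1) * extend)."""
    best = [-math.inf]

    def rec(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            cost = -gap_extend if state == "a" else -gap_open
            rec(i + 1, j, score + cost, "a")
        if j < len(b):
            cost = -gap_extend if state == "b" else -gap_open
            rec(i, j + 1, score + cost, "b")

    rec(0, 0, 0.0, "start")
    return best[0]


# ---------------------------------------------------------------------------
# global alignment


def test_identical_sequences_align_perfectly():
    p = ProteinRecord("a", "MKVLWAALLVT")
    q = ProteinRecord("b", "MKVLWAALLVT")
    aln = global_align(p, q)
    assert aln.identity_pct == 100.0
    assert aln.coverage_pct == 100.0


def test_alignment_score_matches_exhaustive_enumeration(rng):
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(6):
        a = "".join(rng.choice(aa, size=int(rng.integers(3, 6))))
        b = "".join(rng.choice(aa, size=int(rng.integers(3, 6))))
        aln = global_align(ProteinRecord("a", a), ProteinRecord("b", b))
        oracle = _score_all_alignments(a, b, blosum, 11.0, 1.0)
        assert aln.score == pytest.approx(oracle)


def test_alignment_symmetry():
    p = ProteinRecord("a", "MKVLWAALLVTHH")
    q = ProteinRecord("b", "MKVWAALVTH")
    ab, ba = global_align(p, q), global_align(q, p)
    assert ab.score == ba.score
    assert ab.identity_pct == pytest.approx(ba.identity_pct)
    assert ab.coverage_pct == pytest.approx(ba.coverage_pct)


def test_empty_sequence_rejected():
    with pytest.raises(Exception):
        global_align(ProteinRecord("a", "MK"), ProteinRecord("b", ""))


# ---------------------------------------------------------------------------
# reciprocal best hit


def test_rbh_identical_pair_plus_outlier(rng):
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    twin = "".join(rng.choice(aa, size=120))
    other = "".join(rng.choice(aa, size=120))
    prots = [
        ProteinRecord("t1", twin),
        ProteinRecord("t2", twin),
        ProteinRecord("out", other),
    ]
    pairs, _ = reciprocal_best_pairs(prots)
    assert [(p.gene_a, p.gene_b) for p in pairs] == [("t1", "t2")]


def test_rbh_threshold_excludes_dissimilar(rng):
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    prots = [
        ProteinRecord(f"p{i}", "".join(rng.choice(aa, size=100))) for i in range(4)
    ]
    pairs, _ = reciprocal_best_pairs(prots)
    assert pairs == []


def test_rbh_family_recovers_planted_pairs(family):
    prots = [ProteinRecord(g, s) for g, s in family.proteins.items()]
    pairs, _ = reciprocal_best_pairs(prots)
    found = {tuple(sorted((p.gene_a, p.gene_b))) for p in pairs}
    expected = {tuple(sorted((t.gene_a, t.gene_b))) for t in family.truth.pairs}
    assert found == expected
    # disjoint and above thresholds
    members = [g for p in pairs for g in (p.gene_a, p.gene_b)]
    assert len(members) == len(set(members))
    assert all(p.identity_pct > 70 and p.coverage_pct > 70 for p in pairs)


def test_rbh_order_independence(family):
    prots = [ProteinRecord(g, s) for g, s in family.proteins.items()]
    shuffled = list(prots)
    random.Random(3).shuffle(shuffled)
    a, _ = reciprocal_best_pairs(prots)
    b, _ = reciprocal_best_pairs(shuffled)
    assert [(p.gene_a, p.gene_b) for p in a] == [(p.gene_a, p.gene_b) for p in b]


# ---------------------------------------------------------------------------
# codon alignment


def test_codon_align_gap_free_and_gapped():
    cds_a = "ATGAAATTTTGA"  # M K F *
    cds_b = "ATGAAATGTTGA"  # M K C *
    aln = duplication.PairwiseAlignment("a", "b", "MKF", "MKC", 0.0, 66.7, 100.0)
    ca, cb = codon_align(aln, cds_a, cds_b)
    assert (ca, cb) == ("ATGAAATTT", "ATGAAATGT")
    gapped = duplication.PairwiseAlignment("a", "b", "MKF", "M-C", 0.0, 33.3, 100.0)
    ca, cb = codon_align(gapped, cds_a, "ATGTGTTGA")
    assert cb == "ATG---TGT"
    assert ca.replace("-", "") == "ATGAAATTT"  # degapping recovers the CDS


def test_codon_align_reports_discordant_position():
    aln = duplication.PairwiseAlignment("a", "b", "MKF", "MKF", 0.0, 100.0, 100.0)
    with pytest.raises(ValueError, match="position 3"):
        codon_align(aln, "ATGAAATTTTGA", "ATGAAATGTTGA")


# ---------------------------------------------------------------------------
# NG86


def test_ng86_identical_pair_is_zero():
    cds = "ATGAAATTTGGG"
    ka, ks, ratio = ng86_kaks((cds, cds))
    assert ka == 0 and ks == 0 and ratio is None


def test_ng86_two_codon_toy_pair_matches_oracle():
    # TTT (Phe) vs TTA (Leu): single third-position nonsynonymous change
    a, b = "ATGTTT", "ATGTTA"
    ka, ks, _ = ng86_kaks((a, b))
    oka, oks = oracle_ng86(a, b)
    assert ka == pytest.approx(oka)
    assert ks == pytest.approx(oks)
    assert ka > 0 and ks == 0


def test_ng86_exhaustive_single_codon_pairs():
    """NG86 equals the exhaustive-pathway oracle on every sense-codon pair
    (stop codons are not alignable columns)."""
    for ca in SENSE:
        for cb in SENSE:
            sa, na = _oracle_sites(ca)
            sb, nb = _oracle_sites(cb)
            S, N = (sa + sb) / 2, (na + nb) / 2
            sd, nd = _oracle_diffs(ca, cb)
            if S == 0 or sd / S >= 0.75 or nd / N >= 0.75:
                # degenerate one-codon instance: zero synonymous sites or
                # JC saturation must be reported as an error
                with pytest.raises(ValueError):
                    ng86_kaks((ca, cb))
                continue
            ka, ks, _ = ng86_kaks((ca, cb))
            oka, oks = oracle_ng86(ca, cb)
            assert ka == pytest.approx(oka, abs=1e-12)
            assert ks == pytest.approx(oks, abs=1e-12)


def test_ng86_random_multicodon_instances_match_oracle(rng):
    for _ in range(150):
        n = int(rng.integers(2, 4))
        a = "".join(rng.choice(SENSE, size=n))
        b = "".join(rng.choice(SENSE, size=n))
        try:
            ka, ks, _ = ng86_kaks((a, b))
        except ValueError:
            continue  # saturated instance
        oka, oks = oracle_ng86(a, b)
        assert ka == pytest.approx(oka, abs=1e-12)
        assert ks == pytest.approx(oks, abs=1e-12)


def test_ng86_pairwise_deletion_drops_gapped_columns():
    a = "ATG---AAA"
    b = "ATGTTTAAA"
    ka, ks, _ = ng86_kaks((a, b))
    assert ka == 0 and ks == 0  # only identical complete columns remain


def test_synonymous_only_pair(rng):
    cds = random_cds(200, rng)
    mutated, realized = mutate_paralog(cds, target_ka=0.0, target_ks=0.2, rng=rng)
    aln = duplication.PairwiseAlignment(
        "a", "b", duplication.translate_cds(cds), duplication.translate_cds(mutated),
        0.0, 100.0, 100.0,
    )
    ka, ks, _ = ng86_kaks(codon_align(aln, cds, mutated))
    assert ka == 0.0
    assert ks > 0
    assert realized.nonsyn_subs == 0


def test_ks_recovery_within_15_percent():
    """Planted synonymous divergence is recovered by NG86 within +/-15%
    at CDS length 3000 (20 seeds, Ks targets across 0.05-0.5)."""
    errors = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        cds = random_cds(1000, rng)
        target = 0.05 + 0.45 * seed / 19
        mutated, realized = mutate_paralog(cds, target_ka=0.1 * target, target_ks=target, rng=rng)
        prot = duplication.translate_cds(cds)
        aln = duplication.PairwiseAlignment(
            "a", "b", prot, duplication.translate_cds(mutated), 0.0, 100.0, 100.0
        )
        _, ks, _ = ng86_kaks(codon_align(aln, cds, mutated))
        errors.append(abs(ks - realized.realized_ks) / realized.realized_ks)
    assert max(errors) < 0.15


# ---------------------------------------------------------------------------
# dating and selection


def test_divergence_time_closed_form():
    assert divergence_time(0.0) == 0.0
    assert divergence_time(0.1830) == pytest.approx(15.0, abs=1e-9)
    # linear in Ks, inverse in lambda
    assert divergence_time(0.2) == pytest.approx(2 * divergence_time(0.1))
    assert divergence_time(0.2, lam=12.2e-9) == pytest.approx(divergence_time(0.1))
    with pytest.raises(ValueError):
        divergence_time(-0.1)


@pytest.mark.parametrize(
    "ratio,expected",
    [(0.3, "purifying"), (1.0, "neutral"), (1.7, "positive"), (1.0 + 1e-12, "neutral")],
)
def test_classify_selection(ratio, expected):
    assert classify_selection(ratio) == expected
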