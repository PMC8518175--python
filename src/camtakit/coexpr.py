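"""TMM normalization and signed Pearson co-expression partner extraction.

The trimmed-mean-of-M-values (TMM) factor of a sample against a reference
sample is the weighted mean of gene-wise log2 expression ratios after
trimming the most extreme 30% of log-ratios and 5% of log-abundances on
each side (genes zero in either sample excluded), with inverse asymptotic
variance weights; factors are rescaled to geometric mean 1.  Normalized
expression is counts-per-million divided by the factor.

Partner sets around a hub are genes with Pearson r >= r_pos (positive) or
r <= r_neg (negative) against the hub, computed by default on
log2(normalized + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CoexpressionResult:
    hub_id: str
    positive_partners: list[tuple[str, float]] = field(default_factory=list)
    negative_partners: list[tuple[str, float]] = field(default_factory=list)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / lib_obs, ref[keep] / lib_ref
    logR = np.log2(o / r)
    absE = 0.5 * np.log2(o * r)
    # delta-method asymptotic variance of the log ratio
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    rank_r = stats.rankdata(logR)
    rank_a = stats.rankdata(absE)
    lo_r = np.floor(n * logratio_trim) + 1
    hi_r = n + 1 - lo_r
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    keep2 = (rank_r >= lo_r) & (rank_r <= hi_r) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 1.0
    f = np.sum(logR[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame, logratio_trim: float = 0.3, abs_trim: float = 0.05
) -> pd.Series:
    """TMM normalization factors, one per sample (column).

    The reference is the sample whose 75th-percentile count fraction is
    closest to the across-sample mean.  Factors are rescaled so their
    geometric mean is 1.  A sample with all-zero counts is an error.
    """
    mat = counts.to_numpy(dtype=float)
    libs = mat.sum(axis=0)
    if np.any(libs == 0):
        bad = counts.columns[libs == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    f75 = np.array(
        [np.percentile(mat[:, j][mat[:, j] >= 0] / libs[j], 75) for j in range(mat.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_idx], libs[j], libs[ref_idx], logratio_trim, abs_trim)
            for j in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """TMM-scaled counts per million: count / (library size x factor) x 1e6."""
    libs = counts.sum(axis=0)
    return counts / (libs * factors) * 1e6


def correlation_partners(
    normalized: pd.DataFrame,
    hub_ids: list[str],
    r_pos: float = 0.95,
    r_neg: float = -0.95,
    min_samples: int = 4,
    log_transform: bool = True,
) -> dict[str, CoexpressionResult]:
    """Signed Pearson partner sets for each hub gene.

    r is computed between the hub row and every other row across all
    samples, on log2(value + 1) by default.  Zero-variance rows are skipped
    with a warning; a zero-variance hub is an error.
    """
    if normalized.shape[1] < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples, got {normalized.shape[1]}"
        )
    x = np.log2(normalized.to_numpy(dtype=float) + 1.0) if log_transform else (
        normalized.to_numpy(dtype=float)
    )
    genes = list(normalized.index)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    zero_var = norms == 0
    if np.any(zero_var):
        warnings.warn(
            f"skipping {int(zero_var.sum())} zero-variance gene(s)", stacklevel=2
        )
    results = {}
    for hub in hub_ids:
        hi = genes.index(hub)
        if zero_var[hi]:
            raise ValueError(f"hub {hub!r} has zero variance")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = centered @ centered[hi] / (norms * norms[hi])
        res = CoexpressionResult(hub_id=hub)
        for gi, gene in enumerate(genes):
            if gi == hi or zero_var[gi]:
                continue
            if r[gi] >= r_pos:
                res.positive_partners.append((gene, float(r[gi])))
            elif r[gi] <= r_neg:
                res.negative_partners.append((gene, float(r[gi])))
        results[hub] = res
    return results


def edge_list(results: dict[str, CoexpressionResult]) -> pd.DataFrame:
    """Hub-partner edge rows (hub, partner, r, sign) for graph tools."""
    rows = []
    for hub, res in results.items():
        for gene, r in res.positive_partners:
            rows.append({"hub": hub, "partner": gene, "r": r, "sign": "+"})
        for gene, r in res.negative_partners:
            rows.append({"hub": hub, "partner": gene, "r": r, "sign": "-"})
    return pd.DataFrame(rows, columns=["hub", "partner", "r", "sign"])


def cumulative_expression_compare(
    normalized: pd.DataFrame,
    gene_set: list[str],
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> tuple[pd.DataFrame, float | None, str | None]:
    """Per-gene group means and a Wilcoxon signed-rank location-shift test.

    The test is two-sided across the gene set's paired (group_a, group_b)
    means.  Sets smaller than 5 genes warn and return p = None.  The
    direction is 'b>a', 'a>b', or None when the medians tie.
    """
    a_cols = groups.index[groups == group_a]
    b_cols = groups.index[groups == group_b]
    if len(a_cols) == 0 or len(b_cols) == 0:
        raise ValueError("both groups must be non-empty")
    sub = normalized.loc[gene_set]
    means = pd.DataFrame(
        {group_a: sub[a_cols].mean(axis=1), group_b: sub[b_cols].mean(axis=1)}
    )
    diff = means[group_b] - means[group_a]
    direction = None
    med = float(np.median(diff))
    if med > 0:
        direction = "b>a"
    elif med < 0:
        direction = "a>b"
    if len(gene_set) < 5:
        warnings.warn("gene set smaller than 5: no location-shift p-value", stacklevel=2)
        return means, None, direction
    if np.allclose(diff, 0):
        return means, 1.0, None
    _, p = stats.wilcoxon(means[group_a], means[group_b], alternative="two-sided")
    return means, float(p), direction
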