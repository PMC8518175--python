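"""Relative qPCR quantification by the 2^-ddCt method.

Technical replicates are averaged per biological replicate before any
statistics; dCt = Ct_target - Ct_reference per biological replicate;
ddCt subtracts the calibrator group's mean dCt; the reported fold change
is 2^(-mean ddCt), so the calibrator group's fold is exactly 1.
Significance flags come from a two-sided Welch t-test on per-replicate
dCt values against the calibrator (*: p < 0.05, **: p < 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_group", "biological_rep", "technical_rep", "gene_id", "ct"]


@dataclass
class FoldChangeResult:
    gene_id: str
    group: str
    fold_change: float
    se: float | None
    p_vs_calibrator: float | None
    flag: str

    def __post_init__(self):
        assert self.fold_change > 0
        assert self.flag in ("ns", "*", "**")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def _delta_ct(df: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    """Average technical reps, then dCt per (group, biological rep)."""
    tech_mean = (
        df.groupby(["sample_group", "biological_rep", "gene_id"])["ct"]
        .mean()
        .reset_index()
    )
    wide = tech_mean.pivot_table(
        index=["sample_group", "biological_rep"], columns="gene_id", values="ct"
    )
    for gene in (target, reference):
        if gene not in wide.columns or wide[gene].isna().any():
            missing = (
                wide.index.tolist()
                if gene not in wide.columns
                else wide.index[wide[gene].isna()].tolist()
            )
            raise ValueError(f"missing {gene!r} Ct in replicates: {missing}")
    out = (wide[target] - wide[reference]).rename("dct").reset_index()
    return out


def significance(
    dct_group: np.ndarray, dct_calibrator: np.ndarray
) -> tuple[float | None, str]:
    """Welch two-sided t-test on dCt values; flags at 0.05 / 0.01."""
    a = np.asarray(dct_group, dtype=float)
    b = np.asarray(dct_calibrator, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return None, "ns"
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
    else:
        _, p = stats.ttest_ind(a, b, equal_var=False)
        p = float(p)
    if p < 0.01:
        flag = "**"
    elif p < 0.05:
        flag = "*"
    else:
        flag = "ns"
    return p, flag


def delta_delta_ct(
    df: pd.DataFrame, target: str, reference: str, calibrator_group: str
) -> list[FoldChangeResult]:
    """Per-group fold change of ``target`` relative to ``reference``,
    calibrated to ``calibrator_group``.

    fold = 2^(-mean ddCt) over biological replicates; the SE is the
    delta-method propagation of the SE of mean ddCt onto the fold scale.
    """
    dct = _delta_ct(df, target, reference)
    if calibrator_group not in set(dct["sample_group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} not present")
    cal = dct.loc[dct["sample_group"] == calibrator_group, "dct"].to_numpy()
    cal_mean = cal.mean()
    results = []
    for group, sub in dct.groupby("sample_group", sort=False):
        ddct = sub["dct"].to_numpy() - cal_mean
        fold = float(2.0 ** (-ddct.mean()))
        if len(ddct) > 1:
            se_ddct = ddct.std(ddof=1) / math.sqrt(len(ddct))
            se = float(fold * math.log(2.0) * se_ddct)
        else:
            se = None
        if group == calibrator_group:
            p, flag = None, "ns"
        else:
            p, flag = significance(sub["dct"].to_numpy(), cal)
        results.append(
            FoldChangeResult(
                gene_id=target,
                group=str(group),
                fold_change=fold,
                se=se,
                p_vs_calibrator=p,
                flag=flag,
            )
        )
    return results


def fold_change_table(results: list[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "group": r.group,
                "fold_change": r.fold_change,
                "se": r.se,
                "p": r.p_vs_calibrator,
                "flag": r.flag,
            }
            for r in results
        ]
    )
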