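"""TMM-normalize the simulated count matrix, extract signed Pearson partner
sets around the two hubs at the r >= 0.95 / r <= -0.95 thresholds, and
compare cumulative expression of each partner set between stages."""

import json
from pathlib import Path

import pandas as pd
from _common import RESULTS, ensure_inputs

from camtakit import coexpr


def main():
    paths = ensure_inputs()
    counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
    groups = pd.read_csv(paths["groups"], sep="\t", index_col=0)["group"]
    factors = coexpr.tmm_factors(counts)
    norm = coexpr.normalize(counts, factors)
    factors.to_frame().to_csv(RESULTS / "tmm_factors.tsv", sep="\t")

    import re

    hubs = [g for g in counts.index if re.fullmatch(r"hub\d+", g)]
    results = coexpr.correlation_partners(norm, hubs)
    edges = coexpr.edge_list(results)
    edges.to_csv(RESULTS / "coexpression_edges.tsv", sep="\t", index=False)

    truth = json.loads(Path(paths["truth"]).read_text())["expression"]
    print(f"TMM factors within [{factors.min():.3f}, {factors.max():.3f}]")
    for hub in hubs:
        res = results[hub]
        planted = {g for g, _ in truth["hub_partners"][hub]}
        found = {g for g, _ in res.positive_partners} | {
            g for g, _ in res.negative_partners
        }
        print(
            f"{hub}: {len(res.positive_partners)} positive / "
            f"{len(res.negative_partners)} negative partners; "
            f"recovery {100 * len(found & planted) / len(planted):.0f}%, "
            f"false partners {len(found - planted)}"
        )
        pos_set = [g for g, _ in res.positive_partners]
        if len(pos_set) >= 5:
            _, p, direction = coexpr.cumulative_expression_compare(
                norm, pos_set, groups, "mature", "ripe"
            )
            print(
                f"  positive set cumulative expression: direction {direction}, "
                f"Wilcoxon p = {p:.2e}"
            )


if __name__ == "__main__":
    main()
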