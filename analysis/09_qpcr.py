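"""2^-ddCt fold changes across ripening stages from the simulated Ct table,
with Welch significance flags against the mature-stage calibrator."""

import json
from pathlib import Path

from _common import RESULTS, ensure_inputs

from camtakit import qpcr


def main():
    paths = ensure_inputs()
    table = qpcr.read_ct_table(paths["ct_table"])
    results = qpcr.delta_delta_ct(table, "DzCAMTA3", "EF1a", "M")
    out = qpcr.fold_change_table(results)
    out.to_csv(RESULTS / "qpcr_fold_changes.tsv", sep="\t", index=False)
    print(out.round(4).to_string(index=False))
    truth = json.loads(Path(paths["truth"]).read_text())["qpcr_true_folds"]
    print(f"\ntrue folds: {truth}")


if __name__ == "__main__":
    main()
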