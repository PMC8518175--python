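"""Shared plumbing for the numbered analysis drivers: a deterministic
synthetic input bundle under results/inputs and a results directory."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
INPUTS = RESULTS / "inputs"
SEED = 17


def ensure_inputs() -> dict[str, str]:
    from camtakit.pipeline import make_demo
    from camtakit.synthetic import SynthesisConfig

    RESULTS.mkdir(exist_ok=True)
    if not (INPUTS / "truth.json").exists():
        make_demo(SynthesisConfig(seed=SEED), INPUTS)
    names = {
        "genome": "genome.fa",
        "gff3": "genes.gff3",
        "cds": "cds.fa",
        "proteins": "proteins.fa",
        "counts": "counts.tsv",
        "groups": "groups.tsv",
        "ct_table": "ct_table.tsv",
        "truth": "truth.json",
    }
    return {k: str(INPUTS / v) for k, v in names.items()}
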