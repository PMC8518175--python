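"""Exon-intron statistics per gene model and the strand-aware 1 kb
promoter intervals."""

import pandas as pd
from _common import RESULTS, ensure_inputs

from camtakit import genestruct
from camtakit.fastaio import read_fasta_dict


def main():
    paths = ensure_inputs()
    models = genestruct.read_gff3(paths["gff3"])
    scaffolds = read_fasta_dict(paths["genome"])
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
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "gene_structure.tsv", sep="\t", index=False)
    bed = pd.DataFrame(genestruct.promoter_bed(models, scaffolds, 1000))
    bed.to_csv(RESULTS / "promoter_intervals.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    lo, hi = table.n_exons.min(), table.n_exons.max()
    print(f"\nexon counts span {lo}-{hi} per gene; {len(bed)} promoter "
          f"intervals written (all {set(bed.end - bed.start)} bp)")


if __name__ == "__main__":
    main()
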