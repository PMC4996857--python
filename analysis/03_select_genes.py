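"""PCA each platform, orient PC1 along maturation, and select
maturation-associated genes by the summed-loading mean +/- 2SD rule
(shared genes) and per-platform rule (unique genes).

Reports the selection funnel and, since this cohort is synthetic, the
recovery of the planted program.  Writes results/selection/.
"""

from pathlib import Path

import pandas as pd

from cardiomat import (orient_pc1, pca, scale_samples,
                       select_maturation_genes)
from cardiomat import io

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "selection"


def main() -> None:
    gene_a = io.read_expression_matrix(ROOT / "collapse" / "gene_matrix_a.tsv")
    matrix_b = io.read_expression_matrix(ROOT / "data" / "matrix_b.tsv")
    samples_a = io.read_sample_table(ROOT / "data" / "samples_a.tsv")
    samples_b = io.read_sample_table(ROOT / "data" / "samples_b.tsv")
    gene_b = scale_samples(matrix_b)

    p_a = orient_pc1(pca(gene_a, 2), samples_a)
    p_b = orient_pc1(pca(gene_b, 2), samples_b)
    print(f"PC1 explains {p_a.explained_variance[0] / gene_a.shape[0]:.1%} "
          f"of platform-A variance, "
          f"{p_b.explained_variance[0] / gene_b.shape[0]:.1%} of platform-B")

    table, sel = select_maturation_genes(p_a, p_b)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "loading_table.tsv", sep="\t", float_format="%.10g")
    io.write_gene_list(sorted(sel.mature), OUT / "mature.txt")
    io.write_gene_list(sorted(sel.immature), OUT / "immature.txt")

    shared = table["summed"].notna().sum()
    print(f"funnel: {len(table)} genes total, {shared} shared, "
          f"{len(table) - shared} platform-unique")
    print(f"selected {len(sel.selected)} genes: {len(sel.mature)} mature-"
          f"associated, {len(sel.immature)} immature-associated")

    truth = pd.read_csv(ROOT / "data" / "ground_truth.tsv", sep="\t")
    planted = set(truth.loc[truth["direction"] != 0, "gene"])
    tp = sel.selected & planted
    print(f"recovery of planted program: sensitivity "
          f"{len(tp) / len(planted):.3f}, precision "
          f"{len(tp) / len(sel.selected):.3f}")


if __name__ == "__main__":
    main()
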