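"""Compare mouse and human maturation expression changes: map symbols,
compute adult-minus-early deltas in each species, correlate them over all
genes vs the selected genes, count direction-consistent genes, and run the
alternative delta-sum selection.

Writes results/cross_species/.
"""

import json
from pathlib import Path

from cardiomat import (alternative_delta_selection, compute_deltas,
                       consistency_report, delta_correlation,
                       make_delta_table, map_symbols, scale_samples,
                       selection_overlap)
from cardiomat import io
from cardiomat.pca import GeneSelection

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "cross_species"


def main() -> None:
    gene_a = io.read_expression_matrix(ROOT / "collapse" / "gene_matrix_a.tsv")
    samples_a = io.read_sample_table(ROOT / "data" / "samples_a.tsv")
    human = scale_samples(
        io.read_expression_matrix(ROOT / "data" / "human_matrix.tsv"))
    human_samples = io.read_sample_table(ROOT / "data" / "human_samples.tsv")
    sel = GeneSelection(
        mature=set(io.read_gene_list(ROOT / "selection" / "mature.txt")),
        immature=set(io.read_gene_list(ROOT / "selection" / "immature.txt")),
    )

    S = samples_a.n_stages
    delta_mouse = compute_deltas(gene_a, samples_a, str(S), "1", by="stage")
    delta_human = compute_deltas(human, human_samples, "adult", "fetal")
    pairs = map_symbols(delta_mouse.index, human.feature_ids)
    dtab = make_delta_table(pairs, delta_mouse, delta_human)

    r_all = delta_correlation(dtab)
    r_sel = delta_correlation(dtab, subset=sel.selected)
    rep = consistency_report(dtab, sel, fc_threshold=1.5)
    dsel = alternative_delta_selection(dtab)
    overlap = selection_overlap(sel, dsel)

    OUT.mkdir(parents=True, exist_ok=True)
    dtab.to_csv(OUT / "delta_table.tsv", sep="\t", index_label="gene",
                float_format="%.10g")
    io.write_gene_list(sorted(dsel.mature), OUT / "delta_mature.txt")
    io.write_gene_list(sorted(dsel.immature), OUT / "delta_immature.txt")
    summary = {
        "r_all_genes": r_all, "r_selected_genes": r_sel,
        "n_mapped": len(dtab),
        "consistent_mature": f"{rep.n_consistent_mature}/{rep.n_mature_mapped}",
        "consistent_immature":
            f"{rep.n_consistent_immature}/{rep.n_immature_mapped}",
        "n_inconsistent_above_1.5fold": rep.n_inconsistent_above_fc,
        "overlap_with_delta_selection": overlap,
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")

    print(f"mapped {len(dtab)} mouse genes to human counterparts")
    print(f"delta correlation: r = {r_all:.2f} over all genes, "
          f"r = {r_sel:.2f} over the {len(sel.selected)} selected genes")
    print(f"direction consistency: {rep.n_consistent_mature}/"
          f"{rep.n_mature_mapped} mature up in adult human, "
          f"{rep.n_consistent_immature}/{rep.n_immature_mapped} immature up "
          f"in fetal; {rep.n_inconsistent_above_fc} inconsistent genes "
          f"exceed 1.5-fold")
    print(f"delta-sum alternative selects {overlap['n_b']} genes; Jaccard "
          f"with PCA selection = {overlap['jaccard']:.2f}")


if __name__ == "__main__":
    main()
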