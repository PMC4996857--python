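"""Generate the synthetic study cohort: a two-platform mouse developmental
compendium (probe-level platform A, gene-level platform B) plus a fetal/adult
human dataset, with the planted maturation program recorded as ground truth.

Writes everything as TSV under results/data/.
"""

from pathlib import Path

import pandas as pd

from cardiomat import SimulationConfig, simulate_human, simulate_mouse_pair
from cardiomat import io

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
CONFIG = SimulationConfig(n_genes=800, seed=1)


def main() -> None:
    matrix_a, ann_a, matrix_b, samples_a, samples_b, truth = \
        simulate_mouse_pair(CONFIG)
    human_matrix, human_samples = simulate_human(CONFIG, truth)

    io.write_expression_matrix(matrix_a, OUT / "matrix_a.tsv")
    io.write_probe_annotation(ann_a, OUT / "annotation_a.tsv")
    io.write_expression_matrix(matrix_b, OUT / "matrix_b.tsv")
    io.write_sample_table(samples_a, OUT / "samples_a.tsv")
    io.write_sample_table(samples_b, OUT / "samples_b.tsv")
    io.write_expression_matrix(human_matrix, OUT / "human_matrix.tsv")
    io.write_sample_table(human_samples, OUT / "human_samples.tsv")
    pd.DataFrame(
        {"gene": truth.universe,
         "direction": [truth.direction[g] for g in truth.universe],
         "conserved": [truth.conserved.get(g, False) for g in truth.universe]}
    ).to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)
    truth.probe_map.to_csv(OUT / "ground_truth_probes.tsv", sep="\t", index=False)

    n_planted = len(truth.planted)
    print(f"cohort written to {OUT}")
    print(f"  platform A: {matrix_a.shape[0]} probes x {matrix_a.shape[1]} samples")
    print(f"  platform B: {matrix_b.shape[0]} genes x {matrix_b.shape[1]} samples")
    print(f"  human:      {human_matrix.shape[0]} genes x {human_matrix.shape[1]} samples")
    print(f"  planted maturation program: {n_planted} genes "
          f"({len(truth.increasing)} increasing / {len(truth.decreasing)} decreasing), "
          f"{sum(truth.conserved.values())} conserved in the human data")


if __name__ == "__main__":
    main()
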