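"""Sweep generator conditions (effect size x conservation) and report how
selection sensitivity/precision and the cross-species correlations respond,
with Monte-Carlo standard errors over seeds.

Writes results/benchmark/recovery.tsv.
"""

from pathlib import Path

from cardiomat import SimulationConfig, run_benchmark

OUT = Path(__file__).resolve().parent.parent / "results" / "benchmark"


def main() -> None:
    base = SimulationConfig(n_genes=600, seed=1)
    report = run_benchmark(
        effect_sizes=[0.0, 0.5, 1.0, 2.0],
        noise_sds=[1.0],
        conserved_fracs=[0.5, 0.9],
        n_seeds=3,
        base=base,
    )
    OUT.mkdir(parents=True, exist_ok=True)
    report.to_csv(OUT / "recovery.tsv", sep="\t", index=False,
                  float_format="%.4g")
    print(report.to_string(index=False,
                           float_format=lambda v: f"{v:.3f}"))
    print("\nsensitivity rises with effect size; r(selected) tracks the "
          "conserved fraction and exceeds r(all) once a program is planted")


if __name__ == "__main__":
    main()
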