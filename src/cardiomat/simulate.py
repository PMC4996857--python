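"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates a two-platform mouse developmental compendium plus a
fetal/adult human dataset:

* a gene universe partially shared between two platforms (``platform_overlap``),
* five ordered developmental stages with unbalanced per-stage sample counts,
* a planted maturation program — a fraction of genes whose log2 expression
  drifts linearly with stage, split evenly between increasing and decreasing,
* additive per-(gene, batch) offsets emulating batch structure that loads on
  a principal component orthogonal to the stage trend when batches are
  balanced across stages,
* probe-level expansion on platform A where a minority of genes carry 2-4
  probesets: exactly one probe carries the full signal, the others are
  attenuated copies, some nearly flat ("dead"),
* a human dataset whose symbols are the uppercased mouse symbols and in which
  a configurable fraction of the planted program is conserved in direction.

Per gene *g* and sample *j* the model is

    x_gj = mu_g + beta_g * effect_size * (stage_j - (S+1)/2) + batch(g, b_j) + eps_gj

with ``beta_g`` in {+1, -1, 0} and ``eps ~ Normal(0, noise_sd^2)``, on the
log2 scale.  The stage term is centered so baselines are stage-symmetric;
this is the same linear-in-stage mean structure the downstream regression
fits, up to the intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeAnnotation, SampleTable, ValidationError
from .io import GeneSet

log = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_mouse_pair", "simulate_human",
           "make_planted_gmt"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model.  All expression units are log2.

    ``samples_per_stage_a/b`` default to the per-stage array counts of a
    realistic developmental compendium on the two platforms (heavily
    adult-weighted and unbalanced between platforms).
    """

    n_genes: int = 2000          # genes per platform; shared + platform-unique
    frac_maturation: float = 0.10  # fraction of the universe planted monotone
    n_stages: int = 5
    samples_per_stage_a: tuple[int, ...] = (16, 39, 26, 16, 115)
    samples_per_stage_b: tuple[int, ...] = (12, 4, 2, 2, 134)
    n_fetal: int = 10
    n_adult: int = 10
    effect_size: float = 1.0     # per-stage mean increment for planted genes
    noise_sd: float = 1.0
    batch_sd: float = 0.5
    n_batches: int = 4
    platform_overlap: float = 0.8
    multiprobe_frac: float = 0.3  # platform-A genes carried by 2-4 probes
    dead_probe_frac: float = 0.3  # extra probes that are near-flat
    conserved_frac: float = 0.9   # planted genes conserved in the human data
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_maturation": self.frac_maturation,
            "platform_overlap": self.platform_overlap,
            "multiprobe_frac": self.multiprobe_frac,
            "dead_probe_frac": self.dead_probe_frac,
            "conserved_frac": self.conserved_frac,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        counts = {
            "n_genes": self.n_genes,
            "n_stages": self.n_stages,
            "n_batches": self.n_batches,
            "n_fetal": self.n_fetal,
            "n_adult": self.n_adult,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValidationError(f"{name}={v} must be >= 1")
        if self.n_stages < 2:
            raise ValidationError("n_stages must be >= 2")
        for name, tup in (
            ("samples_per_stage_a", self.samples_per_stage_a),
            ("samples_per_stage_b", self.samples_per_stage_b),
        ):
            if len(tup) != self.n_stages:
                raise ValidationError(f"{name} has {len(tup)} entries, need {self.n_stages}")
            if any(n < 1 for n in tup):
                raise ValidationError(f"{name} entries must be >= 1")
        if self.noise_sd < 0 or self.batch_sd < 0 or self.effect_size < 0:
            raise ValidationError("effect_size, noise_sd, batch_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted labels: direction per gene, conservation, probe designations."""

    direction: dict[str, int]          # gene -> +1 / -1 / 0, over the full universe
    conserved: dict[str, bool]         # planted gene -> conserved in human data
    probe_map: pd.DataFrame            # probe_id, gene_symbol, is_signal
    genes_a: list[str] = field(default_factory=list)
    genes_b: list[str] = field(default_factory=list)

    @property
    def universe(self) -> list[str]:
        return sorted(self.direction)

    @property
    def planted(self) -> list[str]:
        return sorted(g for g, d in self.direction.items() if d != 0)

    @property
    def increasing(self) -> set[str]:
        return {g for g, d in self.direction.items() if d == +1}

    @property
    def decreasing(self) -> set[str]:
        return {g for g, d in self.direction.items() if d == -1}

    def signal_probe(self, gene: str) -> str:
        rows = self.probe_map[
            (self.probe_map["gene_symbol"] == gene) & self.probe_map["is_signal"]
        ]
        return rows["probe_id"].iloc[0]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Named substream: module-level determinism from a single config seed."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _stage_vector(samples_per_stage: tuple[int, ...]) -> np.ndarray:
    return np.repeat(np.arange(1, len(samples_per_stage) + 1),
                     samples_per_stage).astype(int)


def _sample_table(prefix: str, stages: np.ndarray, n_batches: int,
                  species: str) -> SampleTable:
    rows = []
    counter_within: dict[int, int] = {}
    for i, s in enumerate(stages):
        k = counter_within.get(int(s), 0)
        counter_within[int(s)] = k + 1
        rows.append(
            {
                "sample_id": f"{prefix}_s{i:03d}",
                "stage": int(s),
                "species": species,
                # cycle batches within each stage -> balanced across stages
                "batch": f"{prefix}_b{k % n_batches}",
            }
        )
    return SampleTable(pd.DataFrame(rows))


def _gene_values(
    rng: np.random.Generator,
    genes: list[str],
    betas: np.ndarray,
    stages: np.ndarray,
    batches: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Gene x sample log2 values from the linear-in-stage model."""
    n_g, n_s = len(genes), len(stages)
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_g)
    centered = stages - (config.n_stages + 1) / 2.0
    trend = betas[:, None] * config.effect_size * centered[None, :]
    batch_ids = np.unique(batches)
    offsets = rng.normal(0.0, config.batch_sd, size=(n_g, batch_ids.size))
    batch_idx = np.searchsorted(batch_ids, batches)
    eps = rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    return mu[:, None] + trend + offsets[:, batch_idx] + eps


def simulate_mouse_pair(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation, ExpressionMatrix,
           SampleTable, SampleTable, GroundTruth]:
    """Simulate the two-platform mouse compendium.

    Returns ``(matrix_a, annotation_a, matrix_b, samples_a, samples_b, truth)``
    where platform A is probe-level (with multiprobe expansion) and platform B
    is gene-level.  Both matrices are on the log2 scale (``is_log2=True``),
    unscaled.
    """
    config.validate()
    rng_universe = _rng(config, 0)

    # --- gene universe and planted program ----------------------------------
    n_shared = int(round(config.platform_overlap * config.n_genes))
    n_unique = config.n_genes - n_shared
    n_universe = config.n_genes + n_unique
    universe = [f"Gene{i:05d}" for i in range(n_universe)]
    perm = rng_universe.permutation(n_universe)
    shared = [universe[i] for i in perm[:n_shared]]
    unique_a = [universe[i] for i in perm[n_shared:n_shared + n_unique]]
    unique_b = [universe[i] for i in perm[n_shared + n_unique:]]
    genes_a = sorted(shared + unique_a)
    genes_b = sorted(shared + unique_b)

    n_planted = int(round(config.frac_maturation * n_universe))
    planted = rng_universe.choice(universe, size=n_planted, replace=False)
    direction = {g: 0 for g in universe}
    for i, g in enumerate(sorted(planted)):
        direction[g] = +1 if i < (n_planted + 1) // 2 else -1
    n_conserved = int(round(config.conserved_frac * n_planted))
    conserved_set = set(
        rng_universe.choice(sorted(planted), size=n_conserved, replace=False)
    ) if n_planted else set()
    conserved = {g: (g in conserved_set) for g in sorted(planted)}

    # --- platform B: gene level ---------------------------------------------
    stages_b = _stage_vector(config.samples_per_stage_b)
    samples_b = _sample_table("b", stages_b, config.n_batches, "mouse-like")
    betas_b = np.array([direction[g] for g in genes_b], dtype=float)
    rng_b = _rng(config, 2)
    vals_b = _gene_values(rng_b, genes_b, betas_b, stages_b,
                          np.array(samples_b.table["batch"]), config)
    matrix_b = ExpressionMatrix(
        pd.DataFrame(vals_b, index=genes_b, columns=samples_b.sample_ids),
        feature_kind="gene", platform="mogene-like", is_log2=True,
    )

    # --- platform A: probe level with multiprobe expansion ------------------
    stages_a = _stage_vector(config.samples_per_stage_a)
    samples_a = _sample_table("a", stages_a, config.n_batches, "mouse-like")
    batch_labels_a = np.array(samples_a.table["batch"])
    rng_a = _rng(config, 1)

    betas_a = np.array([direction[g] for g in genes_a], dtype=float)
    n_ga, n_sa = len(genes_a), stages_a.size
    mu_a = rng_a.normal(config.baseline_mean, config.baseline_sd, size=n_ga)
    centered_a = stages_a - (config.n_stages + 1) / 2.0
    batch_ids_a = np.unique(batch_labels_a)
    offsets_a = rng_a.normal(0.0, config.batch_sd, size=(n_ga, batch_ids_a.size))
    batch_idx_a = np.searchsorted(batch_ids_a, batch_labels_a)
    # per-gene signal component shared by that gene's probes (before shrink)
    signal_a = (betas_a[:, None] * config.effect_size * centered_a[None, :]
                + offsets_a[:, batch_idx_a])

    is_multi = rng_a.random(n_ga) < config.multiprobe_frac
    n_probes = np.where(is_multi, rng_a.integers(2, 5, size=n_ga), 1)

    probe_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    ann_rows: list[dict] = []
    counter = 0
    for gi, gene in enumerate(genes_a):
        k = int(n_probes[gi])
        signal_idx = int(rng_a.integers(k)) if k > 1 else 0
        for p in range(k):
            pid = f"pa{counter:06d}_at"
            counter += 1
            if p == signal_idx:
                shrink = 1.0
            elif rng_a.random() < config.dead_probe_frac:
                shrink = rng_a.uniform(0.02, 0.10)   # near-flat "dead" probe
            else:
                shrink = rng_a.uniform(0.30, 0.70)   # attenuated probe
            jitter = rng_a.normal(0.0, 0.2) if p != signal_idx else 0.0
            eps = rng_a.normal(0.0, config.noise_sd, size=n_sa)
            row = mu_a[gi] + jitter + shrink * (signal_a[gi] + eps)
            probe_rows.append(row)
            probe_ids.append(pid)
            ann_rows.append(
                {"probe_id": pid, "gene_symbol": gene, "is_signal": p == signal_idx}
            )
    matrix_a = ExpressionMatrix(
        pd.DataFrame(np.vstack(probe_rows), index=probe_ids,
                     columns=samples_a.sample_ids),
        feature_kind="probe", platform="mouse430-like", is_log2=True,
    )
    probe_map = pd.DataFrame(ann_rows)
    annotation_a = ProbeAnnotation(probe_map[["probe_id", "gene_symbol"]].copy())

    truth = GroundTruth(
        direction=direction,
        conserved=conserved,
        probe_map=probe_map,
        genes_a=genes_a,
        genes_b=genes_b,
    )
    log.info(
        "simulated universe=%d shared=%d uniqueA=%d uniqueB=%d planted=%d "
        "probesA=%d", n_universe, n_shared, n_unique, n_unique, n_planted,
        len(probe_ids),
    )
    return matrix_a, annotation_a, matrix_b, samples_a, samples_b, truth


def simulate_human(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[ExpressionMatrix, SampleTable]:
    """Simulate the fetal/adult human dataset from mouse ground truth.

    Human symbols are the uppercased mouse symbols.  Conserved planted genes
    get an adult-minus-fetal shift with the same sign and the full
    across-stage magnitude of the mouse program; non-conserved planted genes
    and null genes get zero shift.  Noise is independent of the mouse data.
    """
    config.validate()
    universe = truth.universe
    if not universe:
        raise ValidationError("ground truth has an empty gene universe")
    expect = config.n_genes + (config.n_genes - int(round(config.platform_overlap * config.n_genes)))
    if len(universe) != expect:
        raise ValidationError(
            f"truth universe size {len(universe)} does not match config ({expect})"
        )
    rng = _rng(config, 3)
    human_genes = [g.upper() for g in universe]
    n_g = len(human_genes)
    n_s = config.n_fetal + config.n_adult
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_g)
    shift = np.zeros(n_g)
    span = config.effect_size * (config.n_stages - 1)
    for i, g in enumerate(universe):
        if truth.direction[g] != 0 and truth.conserved.get(g, False):
            shift[i] = truth.direction[g] * span
    is_adult = np.array([0] * config.n_fetal + [1] * config.n_adult)
    eps = rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    vals = mu[:, None] + shift[:, None] * is_adult[None, :] + eps
    sample_ids = [f"h_s{i:03d}" for i in range(n_s)]
    matrix = ExpressionMatrix(
        pd.DataFrame(vals, index=human_genes, columns=sample_ids),
        feature_kind="gene", platform="human-like", is_log2=True,
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "stage": (is_adult + 1).astype(int),
                "group": np.where(is_adult == 1, "adult", "fetal"),
                "species": "human-like",
                "batch": "h_b0",
            }
        )
    )
    return matrix, samples


def make_planted_gmt(
    truth: GroundTruth, n_random_sets: int = 8, set_size: int = 40,
    seed: int = 0,
) -> list[GeneSet]:
    """A synthetic gene-set collection: the planted mature and immature
    programs as two sets, plus random sets drawn from the universe —
    a fixture for over-representation analysis."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    universe = truth.universe
    sets = [
        GeneSet("planted_mature", "planted increasing genes",
                frozenset(truth.increasing)),
        GeneSet("planted_immature", "planted decreasing genes",
                frozenset(truth.decreasing)),
    ]
    for i in range(n_random_sets):
        members = rng.choice(universe, size=min(set_size, len(universe)),
                             replace=False)
        sets.append(GeneSet(f"random_{i:02d}", "random background set",
                            frozenset(members)))
    return sets
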