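"""PCA of sample profiles and cross-platform maturation-gene selection.

The first principal component of a developmental compendium tracks
maturation; its per-gene loadings order genes by how strongly and in which
direction they follow that axis.  Selection sums the (sign-oriented) PC1
loadings of genes shared between two platforms and takes genes whose summed
loading falls outside mean +/- k*SD of the shared pool; genes unique to one
platform are selected by the same rule within that platform's unique-gene
loading pool.

Sign convention: after :func:`orient_pc1`, a positive PC1 loading means
expression increases with maturation, so the upper tail is the
"mature-associated" list and the lower tail the "immature-associated" one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleTable, ValidationError

log = logging.getLogger(__name__)

__all__ = ["PCAResult", "GeneSelection", "pca", "orient_pc1",
           "select_maturation_genes"]


@dataclass
class PCAResult:
    """Scores (samples x components), unit-norm loadings (features x
    components) and per-component explained variance."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def flipped(self, component: int = 0) -> "PCAResult":
        """Copy with one component's sign reversed (PCA signs are arbitrary)."""
        scores = self.scores.copy()
        loadings = self.loadings.copy()
        scores.iloc[:, component] *= -1
        loadings.iloc[:, component] *= -1
        return PCAResult(scores, loadings, self.explained_variance.copy())


@dataclass
class GeneSelection:
    """Disjoint mature/immature gene lists with per-gene provenance and the
    threshold statistics of each pool."""

    mature: set[str] = field(default_factory=set)
    immature: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.mature & self.immature
        if overlap:
            raise ValidationError(f"mature/immature overlap: {sorted(overlap)[:5]}")

    @property
    def selected(self) -> set[str]:
        return self.mature | self.immature


def pca(
    m: ExpressionMatrix,
    n_components: int | None = None,
    *,
    allow_unscaled: bool = False,
) -> PCAResult:
    """PCA of sample profiles on feature-centered data.

    Each feature is centered across samples; components (ordered by
    decreasing variance) are computed by thin SVD.  Scores are the centered
    data projected on the loadings; explained variance uses the n-1
    denominator.  Requires a per-sample scaled matrix unless the caller
    explicitly waives with ``allow_unscaled``.
    """
    if not m.is_scaled and not allow_unscaled:
        raise ValidationError(
            "matrix is not per-sample scaled; pass allow_unscaled=True to waive"
        )
    n_feat, n_samp = m.shape
    if n_feat < 2 or n_samp < 2:
        raise ValidationError(f"need >= 2 features and >= 2 samples, got {m.shape}")
    max_k = min(n_feat, n_samp)
    if n_components is None:
        n_components = max_k
    if n_components > max_k:
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_features, n_samples)={max_k}"
        )
    X = m.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    # thin SVD: columns of U are the unit-norm loading vectors
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components
    loadings = U[:, :k]
    scores = (S[:k, None] * Vt[:k]).T  # = Xc^T @ U
    expl = (S[:k] ** 2) / (n_samp - 1)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=m.feature_ids, columns=comp_names),
        explained_variance=expl,
    )


def orient_pc1(p: PCAResult, samples: SampleTable) -> PCAResult:
    """Fix PC1's arbitrary sign against the stage ordering.

    PC1 is flipped if needed so that the mean PC1 score of the highest stage
    exceeds that of the lowest; positive loading then means expression
    increases with maturation.  An exact tie leaves the sign unchanged with
    a warning.
    """
    stages = samples.stages_for(p.scores.index)
    if np.unique(stages).size < 2:
        raise ValidationError("need >= 2 distinct stages to orient PC1")
    pc1 = p.scores.iloc[:, 0].to_numpy()
    hi = pc1[stages == stages.max()].mean()
    lo = pc1[stages == stages.min()].mean()
    if hi == lo:
        log.warning("PC1 stage means exactly tie; leaving sign unchanged")
        return PCAResult(p.scores.copy(), p.loadings.copy(),
                         p.explained_variance.copy())
    if hi < lo:
        return p.flipped(0)
    return PCAResult(p.scores.copy(), p.loadings.copy(),
                     p.explained_variance.copy())


def _two_sided_tail(
    pool: pd.Series, sd_multiplier: float
) -> tuple[set[str], set[str], tuple[float, float]]:
    """Genes beyond mean +/- k*SD of the pool (upper tail, lower tail)."""
    mu = float(pool.mean())
    sd = float(pool.std(ddof=1)) if len(pool) > 1 else 0.0
    if sd == 0.0:
        log.warning("loading pool has zero SD; nothing selected")
        return set(), set(), (mu, sd)
    upper = set(pool.index[pool - mu > sd_multiplier * sd])
    lower = set(pool.index[mu - pool > sd_multiplier * sd])
    return upper, lower, (mu, sd)


def select_maturation_genes(
    p_a: PCAResult,
    p_b: PCAResult,
    sd_multiplier: float = 2.0,
) -> tuple[pd.DataFrame, GeneSelection]:
    """Cross-platform maturation-gene selection from two oriented PCA results.

    Shared genes: per-gene PC1 loadings of the two platforms are summed and
    the mean +/- ``sd_multiplier``*SD rule is applied to the summed pool.
    Platform-unique genes: the same rule within that platform's unique-gene
    loadings.  Both inputs must already be stage-oriented
    (:func:`orient_pc1`); loading columns are unit-norm on each platform, so
    the platforms contribute comparably to the sum.

    Returns ``(loading_table, selection)`` where the loading table has
    columns ``loading_a, loading_b, summed`` (NaN where a gene is absent
    from a platform).
    """
    if sd_multiplier <= 0:
        raise ValidationError(f"sd_multiplier must be > 0, got {sd_multiplier}")
    la = p_a.loadings.iloc[:, 0]
    lb = p_b.loadings.iloc[:, 0]
    genes_a, genes_b = set(la.index), set(lb.index)
    shared = sorted(genes_a & genes_b)
    unique_a = sorted(genes_a - genes_b)
    unique_b = sorted(genes_b - genes_a)
    if not genes_a and not genes_b:
        raise ValidationError("both platforms have empty gene sets")
    if not shared:
        log.warning("no shared genes; selecting from unique pools only")

    all_genes = sorted(genes_a | genes_b)
    table = pd.DataFrame(index=pd.Index(all_genes, name="gene"))
    table["loading_a"] = la.reindex(all_genes)
    table["loading_b"] = lb.reindex(all_genes)
    table["summed"] = np.where(
        table.index.isin(shared),
        table["loading_a"].fillna(0) + table["loading_b"].fillna(0),
        np.nan,
    )

    sel = GeneSelection()
    pools: list[tuple[str, pd.Series]] = []
    if shared:
        pools.append(("shared", table.loc[shared, "summed"]))
    if unique_a:
        pools.append(("uniqueA", la.loc[unique_a]))
    if unique_b:
        pools.append(("uniqueB", lb.loc[unique_b]))
    for name, pool in pools:
        upper, lower, (mu, sd) = _two_sided_tail(pool, sd_multiplier)
        sel.mature |= upper
        sel.immature |= lower
        for g in upper | lower:
            sel.provenance[g] = name
        sel.thresholds[name] = (mu, sd)
    if not sel.selected:
        log.warning("selection is empty at sd_multiplier=%.2f", sd_multiplier)
    log.info(
        "selection: %d mature, %d immature (shared=%d, uniqueA=%d, uniqueB=%d)",
        len(sel.mature), len(sel.immature), len(shared), len(unique_a),
        len(unique_b),
    )
    return table, sel
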