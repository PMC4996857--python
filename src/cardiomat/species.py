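"""Cross-species comparison of maturation expression changes.

Mouse and human genes are paired by case-insensitive symbol identity
(mouse ``Myh7`` <-> human ``MYH7``).  For each paired gene the adult-minus-
early expression change (delta) is computed in each species; correlation of
the two delta vectors, direction-consistency of the mouse-derived selection
against the human deltas, and the alternative delta-sum selection all
operate on the resulting table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SampleTable, ValidationError
from .pca import GeneSelection

log = logging.getLogger(__name__)

__all__ = ["map_symbols", "compute_deltas", "make_delta_table",
           "delta_correlation", "ConsistencyReport", "consistency_report",
           "alternative_delta_selection", "selection_overlap"]


def map_symbols(
    mouse_genes, human_genes
) -> pd.DataFrame:
    """Pair mouse and human genes by uppercased symbol identity.

    One-to-one: if several case-variants of a symbol occur on one side they
    are collapsed to the lexicographically smallest variant (collision
    logged).  Unmatched symbols are dropped, with counts logged.  Returns a
    DataFrame with columns ``mouse_symbol, human_symbol`` sorted by the
    uppercased key.
    """
    def collapse(genes) -> dict[str, str]:
        by_upper: dict[str, list[str]] = {}
        for g in genes:
            by_upper.setdefault(str(g).upper(), []).append(str(g))
        out = {}
        for key, variants in by_upper.items():
            if len(set(variants)) > 1:
                log.warning("case-variant collision for %s: %s", key,
                            sorted(set(variants)))
            out[key] = min(variants)
        return out

    mouse = collapse(mouse_genes)
    human = collapse(human_genes)
    keys = sorted(set(mouse) & set(human))
    log.info("symbol mapping: %d pairs (%d mouse / %d human unmatched)",
             len(keys), len(mouse) - len(keys), len(human) - len(keys))
    return pd.DataFrame(
        {"mouse_symbol": [mouse[k] for k in keys],
         "human_symbol": [human[k] for k in keys]}
    )


def compute_deltas(
    m: ExpressionMatrix,
    samples: SampleTable,
    group_hi: str,
    group_lo: str,
    by: str = "group",
) -> pd.Series:
    """Per-gene mean difference: mean over ``group_hi`` samples minus mean
    over ``group_lo`` samples.  ``by`` selects the metadata column used for
    grouping (``"group"`` labels or ``"stage"`` codes)."""
    hi = samples.samples_in_group(group_hi, by=by)
    lo = samples.samples_in_group(group_lo, by=by)
    hi = [s for s in hi if s in set(m.sample_ids)]
    lo = [s for s in lo if s in set(m.sample_ids)]
    if not hi or not lo:
        raise ValidationError(
            f"empty group: hi={group_hi!r} ({len(hi)}), lo={group_lo!r} ({len(lo)})"
        )
    delta = m.values[hi].mean(axis=1) - m.values[lo].mean(axis=1)
    delta.name = "delta"
    return delta


def make_delta_table(
    pairs: pd.DataFrame, delta_mouse: pd.Series, delta_human: pd.Series
) -> pd.DataFrame:
    """Join per-species deltas over mapped pairs.

    Only pairs with a delta on both sides are kept.  Returns a DataFrame
    indexed by mouse symbol with columns ``human_symbol, delta_mouse,
    delta_human``.
    """
    keep = pairs[
        pairs["mouse_symbol"].isin(delta_mouse.index)
        & pairs["human_symbol"].isin(delta_human.index)
    ]
    out = pd.DataFrame(
        {
            "human_symbol": keep["human_symbol"].to_numpy(),
            "delta_mouse": delta_mouse.loc[keep["mouse_symbol"]].to_numpy(),
            "delta_human": delta_human.loc[keep["human_symbol"]].to_numpy(),
        },
        index=pd.Index(keep["mouse_symbol"].to_numpy(), name="gene"),
    )
    return out


def delta_correlation(
    d: pd.DataFrame, subset: set[str] | None = None
) -> float:
    """Pearson r between mouse and human deltas, over all mapped genes or a
    subset (indexed by mouse symbol)."""
    t = d if subset is None else d.loc[d.index.isin(subset)]
    if len(t) < 3:
        raise ValidationError(f"need >= 3 genes for correlation, got {len(t)}")
    return float(stats.pearsonr(t["delta_mouse"], t["delta_human"])[0])


@dataclass
class ConsistencyReport:
    """Direction-consistency of a mouse-derived selection in the human data.

    A mature gene is consistent iff its human delta is strictly positive, an
    immature gene iff strictly negative; inconsistent genes above the
    fold-change threshold are those with |delta_human| > log2(fc_threshold).
    """

    n_mature_mapped: int
    n_immature_mapped: int
    n_consistent_mature: int
    n_consistent_immature: int
    n_inconsistent: int
    n_inconsistent_above_fc: int
    fc_threshold: float

    @property
    def n_mapped(self) -> int:
        return self.n_mature_mapped + self.n_immature_mapped


def consistency_report(
    d: pd.DataFrame, sel: GeneSelection, fc_threshold: float = 1.5
) -> ConsistencyReport:
    """Count direction-consistent and -inconsistent selected genes."""
    if fc_threshold <= 1:
        raise ValidationError(f"fc_threshold must be > 1, got {fc_threshold}")
    mapped = set(d.index)
    missing = sel.selected - mapped
    if missing:
        log.info("%d selected genes have no mapped human counterpart",
                 len(missing))
    mature = sorted(sel.mature & mapped)
    immature = sorted(sel.immature & mapped)
    dh_m = d.loc[mature, "delta_human"].to_numpy() if mature else np.array([])
    dh_i = d.loc[immature, "delta_human"].to_numpy() if immature else np.array([])
    cons_m = int((dh_m > 0).sum())
    cons_i = int((dh_i < 0).sum())
    incons_deltas = np.concatenate([dh_m[~(dh_m > 0)], dh_i[~(dh_i < 0)]])
    cut = np.log2(fc_threshold)
    return ConsistencyReport(
        n_mature_mapped=len(mature),
        n_immature_mapped=len(immature),
        n_consistent_mature=cons_m,
        n_consistent_immature=cons_i,
        n_inconsistent=int(incons_deltas.size),
        n_inconsistent_above_fc=int((np.abs(incons_deltas) > cut).sum()),
        fc_threshold=fc_threshold,
    )


def alternative_delta_selection(
    d: pd.DataFrame, sd_multiplier: float = 2.0
) -> GeneSelection:
    """Delta-sum selection: score = delta_mouse + delta_human per mapped
    gene; genes with score beyond mean +/- ``sd_multiplier``*SD of all
    mapped genes are selected (upper tail mature, lower tail immature)."""
    if len(d) < 10:
        raise ValidationError(f"need >= 10 mapped genes, got {len(d)}")
    score = d["delta_mouse"] + d["delta_human"]
    mu = float(score.mean())
    sd = float(score.std(ddof=1))
    sel = GeneSelection()
    if sd == 0.0:
        log.warning("delta-sum scores have zero SD; nothing selected")
        sel.thresholds["delta_sum"] = (mu, sd)
        return sel
    sel.mature = set(score.index[score - mu > sd_multiplier * sd])
    sel.immature = set(score.index[mu - score > sd_multiplier * sd])
    for g in sel.selected:
        sel.provenance[g] = "delta_sum"
    sel.thresholds["delta_sum"] = (mu, sd)
    return sel


def selection_overlap(a: GeneSelection, b: GeneSelection) -> dict[str, float]:
    """Set-arithmetic comparison of two selections."""
    inter = a.selected & b.selected
    union = a.selected | b.selected
    return {
        "n_a": len(a.selected),
        "n_b": len(b.selected),
        "n_mature_both": len(a.mature & b.mature),
        "n_immature_both": len(a.immature & b.immature),
        "n_intersection": len(inter),
        "n_union": len(union),
        "jaccard": (len(inter) / len(union)) if union else 0.0,
    }
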