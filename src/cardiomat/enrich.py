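"""Hypergeometric over-representation analysis and pathway-overlap networks.

Generic ORA against a user-supplied GMT collection: for each set the upper
tail P(X >= overlap) of the hypergeometric distribution is computed within a
stated gene universe, with Benjamini-Hochberg q-values across tested sets.
The pathway network connects tested sets that share query genes, weighting
each edge by the number of shared query genes.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError
from .io import GeneSet

log = logging.getLogger(__name__)

__all__ = ["ora", "pathway_network"]


def ora(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set.

    Sets are intersected with the universe; the query must be a subset of
    the universe.  Zero-overlap sets are still reported.  Returns a
    DataFrame with one row per set: ``set_name, overlap, set_size,
    query_size, universe_size, p_value, q_value, significant`` sorted by
    p-value (ties by set name).
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty query")
    stray = query - universe
    if stray:
        raise ValidationError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )
    M, n = len(universe), len(query)
    rows = []
    for s in sets:
        members = s.genes & universe
        K = len(members)
        k = len(members & query)
        # upper tail P(X >= k) for X ~ Hypergeom(M, K, n)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {"set_name": s.name, "overlap": k, "set_size": K,
             "query_size": n, "universe_size": M, "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["q_value"] = q
    out["significant"] = out["q_value"] < fdr
    return out.sort_values(["p_value", "set_name"]).reset_index(drop=True)


def pathway_network(
    rows: pd.DataFrame,
    sets: Sequence[GeneSet],
    query: Iterable[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap-weighted network over the tested sets, restricted to query genes.

    Nodes are the tested sets (attribute: ``significant``); an edge joins two
    sets sharing at least one query gene, weighted by the shared-gene count.
    Returns ``(edges, nodes)`` DataFrames; edges have columns
    ``node1, node2, weight``.
    """
    query = set(query)
    by_name = {s.name: s.genes & query for s in sets}
    tested = [n for n in rows["set_name"] if n in by_name]
    sig = dict(zip(rows["set_name"], rows["significant"]))
    nodes = pd.DataFrame(
        {
            "set_name": tested,
            "n_query_genes": [len(by_name[n]) for n in tested],
            "significant": [bool(sig[n]) for n in tested],
        }
    )
    edge_rows = []
    for u, v in combinations(tested, 2):
        w = len(by_name[u] & by_name[v])
        if w >= 1:
            edge_rows.append({"node1": u, "node2": v, "weight": w})
    edges = pd.DataFrame(edge_rows, columns=["node1", "node2", "weight"])
    return edges, nodes
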