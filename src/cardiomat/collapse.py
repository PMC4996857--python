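"""Probe-to-gene collapsing.

Two strategies: pick one representative probeset per gene by widest
interquartile range (IQR — robust to the noise that inflates full dynamic
range), or average all of a gene's probesets.  IQRs are computed on
log2-scale, pre-sample-scaling values, optionally from a separate reference
compendium; percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeAnnotation, ValidationError

log = logging.getLogger(__name__)

__all__ = ["compute_probe_iqr", "collapse_by_iqr", "collapse_by_mean"]


def compute_probe_iqr(
    m: ExpressionMatrix,
    ann: ProbeAnnotation,
    reference: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Per-probe IQR and the chosen (widest-IQR) probe per gene.

    The IQR (75th - 25th percentile across samples) is computed on
    ``reference`` when given, else on ``m`` itself.  Ties on IQR are broken
    by the lexicographically smallest probe_id.  Returns a DataFrame with
    columns ``probe_id, gene_symbol, iqr, dynamic_range, chosen`` —
    ``dynamic_range`` (max - min) is an audit column only.
    """
    source = reference if reference is not None else m
    if not source.is_log2:
        raise ValidationError("IQR source matrix must be log2-transformed")
    probes = ann.probe_ids
    known = set(source.feature_ids)
    missing = [p for p in probes if p not in known]
    if missing:
        raise ValidationError(
            f"probes in annotation absent from IQR source matrix: {missing[:10]}"
        )
    vals = source.values.loc[probes].to_numpy(dtype=float)
    q75, q25 = np.percentile(vals, [75, 25], axis=1)  # linear interpolation
    table = pd.DataFrame(
        {
            "probe_id": probes,
            "gene_symbol": ann.table["gene_symbol"].to_numpy(),
            "iqr": q75 - q25,
            "dynamic_range": vals.max(axis=1) - vals.min(axis=1),
        }
    )
    # widest IQR wins; ties -> lexicographically smallest probe_id
    ordered = table.sort_values(
        ["gene_symbol", "iqr", "probe_id"], ascending=[True, False, True]
    )
    chosen_probes = set(ordered.groupby("gene_symbol", sort=False)["probe_id"].first())
    table["chosen"] = table["probe_id"].isin(chosen_probes)
    return table


def collapse_by_iqr(m: ExpressionMatrix, table: pd.DataFrame) -> ExpressionMatrix:
    """Gene-level matrix whose rows are the chosen probes' rows, verbatim.

    ``table`` comes from :func:`compute_probe_iqr` over the same annotation;
    genes are ordered lexicographically.
    """
    chosen = table[table["chosen"]].sort_values("gene_symbol")
    known = set(m.feature_ids)
    missing = [p for p in chosen["probe_id"] if p not in known]
    if missing:
        raise ValidationError(f"chosen probes absent from matrix: {missing[:10]}")
    out = m.values.loc[chosen["probe_id"]].copy()
    out.index = chosen["gene_symbol"].to_numpy()
    # row subsetting breaks exact per-sample moments, so is_scaled is dropped
    return ExpressionMatrix(
        out, feature_kind="gene", platform=m.platform,
        is_log2=m.is_log2, is_scaled=False,
    )


def collapse_by_mean(m: ExpressionMatrix, ann: ProbeAnnotation) -> ExpressionMatrix:
    """Gene-level matrix: unweighted mean of each gene's probe rows
    (arithmetic mean on the log2 scale)."""
    known = set(m.feature_ids)
    missing = [p for p in ann.probe_ids if p not in known]
    if missing:
        raise ValidationError(f"probes in annotation absent from matrix: {missing[:10]}")
    sub = m.values.loc[ann.probe_ids]
    grouped = sub.groupby(ann.table["gene_symbol"].to_numpy()).mean()
    grouped = grouped.sort_index()
    # averaging breaks exact per-sample moments even if input was scaled
    return ExpressionMatrix(
        grouped, feature_kind="gene", platform=m.platform,
        is_log2=m.is_log2, is_scaled=False,
    )
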