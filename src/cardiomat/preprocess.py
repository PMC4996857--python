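"""Log2 transform, per-sample z-scaling, and between-preprocessing concordance.

Scaling is per sample column (mean 0, SD 1 with the n-1 denominator): it makes
arrays comparable across platforms while leaving the across-sample profile of
each gene — and hence the interpretation of PCA loading magnitudes — intact.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)

__all__ = ["log2_transform", "scale_samples", "matrix_concordance"]


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Return log2(values + offset); requires all shifted values > 0."""
    if m.is_log2:
        raise ValidationError("matrix is already log2-transformed")
    if offset < 0:
        raise ValidationError(f"offset must be nonnegative, got {offset}")
    arr = m.values.to_numpy(dtype=float) + offset
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValidationError(
            f"nonpositive value at feature {m.feature_ids[i]!r}, "
            f"sample {m.sample_ids[j]!r} with offset {offset}"
        )
    out = pd.DataFrame(np.log2(arr), index=m.values.index, columns=m.values.columns)
    return m.with_values(out, is_log2=True)


def scale_samples(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample column to mean 0, SD 1 (n-1 denominator)."""
    arr = m.values.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValidationError("need >= 2 features to scale sample columns")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    # a spread at float64 resolution is treated as constant, not scaled up
    flat = np.flatnonzero(sd <= np.abs(arr).max(axis=0) * 1e-13)
    if flat.size:
        raise ValidationError(
            f"constant sample column(s): {[m.sample_ids[i] for i in flat[:5]]}"
        )
    scaled = (arr - mean) / sd
    # second pass kills the cancellation residue left by near-constant
    # columns, making the result an exact fixed point of the transform
    scaled -= scaled.mean(axis=0)
    sd2 = scaled.std(axis=0, ddof=1)
    if (sd2 == 0).any():
        bad = np.flatnonzero(sd2 == 0)
        raise ValidationError(
            f"constant sample column(s): {[m.sample_ids[i] for i in bad[:5]]}"
        )
    scaled /= sd2
    out = pd.DataFrame(scaled, index=m.values.index, columns=m.values.columns)
    return m.with_values(out, is_scaled=True)


def matrix_concordance(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> dict[str, float]:
    """Concordance of two preprocessings of the same samples.

    Returns Pearson r over all matched cells and Pearson r between the
    sign-aligned PC1 loading vectors of the two matrices (b's loadings are
    flipped if their correlation with a's is negative).  Features and samples
    are intersected first; the intersection must keep >= 2 of each.
    """
    from .pca import pca  # local import to avoid a cycle

    feats = [f for f in a.feature_ids if f in set(b.feature_ids)]
    samps = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if len(feats) < 2 or len(samps) < 2:
        raise ValidationError(
            f"intersection too small: {len(feats)} features, {len(samps)} samples"
        )
    va = a.values.loc[feats, samps].to_numpy(dtype=float)
    vb = b.values.loc[feats, samps].to_numpy(dtype=float)
    r_values = float(stats.pearsonr(va.ravel(), vb.ravel())[0])

    pa = pca(a.with_values(a.values.loc[feats, samps], is_scaled=False),
             n_components=1, allow_unscaled=True)
    pb = pca(b.with_values(b.values.loc[feats, samps], is_scaled=False),
             n_components=1, allow_unscaled=True)
    la = pa.loadings.iloc[:, 0].to_numpy()
    lb = pb.loadings.iloc[:, 0].to_numpy()
    r_load = float(stats.pearsonr(la, lb)[0])
    if r_load < 0:  # PCA sign is arbitrary; align before reporting
        r_load = float(stats.pearsonr(la, -lb)[0])
    return {"pearson_r_values": r_values, "pearson_r_pc1_loadings": r_load}
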