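"""Stage coarse-graining, cross-stage rank distributions, and per-gene
ordinal linear regression with FDR control.

Expression is first averaged within each developmental stage, x_is =
(1/N_s) * sum_{j in s} x_ij, then each gene's S stage means are (a) ranked
across stages and (b) regressed on the ordinal stage code, x_is = a_i*s + b_i.
The regression is deliberately fitted to the S coarse-grained means, not the
per-sample values: low-power by construction, but it asks exactly whether
the stage trajectory itself is linear.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SampleTable, ValidationError

log = logging.getLogger(__name__)

__all__ = ["stage_means", "stage_ranks", "stage_rank_distribution",
           "stage_regression"]


def stage_means(m: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    """Genes x stages table of within-stage means x_is (columns 1..S)."""
    samples.check_matches(m)
    stages = samples.stages_for(m.sample_ids)
    n_stages = samples.n_stages
    present = np.unique(stages)
    expected = np.arange(1, n_stages + 1)
    missing = np.setdiff1d(expected, present)
    if missing.size:
        raise ValidationError(f"stages with zero samples in matrix: {missing.tolist()}")
    cols = {}
    arr = m.values.to_numpy(dtype=float)
    for s in expected:
        cols[int(s)] = arr[:, stages == s].mean(axis=1)
    return pd.DataFrame(cols, index=m.values.index)


def stage_ranks(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene competition ranks of x_is across stages.

    Rank 1 is the lowest stage mean; ties share the minimum rank
    ("1, 1, 3" style).
    """
    ranked = profiles.rank(axis=1, method="min", ascending=True)
    return ranked.astype(int)


def stage_rank_distribution(profiles: pd.DataFrame) -> pd.DataFrame:
    """Histogram of ranks per stage: rows = stages, columns = ranks 1..S;
    every row sums to the number of genes."""
    if profiles.shape[1] < 2:
        raise ValidationError("need >= 2 stages")
    ranks = stage_ranks(profiles)
    n_stages = profiles.shape[1]
    out = pd.DataFrame(
        0, index=pd.Index(profiles.columns, name="stage"),
        columns=pd.Index(range(1, n_stages + 1), name="rank"),
    )
    for s in profiles.columns:
        counts = ranks[s].value_counts()
        for r, c in counts.items():
            out.loc[s, int(r)] = int(c)
    return out


def stage_regression(
    profiles: pd.DataFrame, q_threshold: float = 0.1
) -> pd.DataFrame:
    """Per-gene OLS of the S stage means on the ordinal stage code.

    Returns a DataFrame (index = gene) with ``slope, intercept, p_value,
    q_value, significant``.  The two-sided slope p-value uses the t
    distribution with S-2 degrees of freedom; q-values are
    Benjamini-Hochberg over all genes; ``significant`` flags q < q_threshold.

    Degenerate conventions: a constant response gets slope 0 and p = 1; an
    exact non-constant linear fit (zero residual) gets p = 0.
    """
    S = profiles.shape[1]
    if S < 3:
        raise ValidationError(f"need >= 3 stages for regression, got {S}")
    s = np.asarray([int(c) for c in profiles.columns], dtype=float)
    X = profiles.to_numpy(dtype=float)
    s_bar = s.mean()
    sxx = float(((s - s_bar) ** 2).sum())
    x_bar = X.mean(axis=1)
    slope = ((X - x_bar[:, None]) * (s - s_bar)[None, :]).sum(axis=1) / sxx
    intercept = x_bar - slope * s_bar
    resid = X - (intercept[:, None] + slope[:, None] * s[None, :])
    ssr = (resid ** 2).sum(axis=1)
    total_var = ((X - x_bar[:, None]) ** 2).sum(axis=1)

    df = S - 2
    sigma2 = ssr / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = slope / np.sqrt(sigma2 / sxx)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    # conventions for degenerate genes
    constant = total_var <= 1e-300
    exact_fit = (~constant) & (ssr <= 1e-300)
    p = np.where(constant, 1.0, p)
    slope = np.where(constant, 0.0, slope)
    p = np.where(exact_fit, 0.0, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "slope": slope,
            "intercept": intercept,
            "p_value": p,
            "q_value": q,
            "significant": q < q_threshold,
        },
        index=profiles.index,
    )
    log.info("stage regression: %d/%d genes significant at q<%.3g",
             int(out["significant"].sum()), len(out), q_threshold)
    return out
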