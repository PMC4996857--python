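"""Core in-memory containers shared across the pipeline.

The analysis moves three kinds of tables around: expression matrices
(features x samples), sample metadata (stage / group / species / batch),
and probe-to-gene annotations.  Each gets a thin dataclass wrapper around a
pandas object plus an explicit ``validate`` so that malformed inputs fail
at the boundary, not deep inside a numerical routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "SampleTable",
    "ProbeAnnotation",
]

#: tolerance on per-sample moments for a matrix flagged as scaled
SCALED_TOL = 1e-9


class FormatError(ValueError):
    """A file or table violates the expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """A numeric feature x sample expression table.

    Parameters
    ----------
    values
        DataFrame with feature IDs as the index and sample IDs as columns.
        Signal-intensity units, or log2 units once ``is_log2`` is set.
    feature_kind
        ``"probe"`` or ``"gene"``.
    platform
        Free-text platform tag (e.g. ``"mouse430-like"``).
    is_log2, is_scaled
        Processing-state flags.  ``is_scaled`` asserts every sample column
        has mean 0 and SD 1 (n-1 denominator) within ``SCALED_TOL``.
    """

    values: pd.DataFrame
    feature_kind: str = "gene"
    platform: str = ""
    is_log2: bool = False
    is_scaled: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- structural accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def validate(self) -> None:
        if self.feature_kind not in ("probe", "gene"):
            raise ValidationError(
                f"feature_kind must be 'probe' or 'gene', got {self.feature_kind!r}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("matrix is not numeric")
        if np.isnan(arr).any():
            n = int(np.isnan(arr).sum())
            raise ValidationError(f"matrix contains {n} missing values")
        if self.is_scaled and arr.shape[0] >= 2:
            mean = arr.mean(axis=0)
            sd = arr.std(axis=0, ddof=1)
            bad = (np.abs(mean) > SCALED_TOL) | (np.abs(sd - 1.0) > SCALED_TOL)
            if bad.any():
                which = [cols[i] for i in np.flatnonzero(bad)[:5]]
                raise ValidationError(
                    f"is_scaled set but columns deviate from (0, 1) moments: {which}"
                )

    def with_values(self, values: pd.DataFrame, **flags) -> "ExpressionMatrix":
        """Return a copy carrying new values and (optionally) updated flags."""
        out = replace(self, values=values)
        for k, v in flags.items():
            setattr(out, k, v)
        out.validate()
        return out

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise ValidationError(f"features absent from matrix: {sorted(missing)[:5]}")
        return self.with_values(self.values.loc[ids])


@dataclass
class SampleTable:
    """Sample metadata: ordinal stage, optional group label, species, batch.

    ``stage`` is an ordinal integer running contiguously from 1 to S (S >= 2).
    Binary fetal/adult designs are encoded as stages 1 and 2 with the labels
    kept in ``group``.
    """

    table: pd.DataFrame  # columns: sample_id, stage, species, batch[, group]

    REQUIRED = ("sample_id", "stage", "species", "batch")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        sids = self.table["sample_id"]
        if sids.duplicated().any():
            raise ValidationError(
                f"duplicate sample ids: {sids[sids.duplicated()].tolist()[:5]}"
            )
        stages = self.table["stage"].to_numpy()
        try:
            stages = stages.astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError("stage codes must be integers") from exc
        uniq = np.unique(stages)
        if uniq.size < 2:
            raise ValidationError("need at least 2 distinct stages")
        if uniq[0] != 1 or not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValidationError(
                f"stage codes must be contiguous from 1, got {uniq.tolist()}"
            )

    @property
    def n_stages(self) -> int:
        return int(self.table["stage"].max())

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def stages_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Stage codes aligned to ``sample_ids``; raises if any is unknown."""
        lookup = dict(zip(self.table["sample_id"], self.table["stage"].astype(int)))
        out = []
        for sid in sample_ids:
            if sid not in lookup:
                raise ValidationError(f"sample {sid!r} absent from sample table")
            out.append(lookup[sid])
        return np.asarray(out, dtype=int)

    def samples_in_group(self, label: str, by: str = "group") -> list[str]:
        """Sample IDs whose ``by`` column (group or stage) equals ``label``."""
        if by == "stage":
            mask = self.table["stage"].astype(int) == int(label)
        else:
            if "group" not in self.table.columns:
                raise ValidationError("sample table has no 'group' column")
            mask = self.table["group"] == label
        return self.table.loc[mask, "sample_id"].tolist()

    def check_matches(self, m: ExpressionMatrix) -> None:
        """Every sample in ``m`` must appear exactly once here."""
        known = set(self.table["sample_id"])
        missing = [s for s in m.sample_ids if s not in known]
        if missing:
            raise ValidationError(f"samples without metadata: {missing[:5]}")


@dataclass
class ProbeAnnotation:
    """Probe-to-gene-symbol map; many probes may share one gene."""

    table: pd.DataFrame  # columns: probe_id, gene_symbol

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for c in ("probe_id", "gene_symbol"):
            if c not in self.table.columns:
                raise ValidationError(f"annotation missing column {c!r}")
        pid = self.table["probe_id"]
        if pid.duplicated().any():
            raise ValidationError(
                f"duplicate probe ids: {pid[pid.duplicated()].tolist()[:5]}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return self.table["probe_id"].tolist()

    @property
    def gene_symbols(self) -> list[str]:
        return sorted(self.table["gene_symbol"].unique())

    def probes_for_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p, g in zip(self.table["probe_id"], self.table["gene_symbol"]):
            out.setdefault(g, []).append(p)
        return out
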