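"""Readers and writers for the tab-delimited formats the pipeline touches.

Expression matrices are plain TSV (first column = feature IDs, header row =
sample IDs) with an optional JSON sidecar (``<path>.meta.json``) carrying the
processing-state flags; sample tables and probe annotations are TSV with
required named columns; gene-set collections use the standard GMT dialect;
gene lists are one symbol per line.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
import yaml

from .containers import ExpressionMatrix, FormatError, ProbeAnnotation, SampleTable

log = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_config",
    "GeneSet",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_expression_matrix(
    path: str | Path,
    feature_kind: str | None = None,
    *,
    missing: str = "reject",
    transposed: bool = False,
) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    Flags (feature_kind, platform, is_log2, is_scaled) come from the JSON
    sidecar when present and default to false otherwise; an explicit
    ``feature_kind`` argument overrides the sidecar.  ``missing`` is the
    missing-value policy: ``"reject"`` (default) or ``"drop"`` (drop any
    feature row containing a missing value).  ``transposed=True`` declares
    the file is samples x features; orientation is never auto-detected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transposed:
        df = df.T
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature rows: {dups[:5]}")
    try:
        values = df.astype(float)
    except ValueError:
        values = df.apply(pd.to_numeric, errors="coerce")
        bad = values.isna() & df.notna()
        if bad.any().any():
            r = bad.any(axis=1).idxmax()
            c = bad.loc[r].idxmax()
            raise FormatError(
                f"{path}: non-numeric cell at feature {r!r}, sample {c!r}: "
                f"{df.loc[r, c]!r}"
            ) from None
    if values.isna().any().any():
        if missing == "drop":
            before = len(values)
            values = values.dropna(axis=0)
            log.warning("%s: dropped %d features with missing values", path, before - len(values))
        else:
            n = int(values.isna().to_numpy().sum())
            raise FormatError(f"{path}: {n} missing values (policy 'reject')")
    meta: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(
        values=values,
        feature_kind=feature_kind or meta.get("feature_kind", "gene"),
        platform=meta.get("platform", ""),
        is_log2=bool(meta.get("is_log2", False)),
        is_scaled=bool(meta.get("is_scaled", False)),
    )


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> Path:
    """Write matrix as TSV plus a JSON sidecar with its flags."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips float64 exactly
    m.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")
    _sidecar(path).write_text(
        json.dumps(
            {
                "feature_kind": m.feature_kind,
                "platform": m.platform,
                "is_log2": m.is_log2,
                "is_scaled": m.is_scaled,
            },
            sort_keys=True,
        )
        + "\n"
    )
    return path


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    return SampleTable(df)


def write_sample_table(s: SampleTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    s.table.to_csv(path, sep="\t", index=False)
    return path


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ann.table.to_csv(path, sep="\t", index=False)
    return path


class GeneSet(NamedTuple):
    name: str
    description: str
    genes: frozenset[str]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set collection (name TAB description TAB genes...).

    Duplicate genes within a set are deduplicated; a line with fewer than
    three fields is a format error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets.append(GeneSet(name, desc, frozenset(genes)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")
    return path


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{g}\n" for g in genes))
    return path


def read_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
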