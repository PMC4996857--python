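"""End-to-end orchestration: preprocess -> collapse -> PCA selection ->
stage model -> cross-species comparison -> enrichment, with a manifest.

Two entry points: :func:`run_analysis` composes the whole analysis in memory
(on synthetic data with ground-truth metrics, or on user-supplied tables)
and :func:`run_full` additionally writes every artifact to an output
directory with a content-hash manifest.  :func:`run_benchmark` sweeps a
grid of generator conditions and reports recovery metrics with Monte-Carlo
standard errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .collapse import collapse_by_iqr, collapse_by_mean, compute_probe_iqr
from .containers import ExpressionMatrix, ProbeAnnotation, SampleTable, ValidationError
from .enrich import ora, pathway_network
from .pca import GeneSelection, orient_pc1, pca, select_maturation_genes
from .preprocess import log2_transform, scale_samples
from .simulate import (GroundTruth, SimulationConfig, make_planted_gmt,
                       simulate_human, simulate_mouse_pair)
from .species import (alternative_delta_selection, compute_deltas,
                      consistency_report, delta_correlation, make_delta_table,
                      map_symbols, selection_overlap)
from .stages import stage_means, stage_rank_distribution, stage_regression

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineInputs", "run_analysis", "run_full",
           "run_benchmark"]


@dataclass
class PipelineInputs:
    """Paths to user-supplied inputs for a non-synthetic run."""

    matrix_a: str
    samples_a: str
    matrix_b: str
    samples_b: str
    annotation_a: str | None = None
    annotation_b: str | None = None
    human_matrix: str | None = None
    human_samples: str | None = None
    gmt: str | None = None
    human_group_hi: str = "adult"
    human_group_lo: str = "fetal"


@dataclass
class PipelineConfig:
    """All pipeline parameters; exactly one of ``sim`` / ``inputs`` is used."""

    sim: SimulationConfig | None = None
    inputs: PipelineInputs | None = None
    sd_multiplier: float = 2.0
    q_threshold: float = 0.1
    enrichment_fdr: float = 0.01
    fc_threshold: float = 1.5
    log2_offset: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValidationError("provide exactly one of sim= or inputs=")
        if self.sd_multiplier <= 0:
            raise ValidationError("sd_multiplier must be > 0")
        if not 0 < self.q_threshold < 1:
            raise ValidationError("q_threshold must be in (0, 1)")
        if not 0 < self.enrichment_fdr < 1:
            raise ValidationError("enrichment_fdr must be in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValidationError("fc_threshold must be > 1")


def _ensure_log2(m: ExpressionMatrix, offset: float) -> ExpressionMatrix:
    return m if m.is_log2 else log2_transform(m, offset)


def _gene_level_scaled(
    m: ExpressionMatrix,
    ann: ProbeAnnotation | None,
    method: str,
    funnel: dict,
    tag: str,
) -> tuple[ExpressionMatrix, pd.DataFrame | None]:
    """Scale and (if probe-level) collapse one platform to gene level.

    IQR-based collapsing determines representative probes on the pre-scaling
    log2 values, then carries the scaled rows; mean collapsing averages the
    log2 values before scaling.  Returns the scaled gene-level matrix and
    the probe-IQR audit table (None when no collapsing happened).
    """
    iqr_table = None
    funnel[f"n_features_{tag}"] = m.shape[0]
    if m.feature_kind == "probe":
        if ann is None:
            raise ValidationError(f"platform {tag} is probe-level but has no annotation")
        if method == "iqr":
            iqr_table = compute_probe_iqr(m, ann)
            scaled = scale_samples(m)
            gene = collapse_by_iqr(scaled, iqr_table)
        elif method == "mean":
            gene = collapse_by_mean(m, ann)
        else:
            raise ValidationError(f"unknown collapse method {method!r}")
    else:
        gene = m
    gene = scale_samples(gene)
    funnel[f"n_genes_{tag}"] = gene.shape[0]
    return gene, iqr_table


def run_analysis(config: PipelineConfig) -> dict:
    """Run the full analysis in memory; returns a dict of result objects.

    Keys include ``selection`` (:class:`GeneSelection`), ``loading_table``,
    ``regression``, ``rank_distribution``, ``delta_table``, ``consistency``,
    ``delta_selection``, ``overlap``, ``correlations``, ``enrichment``,
    ``funnel`` and, for synthetic runs, ``truth`` and ``recovery`` metrics.
    """
    config.validate()
    funnel: dict = {}
    truth: GroundTruth | None = None
    gmt_sets = None

    if config.sim is not None:
        sim = config.sim
        (matrix_a, ann_a, matrix_b, samples_a, samples_b, truth) = \
            simulate_mouse_pair(sim)
        human_matrix, human_samples = simulate_human(sim, truth)
        ann_b = None
        gmt_sets = make_planted_gmt(truth, seed=sim.seed)
        group_hi, group_lo = "adult", "fetal"
    else:
        inp = config.inputs
        matrix_a = io.read_expression_matrix(inp.matrix_a)
        samples_a = io.read_sample_table(inp.samples_a)
        matrix_b = io.read_expression_matrix(inp.matrix_b)
        samples_b = io.read_sample_table(inp.samples_b)
        ann_a = io.read_probe_annotation(inp.annotation_a) if inp.annotation_a else None
        ann_b = io.read_probe_annotation(inp.annotation_b) if inp.annotation_b else None
        human_matrix = (io.read_expression_matrix(inp.human_matrix)
                        if inp.human_matrix else None)
        human_samples = (io.read_sample_table(inp.human_samples)
                         if inp.human_samples else None)
        gmt_sets = io.read_gmt(inp.gmt) if inp.gmt else None
        group_hi, group_lo = inp.human_group_hi, inp.human_group_lo

    # --- preprocess + collapse ---------------------------------------------
    matrix_a = _ensure_log2(matrix_a, config.log2_offset)
    matrix_b = _ensure_log2(matrix_b, config.log2_offset)
    gene_a, iqr_table = _gene_level_scaled(matrix_a, ann_a, "iqr", funnel, "a")
    gene_b, _ = _gene_level_scaled(matrix_b, ann_b, "mean", funnel, "b")

    # --- PCA + cross-platform selection ------------------------------------
    n_comp_a = min(2, *gene_a.shape)
    n_comp_b = min(2, *gene_b.shape)
    p_a = orient_pc1(pca(gene_a, n_comp_a), samples_a)
    p_b = orient_pc1(pca(gene_b, n_comp_b), samples_b)
    loading_table, selection = select_maturation_genes(
        p_a, p_b, sd_multiplier=config.sd_multiplier
    )
    shared = set(gene_a.feature_ids) & set(gene_b.feature_ids)
    funnel["n_shared_genes"] = len(shared)
    funnel["n_unique_a"] = gene_a.shape[0] - len(shared)
    funnel["n_unique_b"] = gene_b.shape[0] - len(shared)
    funnel["n_selected"] = len(selection.selected)
    funnel["n_mature"] = len(selection.mature)
    funnel["n_immature"] = len(selection.immature)

    # --- stage trajectory model on platform A ------------------------------
    profiles = stage_means(gene_a, samples_a)
    rank_dist = stage_rank_distribution(profiles)
    regression = stage_regression(profiles, q_threshold=config.q_threshold)
    sel_on_a = sorted(selection.selected & set(regression.index))
    frac_sig = (float(regression.loc[sel_on_a, "significant"].mean())
                if sel_on_a else float("nan"))
    funnel["n_selected_on_a"] = len(sel_on_a)

    results: dict = {
        "selection": selection,
        "loading_table": loading_table,
        "pca_a": p_a,
        "pca_b": p_b,
        "iqr_table": iqr_table,
        "stage_profiles": profiles,
        "rank_distribution": rank_dist,
        "regression": regression,
        "frac_selected_significant": frac_sig,
        "funnel": funnel,
        "truth": truth,
        "gene_a": gene_a,
        "gene_b": gene_b,
        "samples_a": samples_a,
        "samples_b": samples_b,
    }

    # --- cross-species comparison ------------------------------------------
    if human_matrix is not None:
        human_scaled = scale_samples(_ensure_log2(human_matrix, config.log2_offset))
        S = samples_a.n_stages
        delta_h = compute_deltas(human_scaled, human_samples, group_hi,
                                 group_lo, by="group")
        delta_a = compute_deltas(gene_a, samples_a, str(S), "1", by="stage")
        delta_b = compute_deltas(gene_b, samples_b,
                                 str(samples_b.n_stages), "1", by="stage")
        # merged mouse delta: platform A where available, else platform B
        delta_mouse = delta_a.combine_first(delta_b)
        mouse_genes = sorted(set(delta_mouse.index))
        pairs = map_symbols(mouse_genes, human_scaled.feature_ids)
        dtab = make_delta_table(pairs, delta_mouse, delta_h)
        dtab_a = make_delta_table(pairs, delta_a, delta_h)
        dtab_b = make_delta_table(pairs, delta_b, delta_h)
        funnel["n_mapped_genes"] = len(dtab)
        sel_mapped = selection.selected & set(dtab.index)
        funnel["n_selected_mapped"] = len(sel_mapped)

        correlations = {}
        for name, t in (("a", dtab_a), ("b", dtab_b)):
            if len(t) >= 3:
                correlations[f"r_all_{name}"] = delta_correlation(t)
            sub = t.loc[t.index.isin(selection.selected)]
            if len(sub) >= 3:
                correlations[f"r_selected_{name}"] = delta_correlation(
                    t, subset=selection.selected
                )
        consistency = consistency_report(dtab, selection,
                                         fc_threshold=config.fc_threshold)
        delta_sel = alternative_delta_selection(
            dtab, sd_multiplier=config.sd_multiplier
        )
        overlap = selection_overlap(selection, delta_sel)
        funnel["n_consistent_mature"] = consistency.n_consistent_mature
        funnel["n_consistent_immature"] = consistency.n_consistent_immature
        funnel["n_inconsistent"] = consistency.n_inconsistent
        funnel["n_delta_selected"] = len(delta_sel.selected)
        results.update(
            delta_table=dtab, delta_table_a=dtab_a, delta_table_b=dtab_b,
            correlations=correlations, consistency=consistency,
            delta_selection=delta_sel, overlap=overlap,
            human_matrix=human_scaled, human_samples=human_samples,
        )

    # --- enrichment ---------------------------------------------------------
    if gmt_sets is not None:
        universe = sorted(set(gene_a.feature_ids) | set(gene_b.feature_ids))
        enr = {}
        for list_name, genes in (("mature", selection.mature),
                                 ("immature", selection.immature)):
            query = genes & set(universe)
            if not query:
                continue
            rows = ora(query, gmt_sets, universe, fdr=config.enrichment_fdr)
            edges, nodes = pathway_network(rows, gmt_sets, query)
            enr[list_name] = {"table": rows, "edges": edges, "nodes": nodes}
        results["enrichment"] = enr

    # --- recovery metrics against planted truth ----------------------------
    if truth is not None:
        results["recovery"] = _recovery_metrics(selection, truth)
        funnel.update({f"recovery_{k}": v for k, v in results["recovery"].items()
                       if isinstance(v, int)})
    return results


def _recovery_metrics(sel: GeneSelection, truth: GroundTruth) -> dict:
    planted = set(truth.planted)
    selected = sel.selected
    tp = selected & planted
    sens = len(tp) / len(planted) if planted else float("nan")
    prec = len(tp) / len(selected) if selected else float("nan")
    # direction agreement among true positives
    agree = sum(
        1 for g in tp
        if (g in sel.mature) == (truth.direction[g] == +1)
    )
    return {
        "n_planted": len(planted),
        "n_selected": len(selected),
        "n_true_positive": len(tp),
        "sensitivity": sens,
        "precision": prec,
        "direction_agreement": (agree / len(tp)) if tp else float("nan"),
    }


# --------------------------------------------------------------------------
# artifact writing


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the analysis and write every artifact plus ``manifest.json``.

    The manifest records all parameters, the gene-count funnel, and a sha256
    per artifact; two runs with identical config and seed produce
    byte-identical manifests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = run_analysis(config)

    def save_df(df: pd.DataFrame, name: str, **kw) -> None:
        df.to_csv(out / name, sep="\t", float_format="%.10g", **kw)

    save_df(res["loading_table"], "loading_table.tsv")
    io.write_gene_list(sorted(res["selection"].mature), out / "mature.txt")
    io.write_gene_list(sorted(res["selection"].immature), out / "immature.txt")
    prov = pd.DataFrame(
        sorted(res["selection"].provenance.items()),
        columns=["gene", "provenance"],
    )
    save_df(prov, "selection_provenance.tsv", index=False)
    if res["iqr_table"] is not None:
        save_df(res["iqr_table"], "probe_iqr.tsv", index=False)
    save_df(res["stage_profiles"], "stage_profiles.tsv", index_label="gene")
    save_df(res["rank_distribution"], "rank_distribution.tsv")
    save_df(res["regression"], "stage_regression.tsv", index_label="gene")
    if "delta_table" in res:
        save_df(res["delta_table"], "delta_table.tsv", index_label="gene")
        io.write_gene_list(sorted(res["delta_selection"].mature),
                           out / "delta_mature.txt")
        io.write_gene_list(sorted(res["delta_selection"].immature),
                           out / "delta_immature.txt")
    for list_name, bundle in res.get("enrichment", {}).items():
        save_df(bundle["table"], f"enrichment_{list_name}.tsv", index=False)
        save_df(bundle["edges"], f"pathway_edges_{list_name}.tsv", index=False)
        save_df(bundle["nodes"], f"pathway_nodes_{list_name}.tsv", index=False)

    summary: dict = {"funnel": res["funnel"]}
    if "correlations" in res:
        summary["correlations"] = {
            k: round(v, 10) for k, v in res["correlations"].items()
        }
        c = res["consistency"]
        summary["consistency"] = {
            "n_mature_mapped": c.n_mature_mapped,
            "n_immature_mapped": c.n_immature_mapped,
            "n_consistent_mature": c.n_consistent_mature,
            "n_consistent_immature": c.n_consistent_immature,
            "n_inconsistent": c.n_inconsistent,
            "n_inconsistent_above_fc": c.n_inconsistent_above_fc,
        }
        summary["overlap"] = res["overlap"]
    if "recovery" in res:
        summary["recovery"] = {
            k: (round(v, 10) if isinstance(v, float) else v)
            for k, v in res["recovery"].items()
        }
    summary["frac_selected_significant"] = (
        None if np.isnan(res["frac_selected_significant"])
        else round(res["frac_selected_significant"], 10)
    )
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True,
                                                 indent=1) + "\n")

    params = {
        "sd_multiplier": config.sd_multiplier,
        "q_threshold": config.q_threshold,
        "enrichment_fdr": config.enrichment_fdr,
        "fc_threshold": config.fc_threshold,
        "seed": config.seed,
        "sim": config.sim.to_dict() if config.sim else None,
    }
    files = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {"params": params, "funnel": res["funnel"], "files": files}
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    log.info("wrote %d artifacts to %s", len(files), out)
    return manifest


# --------------------------------------------------------------------------
# benchmark grid


def run_benchmark(
    effect_sizes: list[float],
    noise_sds: list[float],
    conserved_fracs: list[float],
    n_seeds: int = 5,
    base: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Sweep generator conditions; per cell report recovery and correlation
    metrics averaged over seeds with Monte-Carlo standard errors."""
    from dataclasses import replace as dc_replace

    base = base or SimulationConfig()
    rows = []
    for eff in effect_sizes:
        for noise in noise_sds:
            for cons in conserved_fracs:
                cell = {"effect_size": eff, "noise_sd": noise,
                        "conserved_frac": cons}
                metrics: dict[str, list[float]] = {
                    "sensitivity": [], "precision": [],
                    "r_all": [], "r_selected": [],
                }
                for s in range(n_seeds):
                    sim = dc_replace(base, effect_size=eff, noise_sd=noise,
                                     conserved_frac=cons, seed=base.seed + s)
                    res = run_analysis(PipelineConfig(sim=sim, seed=sim.seed))
                    rec = res["recovery"]
                    corr = res.get("correlations", {})
                    metrics["sensitivity"].append(rec["sensitivity"])
                    metrics["precision"].append(rec["precision"])
                    metrics["r_all"].append(corr.get("r_all_a", np.nan))
                    metrics["r_selected"].append(corr.get("r_selected_a", np.nan))
                for name, vals in metrics.items():
                    arr = np.asarray(vals, dtype=float)
                    ok = arr[~np.isnan(arr)]
                    cell[name] = float(ok.mean()) if ok.size else float("nan")
                    cell[f"{name}_se"] = (
                        float(ok.std(ddof=1) / np.sqrt(ok.size))
                        if ok.size > 1 else float("nan")
                    )
                rows.append(cell)
    return pd.DataFrame(rows)
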