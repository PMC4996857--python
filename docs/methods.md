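# Methods

This note records the models, conventions, and numerical choices behind
`cardiomat`, and what the synthetic benchmark does and does not establish.

## Data model and preprocessing

An `ExpressionMatrix` is a feature × sample table (probes or genes) with
explicit processing-state flags (`is_log2`, `is_scaled`). Loaders reject
missing values by default (an explicit `missing="drop"` policy removes
affected features instead); orientation is never auto-detected — a
transposed file must be declared, because auto-detection is unsafe when the
gene count is close to the sample count.

Scaling is **per sample column** to mean 0, SD 1 with the n−1 denominator
(so a column (1,2,3) becomes (−1,0,1)). Per-sample scaling makes arrays
comparable across platforms while preserving each gene's across-sample
profile, which is what the PCA-loading magnitudes used in selection depend
on; per-gene scaling would destroy that interpretation. A numerical detail:
after the obvious `(x − mean)/sd` a second center-and-scale pass is applied,
making the output an exact fixed point of the transform; columns whose
spread is at float64 resolution (SD ≤ 1e−13 × column max) are rejected as
constant rather than amplified. Counts-style inputs are handled by
`log2(x + offset)` with a caller-chosen non-negative offset.

## Probe→gene collapsing

Per probe, IQR = 75th − 25th percentile of its log2 signal across samples,
with linear interpolation between order statistics (the percentile
convention matters: IQR of (1,2,3,4) is 1.5). IQRs are computed on
**pre-scaling** log2 values — computing them after per-sample scaling would
distort the ranges the rule exists to compare — and optionally from a
separate reference compendium, mirroring designs where the representative
probe is frozen on reference arrays and applied to working data. Per gene,
the widest-IQR probe is chosen; exact ties go to the lexicographically
smallest probe id. Full dynamic range (max − min) is emitted as an audit
column only, never used for choosing, since it is dominated by single
outlier arrays. Mean-collapsing averages log2 values (arithmetic mean on
the log2 scale, i.e. a geometric mean of intensities), appropriate for
platforms where multi-probeset genes are rare.

## PCA and the selection rule

PCA operates on feature-centered data (each feature centered across
samples) via thin SVD; loading columns are unit-norm, scores are the
centered data projected onto them, and explained variance uses the n−1
denominator. PC1's sign is arbitrary, so it is oriented against the stage
labels: flipped if the mean PC1 score of the highest stage is below that of
the lowest. After orientation, positive loading ⇒ expression increases
with maturation; the upper selection tail is therefore the
mature-associated list. An exact tie of the two stage means leaves the sign
unchanged with a warning.

Selection pools:

* **shared genes** — summed PC1 loadings across the two platforms; because
  loading vectors are unit-norm on each platform, platforms with different
  gene counts contribute comparably without further normalization, and the
  sum is taken raw (no z-scoring of loadings before summation).
* **platform-unique genes** — that platform's unique-gene loadings only,
  not all its genes; the unique pool has its own mean and SD.

In each pool, genes strictly beyond mean ± k·SD (default k = 2, arithmetic
mean, n−1 SD) are selected. A zero-SD pool selects nothing, with a warning.
No distribution is fitted: the 2 SD rule is a quantile convention on an
empirically near-normal loading distribution, and on pure-noise data the
two-sided selected fraction converges to 2·(1−Φ(2)) ≈ 4.55% — a property
the acceptance suite checks in all four pools (shared, both unique pools,
and the delta-sum score below).

## Stage model

Stage means `x_is` are arithmetic means over each stage's samples. Ranking
across stages uses competition ranking ("1, 1, 3"): rank 1 is the lowest
stage mean and ties share the minimum rank, so a constant gene ranks 1 at
every stage. The per-gene regression `x_is = a_i·s + b_i` is fitted by OLS
to the **S coarse-grained means** (s = 1..S), not the per-sample values —
deliberately low-power, but it tests exactly whether the stage trajectory
itself is linear. Two-sided slope p-values use the t distribution with S−2
df; degenerate conventions: constant response → slope 0, p = 1; exact
non-constant linear fit → p = 0. Multiple testing uses Benjamini–Hochberg
q-values over all genes with significance at q < 0.1. BH was chosen over
local-FDR density estimation: the step-up procedure is exact,
assumption-light, and preserves the q < 0.1 decision rule; local-fdr
methods can differ in the reported fraction of significant genes.

## Cross-species comparison

Symbols are paired by case-insensitive identity after uppercasing both
sides (mouse `Myh7` ↔ human `MYH7`); case-variant collisions on one side
collapse to the lexicographically smallest variant, logged. Deltas are mean
differences of scaled log2 expression — adult stage minus earliest
embryonic stage in mouse, adult minus fetal in human; the earliest mouse
stage is the comparator because available human fetal samples correspond to
early gestation. Direction consistency uses strict inequalities (a zero
human delta is inconsistent), and "strong" inconsistency means
|Δ_human| > log2(1.5). The fold-change cut is applied on the log2 scale of
scaled intensities; on scaled units this is a convention rather than a
literal expression ratio, which is why the count is reported but given no
special status. The alternative delta-sum selection applies the same
mean ± 2 SD rule to Δ_mouse + Δ_human over all mapped genes.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) within an
explicit universe (default: all genes on the analyzed platforms after
collapsing), BH q-values across tested sets, significance at FDR < 0.01.
This is a deliberate, documented divergence from tools that use modified
(EASE-style) statistics. Zero-overlap sets are reported, not dropped. The
pathway network has one node per tested set restricted to query genes and
an edge wherever two sets share ≥ 1 query gene, weighted by the count; it
is exported as a plain edge list for standard graph tools. No pathway
collections are bundled (KEGG licensing); any GMT file works.

## Synthetic cohorts

The generator plants exactly the structure the pipeline claims to recover —
and nothing stronger:

* per gene and sample, `x_gj = μ_g + β_g·effect·(s_j − (S+1)/2) +
  batch(g, b_j) + ε`, log2 scale, `ε ~ N(0, noise_sd²)`; the mean is linear
  in ordinal stage because the downstream regression is linear in stage —
  the generator must not bake in anything the pipeline cannot recover, and
  the centering only shifts intercepts;
* batch offsets are additive per (gene, batch) draws (`batch_sd`, default
  0.5); batches cycle within each stage, so batch assignment is balanced
  across stages and batch structure loads on a PC orthogonal to the stage
  trend rather than confounding it;
* per-stage sample counts default to 16/39/26/16/115 (platform A) and
  12/4/2/2/134 (platform B) — the heavily adult-weighted, unbalanced
  profile of a realistic developmental compendium, kept so PCA sample
  weighting is realistic;
* platform A expands a fraction of genes (default 30%) into 2–4 probesets;
  one designated probe carries the full signal, the rest shrink
  signal + batch + noise by 0.3–0.7 (attenuated) or 0.02–0.1 ("dead",
  near-flat), so the designated probe has the widest IQR with
  near-certainty at realistic sample counts — making the IQR rule's choice
  exactly checkable;
* the human-like dataset uppercases the mouse symbols; a configurable
  fraction of planted genes (default 0.9) keeps its full signed
  across-stage shift between the fetal and adult groups, the rest get zero
  shift;
* defaults: 2,000 genes per platform, 80% platform overlap, 10% planted
  (split evenly increasing/decreasing), effect 1.0 log2 units per stage,
  noise SD 1.0, baseline N(8, 1.5²) — magnitudes typical of log2 microarray
  intensities. All randomness flows from one config seed through named
  substreams, so module-level and pipeline-level runs agree bit-for-bit.

What the generator does **not** emulate: probe-level hybridization
chemistry, count overdispersion, platform-specific normalization artifacts,
correlated gene modules, or nonlinear (saturating, switch-like)
trajectories. Passing tests therefore establish that the implementation is
correct and well-calibrated under the stated model — not that the
biological conclusions transfer to any particular real compendium.

## Problem sizes and runtime choices

The test and acceptance runs use desk-scale sizes chosen once: 10,000 genes
× 20 seeds for null calibration of the selection rule, 1,000 genes × 100
replicates for the correlation-improvement check, 2,000 genes for the
default study conditions, and 300–500 genes for end-to-end fixtures. The
analysis drivers use an 800-gene cohort so their artifacts stay small.

## Known limitations

* The regression's 5-point design cannot distinguish monotone-nonlinear
  from linear trajectories with any power; it is a faithfulness choice.
* Symbol-identity ortholog mapping misses true orthologs with diverged
  names and cannot handle one-to-many homology.
* The mean ± 2 SD rule's null rate is calibrated only under approximately
  normal loading distributions; heavy-tailed loadings (e.g. strong outlier
  samples) would change the selected fraction.
* Selection invariance to platform relabeling holds for the shared pool by
  construction; unique pools are platform-specific by design.
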