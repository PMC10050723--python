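"""Outer Monte Carlo loop and cross-split aggregation.

A run repeats the pair -> group -> score -> model chain over
``n_outer_splits`` stratified train/test splits of the samples and then
aggregates: which groups recur across splits (and with what score/rank),
which miRNAs / CpGs / genes they decompose into, per-split rank matrices for
co-occurrence heatmaps, and a Jaccard similarity matrix over the groups'
gene sets.

Under ``leakage_mode="global"`` the t-test filter, pair detection and group
construction are computed once on all samples and shared by every split
(mirroring the original workflow, at the price of test-set leakage into
feature selection); under ``"train_only"`` they are recomputed inside each
split from the training samples alone.
"""

from __future__ import annotations

import dataclasses
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .grouping import Group, build_groups
from .io_config import (
    LabelTable,
    OmicsMatrix,
    RunConfig,
    TrimintError,
    derive_seed,
    logger,
    write_table,
)
from .modeling import PerformanceRow, evaluate_cumulative
from .pairing import detect_pairs
from .preprocess import FilterReport, preprocess_cpg, ttest_filter
from .scoring import ScoredGroup, score_and_rank, stratified_split


@dataclass
class SplitResult:
    """Everything produced by one outer train/test split."""

    split_index: int
    seed: int
    scored_groups: list[ScoredGroup]
    performance: list[PerformanceRow]
    n_pairs: int
    n_groups: int
    train_samples: list[str] = field(default_factory=list)
    test_samples: list[str] = field(default_factory=list)


@dataclass
class AggregateGroupRecord:
    """Per-group statistics over all outer splits."""

    group_name: str
    frequency: int
    average_score: float
    average_rank: float
    associated_genes: set[str]
    n_associated_genes: int
    min_gene_count: int
    max_gene_count: int
    median_gene_count: float
    split_list: list[int]
    rank_list: list[int]


@dataclass
class FeatureAggregateRecord:
    """Per-feature (miRNA / CpG / gene) statistics over all splits.

    ``frequency`` counts splits with at least one containing group;
    ``total_frequency`` counts (split, group) occurrences, so it is always
    >= frequency.  Scores and ranks are occurrence-weighted means.
    """

    feature_id: str
    feature_kind: str
    frequency: int
    total_frequency: int
    average_score: float
    average_rank: float
    associated_ids: dict[str, set[str]]
    group_list: list[str]
    rank_list: list[int]
    split_list: list[int]


@dataclass
class Precomputed:
    """Shared split-independent stage outputs for leakage_mode='global'."""

    A: OmicsMatrix
    B: OmicsMatrix
    C: OmicsMatrix
    groups: list[Group]
    n_pairs: int


@dataclass
class PipelineResult:
    config: RunConfig
    results: list[SplitResult]
    filter_reports: list[FilterReport] = field(default_factory=list)


def _filter_and_group(
    A: OmicsMatrix,
    B: OmicsMatrix,
    C: OmicsMatrix,
    labels: LabelTable,
    cfg: RunConfig,
) -> tuple[list[Group], int]:
    """t-test filter all three omics, then detect pairs and build groups."""
    if cfg.ttest_p_max < 1.0:
        A, _ = ttest_filter(A, labels, cfg.ttest_p_max, cfg.welch)
        B, _ = ttest_filter(B, labels, cfg.ttest_p_max, cfg.welch)
        C, _ = ttest_filter(C, labels, cfg.ttest_p_max, cfg.welch)
    pairs = detect_pairs(A, B, cfg.alpha, cfg.pair_p_max)
    groups = build_groups(pairs, A, B, C, cfg.beta, cfg.use_abs_beta)
    return groups, len(pairs)


def run_split(
    A: OmicsMatrix,
    B: OmicsMatrix,
    C: OmicsMatrix,
    labels: LabelTable,
    cfg: RunConfig,
    split_index: int,
    precomputed: Precomputed | None = None,
) -> SplitResult:
    """Execute one outer split end to end.

    The split's master seed is ``cfg.seed + split_index``; the outer
    partition, the inner scoring partitions and every classifier seed derive
    from it, so a split is reproducible in isolation.  Zero detected groups
    is a legal outcome (empty scored list, no performance rows).
    """
    split_seed = cfg.seed + split_index
    sample_ids = A.sample_ids
    y = labels.vector(sample_ids)
    rng = np.random.default_rng(derive_seed(split_seed, 0))
    tr_idx, te_idx = stratified_split(y, cfg.test_fraction, rng)
    train = [sample_ids[i] for i in tr_idx]
    test = [sample_ids[i] for i in te_idx]

    if cfg.leakage_mode == "train_only":
        sub_labels = labels.subset(train)
        groups, n_pairs = _filter_and_group(
            A.subset_samples(train), B.subset_samples(train), C.subset_samples(train),
            sub_labels, cfg,
        )
    elif precomputed is not None:
        groups, n_pairs = precomputed.groups, precomputed.n_pairs
    else:
        groups, n_pairs = _filter_and_group(A, B, C, labels, cfg)

    if not groups:
        logger.warning("split %d: no groups detected", split_index)
        return SplitResult(split_index, split_seed, [], [], n_pairs, 0, train, test)

    C_train = C.subset_samples(train)
    C_test = C.subset_samples(test)
    scored = score_and_rank(groups, C_train, labels.subset(train), cfg, derive_seed(split_seed, 1))
    performance = evaluate_cumulative(
        scored, C_train, C_test, labels, cfg, derive_seed(split_seed, 2)
    )
    return SplitResult(split_index, split_seed, scored, performance, n_pairs, len(groups), train, test)


def run_pipeline(
    A: OmicsMatrix,
    B: OmicsMatrix,
    C: OmicsMatrix,
    labels: LabelTable,
    cfg: RunConfig,
    blocklists: list[set[str]] | None = None,
    apply_cpg_preprocessing: bool = True,
) -> PipelineResult:
    """Preprocess, then run all outer splits.

    Inputs need not be sample-aligned; alignment to the lexicographic common
    sample order happens first.  CpG preprocessing (missing-fraction filter
    with mean imputation, IQR filter, exclusion lists) can be switched off
    for pre-cleaned matrices.
    """
    from .io_config import align_samples

    (A, B, C), labels = align_samples([A, B, C], labels)
    reports: list[FilterReport] = []
    if apply_cpg_preprocessing:
        B, reports = preprocess_cpg(B, cfg.max_missing_fraction, cfg.min_iqr, blocklists or [])
    precomputed = None
    if cfg.leakage_mode == "global":
        groups, n_pairs = _filter_and_group(A, B, C, labels, cfg)
        precomputed = Precomputed(A, B, C, groups, n_pairs)
    results = [
        run_split(A, B, C, labels, cfg, i, precomputed) for i in range(cfg.n_outer_splits)
    ]
    return PipelineResult(cfg, results, reports)


# ---------------------------------------------------------------------------
# aggregation over splits
# ---------------------------------------------------------------------------


def _occurrences(
    results: list[SplitResult], count_top_k_only: bool = False, top_k: int = 10
) -> list[tuple[int, ScoredGroup]]:
    """Flat (split_index, scored group) occurrence list.

    By default a group counts as detected in a split whenever it appears in
    the split's scored list; ``count_top_k_only`` restricts counting to the
    top_k groups of each split.
    """
    occ = []
    for res in results:
        for sg in res.scored_groups:
            if count_top_k_only and sg.rank > top_k:
                continue
            occ.append((res.split_index, sg))
    return occ


def aggregate_groups(
    results: list[SplitResult],
    min_group_frequency: int = 5,
    count_top_k_only: bool = False,
    top_k: int = 10,
) -> list[AggregateGroupRecord]:
    """Per-group statistics over splits, keeping frequency > min_group_frequency.

    Sorted by frequency descending, then average rank ascending, then name.
    Gene-count summaries are over the per-split gene lists of the group;
    ``associated_genes`` is their union.
    """
    if not results:
        raise TrimintError("aggregate_groups needs at least one split result")
    by_name: dict[str, list[tuple[int, ScoredGroup]]] = {}
    for split_index, sg in _occurrences(results, count_top_k_only, top_k):
        by_name.setdefault(sg.name, []).append((split_index, sg))
    records = []
    for name, occ in by_name.items():
        occ.sort(key=lambda t: t[0])
        freq = len({s for s, _ in occ})
        if freq <= min_group_frequency:
            continue
        sizes = [sg.group.n_genes for _, sg in occ]
        union: set[str] = set().union(*(set(sg.group.gene_ids) for _, sg in occ))
        records.append(
            AggregateGroupRecord(
                group_name=name,
                frequency=freq,
                average_score=float(np.mean([sg.score for _, sg in occ])),
                average_rank=float(np.mean([sg.rank for _, sg in occ])),
                associated_genes=union,
                n_associated_genes=len(union),
                min_gene_count=min(sizes),
                max_gene_count=max(sizes),
                median_gene_count=float(statistics.median(sizes)),
                split_list=[s for s, _ in occ],
                rank_list=[sg.rank for _, sg in occ],
            )
        )
    records.sort(key=lambda r: (-r.frequency, r.average_rank, r.group_name))
    return records


_KIND_TO_COUNTERPARTS = {
    "miRNA": ("CpG", "gene"),
    "CpG": ("miRNA", "gene"),
    "gene": ("miRNA", "CpG"),
}


def _constituents(sg: ScoredGroup, kind: str) -> list[str]:
    if kind == "miRNA":
        return [sg.group.pair.mirna_id]
    if kind == "CpG":
        return [sg.group.pair.cpg_id]
    if kind == "gene":
        return list(sg.group.gene_ids)
    raise TrimintError(f"unknown feature kind {kind!r}")


def aggregate_features(
    results: list[SplitResult],
    kind: str,
    min_group_frequency: int = 5,
    count_top_k_only: bool = False,
    top_k: int = 10,
) -> list[FeatureAggregateRecord]:
    """Decompose frequency-retained groups into per-feature statistics.

    Only groups that themselves pass the frequency filter contribute.  For
    each feature of the requested kind: ``frequency`` distinct splits,
    ``total_frequency`` (split, group) occurrences, occurrence-weighted mean
    score and rank, and the identities of counterpart features it co-occurs
    with.
    """
    retained = {
        r.group_name
        for r in aggregate_groups(results, min_group_frequency, count_top_k_only, top_k)
    }
    acc: dict[str, list[tuple[int, ScoredGroup]]] = {}
    for split_index, sg in _occurrences(results, count_top_k_only, top_k):
        if sg.name not in retained:
            continue
        for fid in _constituents(sg, kind):
            acc.setdefault(fid, []).append((split_index, sg))
    records = []
    for fid, occ in acc.items():
        occ.sort(key=lambda t: (t[0], t[1].rank))
        assoc: dict[str, set[str]] = {k: set() for k in _KIND_TO_COUNTERPARTS[kind]}
        for _, sg in occ:
            for counter in assoc:
                assoc[counter].update(_constituents(sg, counter))
        records.append(
            FeatureAggregateRecord(
                feature_id=fid,
                feature_kind=kind,
                frequency=len({s for s, _ in occ}),
                total_frequency=len(occ),
                average_score=float(np.mean([sg.score for _, sg in occ])),
                average_rank=float(np.mean([sg.rank for _, sg in occ])),
                associated_ids=assoc,
                group_list=[sg.name for _, sg in occ],
                rank_list=[sg.rank for _, sg in occ],
                split_list=[s for s, _ in occ],
            )
        )
    records.sort(key=lambda r: (-r.frequency, r.average_rank, r.feature_id))
    return records


@dataclass
class RankMatrix:
    """Entities x splits best-rank matrix with a clustering order for columns.

    ``matrix`` holds the best (minimum) rank of any containing group per
    split, NaN where the entity was not detected.  ``column_order`` is the
    dendrogram leaf order from average-linkage hierarchical clustering of the
    split columns (Euclidean distance, missing ranks imputed one worse than
    the worst observed rank -- for distances only, the exported matrix keeps
    NaN).
    """

    matrix: pd.DataFrame
    row_average_rank: pd.Series
    column_order: list[int]


def rank_matrix(
    results: list[SplitResult],
    kind: str,
    min_group_frequency: int = 0,
    count_top_k_only: bool = False,
    top_k: int = 10,
) -> RankMatrix:
    """Best rank of each entity (group / miRNA / CpG / gene) per split."""
    split_ids = [r.split_index for r in results]
    cells: dict[str, dict[int, int]] = {}
    retained = None
    if min_group_frequency > 0:
        retained = {
            r.group_name
            for r in aggregate_groups(results, min_group_frequency, count_top_k_only, top_k)
        }
    for split_index, sg in _occurrences(results, count_top_k_only, top_k):
        if retained is not None and sg.name not in retained:
            continue
        ids = [sg.name] if kind == "group" else _constituents(sg, kind)
        for fid in ids:
            row = cells.setdefault(fid, {})
            row[split_index] = min(row.get(split_index, sg.rank), sg.rank)
    mat = pd.DataFrame(
        {s: {fid: cells[fid].get(s, np.nan) for fid in cells} for s in split_ids},
        columns=split_ids,
    )
    if mat.empty:
        return RankMatrix(mat, pd.Series(dtype=float), split_ids)
    avg = mat.mean(axis=1, skipna=True)
    mat = mat.loc[avg.sort_values(kind="stable").index]
    avg = avg.loc[mat.index]
    order = cluster_order(mat.T.to_numpy(dtype=float))
    return RankMatrix(mat, avg, [split_ids[i] for i in order])


def cluster_order(X: np.ndarray, impute_missing: bool = True) -> list[int]:
    """Average-linkage (Euclidean) dendrogram leaf order of the rows of X.

    NaNs are imputed as one worse than the worst observed value, matching the
    convention that a non-detected feature sits just beyond the worst rank.
    """
    if X.shape[0] <= 1:
        return list(range(X.shape[0]))
    X = np.asarray(X, dtype=float).copy()
    if impute_missing and np.isnan(X).any():
        worst = np.nanmax(X) if np.isfinite(np.nanmax(X)) else 0.0
        X[np.isnan(X)] = worst + 1.0
    Z = linkage(X, method="average", metric="euclidean")
    return [int(i) for i in leaves_list(Z)]


def group_similarity(
    agg: list[AggregateGroupRecord],
) -> tuple[pd.DataFrame, list[str]]:
    """Jaccard similarity of the groups' union gene sets, plus a clustering order.

    Entry (i, j) is |genes_i & genes_j| / |genes_i | genes_j|; the diagonal
    is 1.  The companion list is the average-linkage leaf order of the rows.
    """
    if len(agg) < 2:
        raise TrimintError("group_similarity needs at least 2 group records")
    names = [r.group_name for r in agg]
    sets = [r.associated_genes for r in agg]
    m = np.eye(len(agg))
    for i in range(len(agg)):
        for j in range(i + 1, len(agg)):
            union = len(sets[i] | sets[j])
            m[i, j] = m[j, i] = (len(sets[i] & sets[j]) / union) if union else 0.0
    df = pd.DataFrame(m, index=names, columns=names)
    order = cluster_order(m, impute_missing=False)
    return df, [names[i] for i in order]


def gene_frequency_per_group(results: list[SplitResult], group_name: str) -> dict[str, int]:
    """For one group, how many splits each gene was a member in."""
    counts: dict[str, int] = {}
    found = False
    for res in results:
        for sg in res.scored_groups:
            if sg.name == group_name:
                found = True
                for g in sg.group.gene_ids:
                    counts[g] = counts.get(g, 0) + 1
    if not found:
        raise TrimintError(f"group {group_name!r} not detected in any split")
    return counts


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

_METRICS = ("accuracy", "specificity", "sensitivity", "auc")


def performance_table_rows(results: list[SplitResult]) -> list[dict]:
    rows = []
    for res in results:
        for perf in res.performance:
            rows.append(
                {
                    "split": res.split_index,
                    "cumulative_group": perf.cumulative_rank,
                    "n_unique_genes": perf.unique_gene_count,
                    "accuracy": perf.accuracy,
                    "specificity": perf.specificity,
                    "sensitivity": perf.sensitivity,
                    "auc": perf.auc,
                }
            )
    return rows


def performance_summary_rows(results: list[SplitResult]) -> list[dict]:
    """Across-splits summary per k: mean and standard error of each metric.

    The unique-gene column reports the largest union size observed at k over
    the splits, the average-gene column the mean union size.
    """
    per_k: dict[int, list[PerformanceRow]] = {}
    for res in results:
        for perf in res.performance:
            per_k.setdefault(perf.cumulative_rank, []).append(perf)
    rows = []
    for k in sorted(per_k):
        perfs = per_k[k]
        row: dict[str, object] = {
            "cumulative_group": k,
            "n_splits": len(perfs),
            "n_unique_genes": max(p.unique_gene_count for p in perfs),
            "average_gene_count": float(np.mean([p.unique_gene_count for p in perfs])),
        }
        for metric in _METRICS:
            vals = np.array([getattr(p, metric) for p in perfs], dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{metric}_mean"] = float(vals.mean()) if vals.size else float("nan")
            row[f"{metric}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
            )
        rows.append(row)
    return rows


def write_outputs(outdir: str | Path, pipeline_result: PipelineResult) -> None:
    """Write the full set of result tables to ``outdir``.

    Files: performance_table.tsv, performance_summary.tsv,
    significant_groups.tsv, significant_{mirnas,cpgs,genes}.tsv,
    group_similarity.tsv (+ row order), rank_matrix_{groups,mirnas,cpgs,genes}.tsv
    (+ column order files), run_config.yaml, run.log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = pipeline_result.config
    results = pipeline_result.results

    write_table(
        performance_table_rows(results),
        outdir / "performance_table.tsv",
        ["split", "cumulative_group", "n_unique_genes", *_METRICS],
    )
    write_table(
        performance_summary_rows(results),
        outdir / "performance_summary.tsv",
        ["cumulative_group", "n_splits", "n_unique_genes", "average_gene_count"]
        + [f"{m}_{s}" for m in _METRICS for s in ("mean", "se")],
    )

    agg = aggregate_groups(results, cfg.min_group_frequency, cfg.count_top_k_only, cfg.top_k_groups)
    write_table(
        [
            {
                "group": r.group_name,
                "frequency": r.frequency,
                "average_score": r.average_score,
                "average_rank": r.average_rank,
                "n_associated_genes": r.n_associated_genes,
                "associated_genes": sorted(r.associated_genes),
                "min_gene_count": r.min_gene_count,
                "max_gene_count": r.max_gene_count,
                "median_gene_count": r.median_gene_count,
                "split_list": r.split_list,
                "rank_list": r.rank_list,
            }
            for r in agg
        ],
        outdir / "significant_groups.tsv",
        [
            "group", "frequency", "average_score", "average_rank", "n_associated_genes",
            "associated_genes", "min_gene_count", "max_gene_count", "median_gene_count",
            "split_list", "rank_list",
        ],
    )

    kind_to_file = {"miRNA": "significant_mirnas.tsv", "CpG": "significant_cpgs.tsv", "gene": "significant_genes.tsv"}
    for kind, fname in kind_to_file.items():
        feats = aggregate_features(
            results, kind, cfg.min_group_frequency, cfg.count_top_k_only, cfg.top_k_groups
        )
        counters = _KIND_TO_COUNTERPARTS[kind]
        write_table(
            [
                {
                    "feature": r.feature_id,
                    "frequency": r.frequency,
                    "total_frequency": r.total_frequency,
                    "average_score": r.average_score,
                    "average_rank": r.average_rank,
                    f"associated_{counters[0].lower()}s": sorted(r.associated_ids[counters[0]]),
                    f"associated_{counters[1].lower()}s": sorted(r.associated_ids[counters[1]]),
                    "n_groups": len(set(r.group_list)),
                    "group_list": r.group_list,
                    "rank_list": r.rank_list,
                    "split_list": r.split_list,
                }
                for r in feats
            ],
            outdir / fname,
            [
                "feature", "frequency", "total_frequency", "average_score", "average_rank",
                f"associated_{counters[0].lower()}s", f"associated_{counters[1].lower()}s",
                "n_groups", "group_list", "rank_list", "split_list",
            ],
        )

    if len(agg) >= 2:
        sim, order = group_similarity(agg)
        sim.to_csv(outdir / "group_similarity.tsv", sep="\t", float_format="%.6g",
                   index_label="group")
        (outdir / "group_similarity.order.txt").write_text("\n".join(order) + "\n")

    for kind, fname in (
        ("group", "rank_matrix_groups.tsv"),
        ("miRNA", "rank_matrix_mirnas.tsv"),
        ("CpG", "rank_matrix_cpgs.tsv"),
        ("gene", "rank_matrix_genes.tsv"),
    ):
        rm = rank_matrix(results, kind, cfg.min_group_frequency, cfg.count_top_k_only, cfg.top_k_groups)
        out = rm.matrix.copy()
        out.insert(0, "average_rank", rm.row_average_rank)
        out.to_csv(outdir / fname, sep="\t", float_format="%.6g", na_rep="", index_label=kind)
        (outdir / (fname.replace(".tsv", ".column_order.txt"))).write_text(
            "\n".join(str(c) for c in rm.column_order) + "\n"
        )

    cfg.to_yaml(outdir / "run_config.yaml")
    log_lines = [
        f"splits={len(results)}",
        f"splits_with_groups={sum(1 for r in results if r.n_groups > 0)}",
        f"total_group_occurrences={sum(r.n_groups for r in results)}",
        f"significant_groups={len(agg)}",
    ]
    for rep in pipeline_result.filter_reports:
        log_lines.append(
            f"filter[{rep.stage}]: {rep.features_in} -> {rep.features_out}"
            + (f" ({rep.notes})" if rep.notes else "")
        )
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")


def run_and_write(
    A: OmicsMatrix,
    B: OmicsMatrix,
    C: OmicsMatrix,
    labels: LabelTable,
    cfg: RunConfig,
    outdir: str | Path,
    blocklists: list[set[str]] | None = None,
    apply_cpg_preprocessing: bool = True,
) -> PipelineResult:
    """Convenience: run the pipeline and write all output tables."""
    result = run_pipeline(A, B, C, labels, cfg, blocklists, apply_cpg_preprocessing)
    write_outputs(outdir, result)
    return result
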