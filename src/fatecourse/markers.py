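"""Cluster marker-gene detection in two parameterizations.

``markers_pairwise`` tests every cluster against every other cluster per gene
(Welch t-tests on the log-normalized layer) and aggregates by best rank
across the pairwise comparisons, the reporting convention of pairwise
marker tools; the conventional reporting filter is FDR < 0.05 with
|log2 fold change| > 0.5 and a top-20-rank display (dense ranks, so tied
genes at rank <= 20 are all kept).

``markers_onevsrest`` runs Wilcoxon rank-sum tests of each cluster against
all remaining cells, after discarding genes expressed in less than
``min_frac`` of the cluster or with log fold change below ``min_lfc``
(defaults 0.25 / 0.25); BH adjustment is over the genes actually tested.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

__all__ = ["markers_pairwise", "markers_onevsrest", "top_rank_display"]

MIN_CLUSTER_SIZE = 3


def _cluster_groups(clusters: np.ndarray) -> dict:
    groups = {}
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        if idx.size < MIN_CLUSTER_SIZE:
            warnings.warn(f"cluster {c!r} has fewer than {MIN_CLUSTER_SIZE} cells; excluded")
            continue
        groups[c] = idx
    if len(groups) < 2:
        raise ValueError("need at least two clusters with >=3 cells")
    return groups


def _fractions_and_lfc(
    norm: np.ndarray, in_idx: np.ndarray, out_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frac_in = (norm[in_idx] > 0).mean(axis=0)
    frac_out = (norm[out_idx] > 0).mean(axis=0)
    lfc = norm[in_idx].mean(axis=0) - norm[out_idx].mean(axis=0)
    return frac_in, frac_out, lfc


def markers_pairwise(
    norm: np.ndarray,
    clusters: np.ndarray | pd.Series,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster marker table from all pairwise Welch t-tests.

    For each cluster, every gene is tested against each other cluster; the
    gene's p-value is BH-adjusted within each pairwise comparison and its
    rank in the cluster is its best (minimum) rank across comparisons
    (dense-ranked), mirroring pairwise "top" semantics.  Deterministic.
    """
    norm = np.asarray(norm, dtype=float)
    clusters = np.asarray(clusters)
    n_genes = norm.shape[1]
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    groups = _cluster_groups(clusters)
    names = sorted(groups, key=str)
    per_cluster: dict = {}
    for c in names:
        in_idx = groups[c]
        best_rank = np.full(n_genes, np.inf)
        min_p = np.ones(n_genes)
        for other in names:
            if other == c:
                continue
            o_idx = groups[other]
            with np.errstate(invalid="ignore", divide="ignore"):
                stat, p = ttest_ind(norm[in_idx], norm[o_idx], equal_var=False, axis=0)
            p = np.where(np.isfinite(p), p, 1.0)
            # one-sided up-regulation: halve where the cluster mean is higher
            up = norm[in_idx].mean(axis=0) > norm[o_idx].mean(axis=0)
            p_one = np.where(up, p / 2.0, 1.0 - p / 2.0)
            order = np.argsort(p_one, kind="stable")
            ranks = np.empty(n_genes)
            ranks[order] = np.arange(1, n_genes + 1)
            best_rank = np.minimum(best_rank, ranks)
            min_p = np.minimum(min_p, p_one)
        rest_idx = np.concatenate([groups[o] for o in names if o != c])
        frac_in, frac_out, lfc = _fractions_and_lfc(norm, in_idx, rest_idx)
        # Simes-style combination of the pairwise one-sided p-values
        p_comb = np.minimum(min_p * (len(names) - 1), 1.0)
        per_cluster[c] = (p_comb, best_rank, frac_in, frac_out, lfc)
    # BH over the pooled (cluster, gene) family so error control is
    # experiment-wide, not per cluster
    pooled = np.concatenate([per_cluster[c][0] for c in names])
    pooled_adj = multipletests(pooled, method="fdr_bh")[1]
    records = []
    for ci, c in enumerate(names):
        p_comb, best_rank, frac_in, frac_out, lfc = per_cluster[c]
        p_adj = pooled_adj[ci * n_genes : (ci + 1) * n_genes]
        dense = pd.Series(best_rank).rank(method="dense").to_numpy()
        for gi in range(n_genes):
            records.append(
                {
                    "cluster": c,
                    "gene_id": gene_ids[gi],
                    "log_fold_change": lfc[gi],
                    "frac_in": frac_in[gi],
                    "frac_out": frac_out[gi],
                    "p_value": p_comb[gi],
                    "p_adjusted": p_adj[gi],
                    "rank": int(dense[gi]),
                }
            )
    out = pd.DataFrame(records)
    return out.sort_values(["cluster", "rank", "gene_id"], kind="stable").reset_index(drop=True)


def markers_onevsrest(
    norm: np.ndarray,
    clusters: np.ndarray | pd.Series,
    gene_ids: list[str] | None = None,
    min_frac: float = 0.25,
    min_lfc: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers with expression filters.

    Genes expressed in under ``min_frac`` of the cluster or with log2 fold
    change under ``min_lfc`` are excluded before testing; BH adjustment runs
    over the tested genes of each cluster.
    """
    norm = np.asarray(norm, dtype=float)
    clusters = np.asarray(clusters)
    n_genes = norm.shape[1]
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    groups = _cluster_groups(clusters)
    names = sorted(groups, key=str)
    all_idx = np.concatenate([groups[c] for c in names])
    records = []
    for c in names:
        in_idx = groups[c]
        rest_idx = np.setdiff1d(all_idx, in_idx)
        frac_in, frac_out, lfc = _fractions_and_lfc(norm, in_idx, rest_idx)
        testable = (frac_in >= min_frac) & (lfc >= min_lfc)
        pvals = np.full(n_genes, np.nan)
        if testable.any():
            cols = np.flatnonzero(testable)
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = mannwhitneyu(
                    norm[np.ix_(in_idx, cols)],
                    norm[np.ix_(rest_idx, cols)],
                    alternative="greater",
                    axis=0,
                )
            pvals[cols] = p
        p_adj = np.full(n_genes, np.nan)
        if testable.any():
            p_adj[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
        order = np.argsort(np.where(np.isnan(pvals), np.inf, pvals), kind="stable")
        ranks = np.empty(n_genes)
        ranks[order] = np.arange(1, n_genes + 1)
        for gi in range(n_genes):
            records.append(
                {
                    "cluster": c,
                    "gene_id": gene_ids[gi],
                    "log_fold_change": lfc[gi],
                    "frac_in": frac_in[gi],
                    "frac_out": frac_out[gi],
                    "tested": bool(testable[gi]),
                    "p_value": pvals[gi],
                    "p_adjusted": p_adj[gi],
                    "rank": int(ranks[gi]),
                }
            )
    out = pd.DataFrame(records)
    return out.sort_values(["cluster", "rank", "gene_id"], kind="stable").reset_index(drop=True)


def top_rank_display(
    table: pd.DataFrame,
    max_rank: int = 20,
    fdr: float = 0.05,
    min_lfc: float = 0.5,
) -> pd.DataFrame:
    """Reporting filter: adjusted p < ``fdr``, log fold change > ``min_lfc``,
    rank <= ``max_rank`` (dense ranks, so ties at the boundary are all kept)."""
    ok = (
        (table["p_adjusted"] < fdr)
        & (table["log_fold_change"] > min_lfc)
        & (table["rank"] <= max_rank)
    )
    return table.loc[ok.fillna(False)].reset_index(drop=True)
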