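"""QC, normalization, highly-variable genes, PCA and MNN batch correction.

This module produces the batch-corrected principal-component embedding every
downstream stage (label transfer, optimal transport, landscapes) consumes.

Conventions: cells are rows everywhere; counts stay sparse; the normalized
layer is ``log2(count / size_factor + pseudocount)``.  Size factors are
library-size based and centred so their geometric mean is one.  Highly
variable genes are those whose variance sits significantly above a local
mean-variance trend (tricube-weighted linear smoother, span as a fraction of
genes), tested with a scaled chi-square on the variance ratio and
Benjamini-Hochberg corrected.  Batch correction follows the mutual-nearest-
neighbour scheme: per-pair correction vectors between an accumulating
reference and each incoming batch, smoothed over incoming cells with a
Gaussian kernel.  Nothing in this module is stochastic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from scipy.stats import chi2
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .datasets import TimecourseDataset

__all__ = [
    "qc_filter",
    "compute_size_factors",
    "log_normalize",
    "select_hvgs",
    "embed_pca",
    "mnn_correct",
    "Embedding",
    "run_preprocess",
    "own_batch_neighbor_fraction",
]


@dataclass
class Embedding:
    """A cells x components real matrix plus its provenance."""

    coords: np.ndarray
    provenance: str = "pca"  # "pca" | "mnn_corrected"
    genes_used: list[str] = field(default_factory=list)
    explained_variance: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains non-finite entries")


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter(
    ds: TimecourseDataset,
    min_total_counts: int = 10_000,
    max_mito_fraction: float = 0.04,
    mito_gene_prefix: str = "mt-",
) -> tuple[TimecourseDataset, pd.DataFrame]:
    """Remove cells with low total counts or high mitochondrial fraction.

    Returns the filtered dataset and a per-cell report with total counts,
    genes detected, mitochondrial fraction and the pass/fail reason.
    """
    counts = ds.counts
    totals = np.asarray(counts.sum(axis=1)).ravel()
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    gene_ids = ds.gene_table["gene_id"].astype(str)
    mito_mask = gene_ids.str.lower().str.startswith(mito_gene_prefix.lower()).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0,
            np.asarray(counts[:, mito_mask].sum(axis=1)).ravel() / np.maximum(totals, 1),
            0.0,
        )
    reasons = np.full(ds.n_cells, "", dtype=object)
    reasons[mito_frac > max_mito_fraction] = "high_mito"
    reasons[totals < min_total_counts] = "low_counts"
    keep = reasons == ""
    report = pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "total_counts": totals,
            "genes_detected": detected,
            "mito_fraction": mito_frac,
            "pass": keep,
            "reason": reasons,
        }
    )
    if ds.n_cells and not keep.any():
        raise ValueError(
            "QC removed every cell; review min_total_counts/max_mito_fraction "
            f"(medians: total={np.median(totals):.0f}, mito={np.median(mito_frac):.3f})"
        )
    return ds.subset(keep), report


def compute_size_factors(counts: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Library-size factors rescaled to geometric mean one."""
    totals = np.asarray(sp.csr_matrix(counts).sum(axis=1), dtype=float).ravel()
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(f"cells with zero total counts: rows {zero[:10].tolist()}")
    log_t = np.log(totals)
    return np.exp(log_t - log_t.mean())


def log_normalize(
    counts: sp.spmatrix | np.ndarray,
    size_factors: np.ndarray,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """``log2(count / size_factor + pseudocount)`` as a dense cells x genes array."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    dense = np.asarray(sp.csr_matrix(counts).todense(), dtype=float)
    if np.any(dense < 0):
        raise ValueError("counts must be nonnegative")
    sf = np.asarray(size_factors, dtype=float)
    if np.any(sf <= 0):
        raise ValueError("size factors must be positive")
    return np.log2(dense / sf[:, None] + pseudocount)


# ---------------------------------------------------------------------------
# highly variable genes
# ---------------------------------------------------------------------------

def _loess_trend(x: np.ndarray, y: np.ndarray, span: float, robust_iter: int = 2) -> np.ndarray:
    """Tricube-weighted local linear fit of y on x, evaluated at each x.

    ``robust_iter`` bisquare re-weighting passes keep genes far above the
    trend from dragging the trend up toward themselves.
    """
    n = x.size
    # floor of 20 genes keeps the fit from interpolating on small panels
    k = max(20, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    robust = np.ones(n)
    fitted = np.empty(n)
    for it in range(robust_iter + 1):
        for pos in range(n):
            lo = np.clip(pos - k // 2, 0, n - k)
            window = slice(lo, lo + k)
            xw, yw = xs[window], ys[window]
            d = np.abs(xw - xs[pos])
            dmax = d.max()
            w = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
            w = w * robust[window]
            sw = w.sum()
            if sw <= 1e-12:
                fitted[pos] = yw.mean()
                continue
            xm = (w * xw).sum() / sw
            ym = (w * yw).sum() / sw
            sxx = (w * (xw - xm) ** 2).sum()
            slope = (w * (xw - xm) * (yw - ym)).sum() / sxx if sxx > 1e-12 else 0.0
            fitted[pos] = ym + slope * (xs[pos] - xm)
        if it < robust_iter:
            resid = ys - fitted
            s = np.median(np.abs(resid))
            if s <= 1e-12:
                break
            u = resid / (6.0 * s)
            robust = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    out = np.empty(n)
    out[order] = fitted
    return out


def select_hvgs(
    norm: np.ndarray,
    gene_ids: list[str] | None = None,
    trend_span: float = 0.05,
    fdr: float = 0.05,
    min_mean: float = 1e-3,
    blacklist: list[str] | None = None,
) -> pd.DataFrame:
    """Highly variable genes: variance significantly above a local trend.

    Fits a tricube local-linear mean-variance trend, tests each gene's
    variance ratio with a chi-square on ``(n-1) * var / trend`` and BH-adjusts.
    Genes with mean below ``min_mean`` or on the ``blacklist`` are excluded
    before testing, with their reason recorded.
    """
    norm = np.asarray(norm, dtype=float)
    n_cells, n_genes = norm.shape
    if n_genes < 10:
        raise ValueError(f"need at least 10 genes to fit a trend, got {n_genes}")
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    blacklist = set(blacklist or [])
    mean = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1)
    if np.allclose(var, 0):
        warnings.warn("all genes have zero variance; no HVGs selected")
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "mean": mean,
                "variance": var,
                "trend": 0.0,
                "excess": 0.0,
                "p_value": 1.0,
                "p_adjusted": 1.0,
                "selected": False,
                "exclusion_reason": "none",
            }
        )

    exclusion = np.full(n_genes, "none", dtype=object)
    exclusion[mean < min_mean] = "low_mean"
    for i, g in enumerate(gene_ids):
        if g in blacklist:
            exclusion[i] = "blacklist"
    tested = exclusion == "none"

    trend = _loess_trend(mean, var, trend_span)
    trend = np.maximum(trend, 1e-12)
    excess = var - trend
    df = max(n_cells - 1, 1)
    stat = df * var / trend
    pvals = chi2.sf(stat, df)
    p_adj = np.full(n_genes, np.nan)
    if tested.any():
        p_adj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    selected = tested & (p_adj < fdr) & (excess > 0)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean": mean,
            "variance": var,
            "trend": trend,
            "excess": excess,
            "p_value": pvals,
            "p_adjusted": p_adj,
            "selected": selected,
            "exclusion_reason": exclusion,
        }
    )


# ---------------------------------------------------------------------------
# PCA and MNN correction
# ---------------------------------------------------------------------------

def embed_pca(
    norm: np.ndarray,
    gene_mask: np.ndarray | list[str] | None = None,
    n_components: int = 50,
    gene_ids: list[str] | None = None,
) -> Embedding:
    """PCA on the normalized layer restricted to a gene set.

    Components are ordered by decreasing explained variance; the sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    norm = np.asarray(norm, dtype=float)
    if gene_mask is None:
        sub = norm
        used: list[str] = list(gene_ids or [])
    elif isinstance(gene_mask, np.ndarray) and gene_mask.dtype == bool:
        sub = norm[:, gene_mask]
        used = [g for g, m in zip(gene_ids or [], gene_mask) if m]
    else:  # list of gene ids
        if gene_ids is None:
            raise ValueError("gene_ids required when selecting genes by id")
        idx = [gene_ids.index(g) for g in gene_mask]
        sub = norm[:, idx]
        used = list(gene_mask)
    n_cells, n_used = sub.shape
    if n_components > min(n_cells, n_used):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells={n_cells}, genes={n_used})"
        )
    centered = sub - sub.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-|loading| entry positive
    for j in range(n_components):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    coords = u * s
    expl = s**2 / max(n_cells - 1, 1)
    return Embedding(coords=coords, provenance="pca", genes_used=used, explained_variance=expl)


def _mean_pairwise_distance(coords: np.ndarray, cap: int = 500) -> float:
    x = coords if coords.shape[0] <= cap else coords[:: max(1, coords.shape[0] // cap)][:cap]
    d = cdist(x, x)
    return float(d[np.triu_indices_from(d, k=1)].mean()) if x.shape[0] > 1 else 1.0

def _mnn_pairs(ref: np.ndarray, cur: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    nn_ref = NearestNeighbors(n_neighbors=k).fit(ref)
    nn_cur = NearestNeighbors(n_neighbors=k).fit(cur)
    cur_to_ref = nn_ref.kneighbors(cur, return_distance=False)
    ref_to_cur = nn_cur.kneighbors(ref, return_distance=False)
    ref_sets = [set(row) for row in ref_to_cur]
    pairs = [
        (r, c) for c in range(cur.shape[0]) for r in cur_to_ref[c] if c in ref_sets[r]
    ]
    if not pairs:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])


def mnn_correct(
    coords: np.ndarray,
    batches: np.ndarray | pd.Series,
    k_mnn: int = 20,
    sigma: float | None = None,
    merge_order: list | None = None,
    n_refine: int = 15,
) -> Embedding:
    """Mutual-nearest-neighbour batch correction in a shared component space.

    Batches are merged sequentially: the first batch in ``merge_order``
    (default: descending size) is the untouched reference; each incoming batch
    contributes MNN pairs (``k_mnn`` neighbours each way) against the
    accumulated reference, per-pair correction vectors are smoothed over the
    incoming cells with a Gaussian kernel of bandwidth ``sigma`` (default
    0.5 x mean pairwise distance) and applied.  Because pairs found between
    still-separated batches under-estimate the displacement, each merge is
    refined: pairs are recomputed after applying the correction, up to
    ``n_refine`` rounds or until the mean pair vector is negligible (the
    aligned fixed point).  The corrected batch then joins the reference.
    A single batch is returned unchanged.
    """
    coords = np.asarray(coords, dtype=float)
    batches = np.asarray(batches)
    uniq, counts = np.unique(batches, return_counts=True)
    if merge_order is None:
        merge_order = [b for _, b in sorted(zip(-counts, uniq), key=lambda t: (t[0], str(t[1])))]
    else:
        missing = set(uniq) - set(merge_order)
        if missing:
            raise ValueError(f"merge_order missing batches: {sorted(map(str, missing))}")
    corrected = coords.copy()
    if len(uniq) == 1:
        return Embedding(coords=corrected, provenance="mnn_corrected")
    scale = _mean_pairwise_distance(coords)
    if sigma is None:
        sigma = 0.5 * scale
    refine_tol = 2e-3 * scale
    ref_rows = np.flatnonzero(batches == merge_order[0])
    for b in merge_order[1:]:
        cur_rows = np.flatnonzero(batches == b)
        if cur_rows.size == 0:
            continue
        ref = corrected[ref_rows]
        cur = corrected[cur_rows].copy()
        k = min(k_mnn, ref.shape[0], cur.shape[0])
        for round_ in range(max(n_refine, 1)):
            pr, pc = _mnn_pairs(ref, cur, k)
            if pr.size == 0:
                if round_ == 0:
                    raise ValueError(
                        f"no mutual nearest neighbours between reference and batch "
                        f"{b!r}; try a larger k_mnn"
                    )
                break
            pair_vec = ref[pr] - cur[pc]
            if np.linalg.norm(pair_vec.mean(axis=0)) < refine_tol and round_ > 0:
                break
            d2 = cdist(cur, cur[pc], metric="sqeuclidean")
            w = np.exp(-d2 / (2.0 * sigma**2))
            wsum = w.sum(axis=1, keepdims=True)
            # cells far from every pair fall back to their nearest pair's vector
            far = wsum.ravel() < 1e-300
            shift = np.zeros_like(cur)
            ok = ~far
            if ok.any():
                shift[ok] = (w[ok] @ pair_vec) / wsum[ok]
            if far.any():
                nearest_pair = np.argmin(d2[far], axis=1)
                shift[far] = pair_vec[nearest_pair]
            cur = cur + shift
        corrected[cur_rows] = cur
        ref_rows = np.concatenate([ref_rows, cur_rows])
    return Embedding(coords=corrected, provenance="mnn_corrected")


def own_batch_neighbor_fraction(
    coords: np.ndarray, batches: np.ndarray | pd.Series, k: int = 15
) -> np.ndarray:
    """Per-cell fraction of its k nearest neighbours from its own batch
    (mixing diagnostic; chance value is each batch's overall share)."""
    batches = np.asarray(batches)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)[:, 1:]
    return (batches[idx] == batches[:, None]).mean(axis=1)


def default_merge_order(cell_table: pd.DataFrame) -> list:
    """Merge order: ascending earliest time point, then descending batch size."""
    stats = cell_table.groupby("batch_id").agg(
        first_tp=("time_point", "min"), size=("cell_id", "count")
    )
    return stats.sort_values(["first_tp", "size"], ascending=[True, False]).index.tolist()


def run_preprocess(
    ds: TimecourseDataset,
    min_total_counts: int = 0,
    max_mito_fraction: float = 1.0,
    pseudocount: float = 1.0,
    trend_span: float = 0.05,
    fdr: float = 0.05,
    min_mean: float = 1e-3,
    blacklist: list[str] | None = None,
    n_components: int = 50,
    k_mnn: int = 20,
    sigma: float | None = None,
) -> tuple[TimecourseDataset, pd.DataFrame, pd.DataFrame]:
    """QC -> size factors -> log normalization -> HVGs -> PCA -> MNN.

    Returns the dataset with ``normalized`` and (batch-corrected) ``embedding``
    filled in, plus the QC report and the HVG table.  QC thresholds default to
    pass-through here; callers targeting deep-coverage plate data use the
    10,000-count / 4% mitochondrial defaults of :func:`qc_filter` directly.
    """
    ds, qc_report = qc_filter(ds, min_total_counts, max_mito_fraction)
    sf = compute_size_factors(ds.counts)
    norm = log_normalize(ds.counts, sf, pseudocount)
    gene_ids = ds.gene_table["gene_id"].tolist()
    hvg = select_hvgs(norm, gene_ids, trend_span, fdr, min_mean, blacklist)
    mask = hvg["selected"].to_numpy()
    if mask.sum() < n_components:
        # fall back to all tested genes so PCA stays well-posed on tiny data
        mask = (hvg["exclusion_reason"] == "none").to_numpy()
    n_components = min(n_components, ds.n_cells - 1, int(mask.sum()))
    pca = embed_pca(norm, mask, n_components, gene_ids)
    order = default_merge_order(ds.cell_table)
    corrected = mnn_correct(
        pca.coords, ds.cell_table["batch_id"].to_numpy(), k_mnn, sigma, order
    )
    ds.normalized = norm
    ds.embedding = corrected.coords
    ds.attrs["size_factors"] = sf
    ds.attrs["n_hvgs"] = int(hvg["selected"].sum())
    return ds, qc_report, hvg
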