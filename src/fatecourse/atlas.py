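"""Reference-atlas mapping: joint embedding, KNN label transfer, nearest cells.

Query datasets are merged with the reference (shared genes only), normalized
and log-transformed together, re-embedded with HVG selection and PCA on the
merged data, and MNN-rescaled treating the query as the incoming batch;
large queries are split into chunks (default below 10,000 cells) that are
mapped independently and concatenated back in the original cell order.
Annotations transfer as the mode among the k nearest reference neighbours in
the shared space (k chosen per annotation resolution: 30 for coarse stage,
10-15 for cell types), with ties resolved to the nearest neighbour's label
and then lexicographically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .datasets import TimecourseDataset
from .preprocess import (
    compute_size_factors,
    embed_pca,
    log_normalize,
    mnn_correct,
    select_hvgs,
)

__all__ = ["joint_embed", "transfer_labels", "nearest_reference_cells", "map_query"]


def joint_embed(
    reference: TimecourseDataset,
    query: TimecourseDataset,
    n_components: int = 50,
    chunk_size: int = 10_000,
    k_mnn: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Embed reference and query cells in one MNN-rescaled PCA space.

    Returns ``(ref_coords, query_coords)`` with query rows in their original
    order.  Queries above ``chunk_size`` are split into seeded-shuffle
    contiguous chunks, each merged against the reference independently.
    """
    ref_genes = reference.gene_table["gene_id"]
    q_genes = query.gene_table["gene_id"]
    shared = ref_genes[ref_genes.isin(set(q_genes))].tolist()
    if not shared:
        raise ValueError(
            f"no shared genes between reference ({len(ref_genes)}) and query "
            f"({len(q_genes)})"
        )
    ref_cols = pd.Index(ref_genes).get_indexer(shared)
    q_cols = pd.Index(q_genes).get_indexer(shared)
    ref_counts = reference.counts[:, ref_cols]
    q_counts = query.counts[:, q_cols]

    n_query = query.n_cells
    if n_query > chunk_size:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_query)
        chunks = [perm[i : i + chunk_size] for i in range(0, n_query, chunk_size)]
    else:
        chunks = [np.arange(n_query)]

    ref_out: np.ndarray | None = None
    q_out = np.zeros((n_query, 0))
    for chunk in chunks:
        import scipy.sparse as sp

        merged = sp.vstack([ref_counts, q_counts[chunk]]).tocsr()
        sf = compute_size_factors(merged)
        norm = log_normalize(merged, sf)
        hvg = select_hvgs(norm, shared)
        mask = hvg["selected"].to_numpy()
        if mask.sum() < n_components:
            mask = (hvg["exclusion_reason"] == "none").to_numpy()
        ncomp = min(n_components, merged.shape[0] - 1, int(mask.sum()))
        pca = embed_pca(norm, mask, ncomp, shared)
        batches = np.array(
            ["__reference__"] * reference.n_cells + ["__query__"] * chunk.size
        )
        corrected = mnn_correct(
            pca.coords, batches, k_mnn=k_mnn, merge_order=["__reference__", "__query__"]
        )
        if q_out.shape[1] == 0:
            q_out = np.zeros((n_query, corrected.coords.shape[1]))
            ref_out = corrected.coords[: reference.n_cells]
        q_out[chunk] = corrected.coords[reference.n_cells :]
    assert ref_out is not None
    return ref_out, q_out


def transfer_labels(
    ref_emb: np.ndarray,
    ref_labels: np.ndarray | pd.Series,
    query_emb: np.ndarray,
    k: int = 15,
    ref_ids: np.ndarray | None = None,
    query_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mode-of-KNN label transfer with deterministic tie breaking.

    For each query cell the k nearest reference neighbours (Euclidean) vote;
    the assigned label is the mode, ties going to the label of the nearest
    tied neighbour (then lexicographic).  Confidence is mode count over k.
    """
    ref_emb = np.asarray(ref_emb, dtype=float)
    query_emb = np.asarray(query_emb, dtype=float)
    labels = np.asarray(ref_labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ref_emb.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {ref_emb.shape[0]}")
    if ref_ids is None:
        ref_ids = np.arange(ref_emb.shape[0])
    if query_ids is None:
        query_ids = np.arange(query_emb.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(ref_emb)
    dist, idx = nn.kneighbors(query_emb)
    records = []
    for q in range(query_emb.shape[0]):
        neigh_labels = labels[idx[q]]
        vals, counts = np.unique(neigh_labels, return_counts=True)
        top = counts.max()
        tied = set(vals[counts == top])
        if len(tied) == 1:
            assigned = next(iter(tied))
        else:
            # nearest tied neighbour wins; exact distance ties fall back to
            # lexicographic label order
            cand = []
            for lab in tied:
                pos = int(np.argmax(neigh_labels == lab))
                cand.append((float(dist[q, pos]), str(lab), lab))
            assigned = min(cand)[2]
        records.append(
            {
                "cell_id": query_ids[q],
                "assigned_label": assigned,
                "k": k,
                "confidence": top / k,
                "neighbor_counts": {str(v): int(c) for v, c in zip(vals, counts)},
                "nearest_ref_id": ref_ids[idx[q, 0]],
                "nearest_distance": float(dist[q, 0]),
            }
        )
    return pd.DataFrame(records)


def nearest_reference_cells(
    ref_emb: np.ndarray,
    query_emb: np.ndarray,
    ref_ids: np.ndarray | None = None,
    query_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact (brute-force-equivalent) nearest reference cell per query cell."""
    ref_emb = np.asarray(ref_emb, dtype=float)
    query_emb = np.asarray(query_emb, dtype=float)
    if ref_emb.shape[0] == 0:
        raise ValueError("reference embedding is empty")
    if ref_ids is None:
        ref_ids = np.arange(ref_emb.shape[0])
    if query_emb.shape[0] == 0:
        return pd.DataFrame(columns=["cell_id", "nearest_ref_id", "distance"])
    if query_ids is None:
        query_ids = np.arange(query_emb.shape[0])
    nn = NearestNeighbors(n_neighbors=1, algorithm="brute").fit(ref_emb)
    dist, idx = nn.kneighbors(query_emb)
    return pd.DataFrame(
        {
            "cell_id": query_ids,
            "nearest_ref_id": np.asarray(ref_ids)[idx[:, 0]],
            "distance": dist[:, 0],
        }
    )


def map_query(
    reference: TimecourseDataset,
    query: TimecourseDataset,
    label_column: str,
    k: int = 15,
    n_components: int = 50,
    chunk_size: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Joint embedding followed by label transfer from a reference annotation."""
    if label_column not in reference.cell_table.columns:
        raise ValueError(f"reference has no column {label_column!r}")
    ref_emb, q_emb = joint_embed(reference, query, n_components, chunk_size, seed=seed)
    return transfer_labels(
        ref_emb,
        reference.cell_table[label_column].to_numpy(),
        q_emb,
        k=k,
        ref_ids=reference.cell_ids,
        query_ids=query.cell_ids,
    )
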