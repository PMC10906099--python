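"""Fate prediction for query cells and predicted-vs-observed concordance.

A query cell inherits the fate-matrix row of its closest atlas cell and is
predicted the fate of highest probability.  Predictions grouped by region of
origin become a fate-fraction table ("fate plot"): rows are regions, columns
fates, entries the fraction of the region's cells (or embryos, for
microscopically scored tables) assigned each fate.  Concordance between two
such tables is scored per region by cosine similarity and Spearman rank
correlation on the shared fates, contextualized by a seeded region-shuffling
permutation baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .fate import FateMatrix

__all__ = [
    "predict_query_fates",
    "fate_fraction_table",
    "concordance_score",
    "harmonize_fates",
]


def predict_query_fates(transfer: pd.DataFrame, fm: FateMatrix) -> pd.DataFrame:
    """Argmax fate of each query cell's nearest atlas cell.

    ``transfer`` must carry ``cell_id`` and ``nearest_ref_id`` (as produced by
    the atlas-mapping step).  Ties at the argmax go to the lexicographically
    first fate name and are flagged.
    """
    for col in ("cell_id", "nearest_ref_id"):
        if col not in transfer.columns:
            raise ValueError(f"transfer table missing column {col!r}")
    missing = [
        str(c) for c in transfer["nearest_ref_id"] if c not in fm.probs.index
    ]
    if missing:
        raise ValueError(f"nearest atlas cells absent from fate matrix: {missing[:10]}")
    fates = sorted(fm.fate_names)
    rows = fm.probs.loc[transfer["nearest_ref_id"], fates].to_numpy()
    best = rows.argmax(axis=1)  # first (lexicographically first) on ties
    top = rows.max(axis=1)
    tie = (rows == top[:, None]).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "cell_id": transfer["cell_id"].to_numpy(),
            "predicted_fate": [fates[i] for i in best],
            "probability": top,
            "tie": tie,
            "nearest_ref_id": transfer["nearest_ref_id"].to_numpy(),
        }
    )


def fate_fraction_table(
    assignments: pd.DataFrame,
    region_column: str = "region",
    fate_column: str = "predicted_fate",
    basis: str = "cell counts",
) -> pd.DataFrame:
    """Region x fate fraction table; rows sum to one, absent fates zero-filled."""
    for col in (region_column, fate_column):
        if col not in assignments.columns:
            raise ValueError(f"assignments missing column {col!r}")
    counts = (
        assignments.groupby([region_column, fate_column], observed=True)
        .size()
        .unstack(fill_value=0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    empty = counts.sum(axis=1) == 0
    if empty.any():
        import warnings

        warnings.warn(f"dropping empty regions: {counts.index[empty].tolist()}")
        counts = counts.loc[~empty]
    table = counts.div(counts.sum(axis=1), axis=0)
    table.attrs["basis"] = basis
    table.index.name = "region"
    table.columns.name = "fate"
    return table


def harmonize_fates(table: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Rename and merge fate columns via an explicit user-supplied mapping
    (anatomical labels -> transcriptional fate names); never fuzzy."""
    renamed = table.rename(columns=mapping)
    merged = renamed.T.groupby(level=0).sum().T
    return merged.div(merged.sum(axis=1), axis=0)


def concordance_score(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-region cosine and Spearman concordance on the shared fate set.

    Both tables are row-normalized on the shared fates first (observed embryo-
    count tables may be sub-stochastic before this).  The overall score is the
    mean across shared regions; a seeded permutation baseline (observed rows
    shuffled across regions) contextualizes it.  Symmetric in its arguments.
    """
    shared_fates = sorted(set(predicted.columns) & set(observed.columns))
    if len(shared_fates) < 2:
        raise ValueError(
            f"need >=2 shared fates after harmonization, got {shared_fates}"
        )
    shared_regions = sorted(set(predicted.index) & set(observed.index))
    if not shared_regions:
        raise ValueError("no shared regions between the two tables")

    def _norm(tab: pd.DataFrame) -> np.ndarray:
        x = tab.loc[shared_regions, shared_fates].to_numpy(dtype=float)
        s = x.sum(axis=1, keepdims=True)
        return x / np.where(s > 0, s, 1.0)

    P, O = _norm(predicted), _norm(observed)

    def _cos(u: np.ndarray, v: np.ndarray) -> float:
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        return float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else 0.0

    def _rank(u: np.ndarray, v: np.ndarray) -> float:
        if np.std(u) == 0 or np.std(v) == 0:
            return 0.0
        r = spearmanr(u, v).statistic
        return float(r) if np.isfinite(r) else 0.0

    per_region = pd.DataFrame(
        {
            "region": shared_regions,
            "cosine": [_cos(P[i], O[i]) for i in range(len(shared_regions))],
            "spearman": [_rank(P[i], O[i]) for i in range(len(shared_regions))],
        }
    )
    overall_cos = float(per_region["cosine"].mean())
    overall_rank = float(per_region["spearman"].mean())

    rng = np.random.default_rng(seed)
    baseline = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(shared_regions))
        baseline.append(np.mean([_cos(P[i], O[perm[i]]) for i in range(len(perm))]))
    baseline = np.asarray(baseline)
    return {
        "per_region": per_region,
        "overall_cosine": overall_cos,
        "overall_spearman": overall_rank,
        "permutation_mean_cosine": float(baseline.mean()),
        "permutation_p": float((np.sum(baseline >= overall_cos) + 1) / (n_permutations + 1)),
        "shared_fates": shared_fates,
    }
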