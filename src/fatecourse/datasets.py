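"""Core containers: the lineage-tree ground-truth model and the timecourse dataset.

A :class:`LineageTree` is the generative description of a branching
differentiation process: a rooted tree of transcriptional states, each with a
nonnegative per-gene expression program and a strictly positive exponential
growth rate (per day).  Internal states hand their mass to their children at a
fixed branch time; terminal states (leaves) are the fates every analysis
downstream reasons about.

A :class:`TimecourseDataset` holds what a sampled timecourse experiment
provides: a sparse cells x genes integer count matrix, a per-cell metadata
table (time point on a declared grid, batch, anatomical section, optional
state label), a gene table, and optional derived layers (normalized
expression, embedding).  Simulated datasets additionally carry the analytic
terminal-fate probabilities of every cell as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

MANDATORY_CELL_COLUMNS = ("cell_id", "time_point", "batch_id", "section_id")


@dataclass(frozen=True)
class State:
    """One transcriptional state of a lineage tree."""

    state_id: str
    parent_id: Optional[str]
    birth_time: float
    program: np.ndarray  # nonnegative per-gene mean expression


@dataclass
class LineageTree:
    """Rooted branching model of cell states with growth rates.

    Parameters
    ----------
    states
        All states; exactly one has ``parent_id is None`` (the root).
    growth
        Per-state exponential growth rate per day, strictly positive.
    branch_times
        For every non-terminal state, the time its children appear.
    """

    states: list[State]
    growth: dict[str, float]
    branch_times: dict[str, float]

    def __post_init__(self) -> None:
        self._by_id = {s.state_id: s for s in self.states}
        self._children: dict[str, list[str]] = {s.state_id: [] for s in self.states}
        for s in self.states:
            if s.parent_id is not None:
                self._children[s.parent_id].append(s.state_id)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> State:
        return next(s for s in self.states if s.parent_id is None)

    @property
    def terminal_states(self) -> list[str]:
        return sorted(sid for sid, ch in self._children.items() if not ch)

    @property
    def n_genes(self) -> int:
        return int(self.root.program.size)

    def state(self, state_id: str) -> State:
        return self._by_id[state_id]

    def children(self, state_id: str) -> list[str]:
        return sorted(self._children[state_id])

    def end_time(self, state_id: str, horizon: float) -> float:
        """Time a state stops existing: its branch time, or ``horizon`` for leaves."""
        if self._children[state_id]:
            return self.branch_times[state_id]
        return horizon

    def max_branch_time(self) -> float:
        return max(self.branch_times.values(), default=self.root.birth_time)

    def validate(self) -> None:
        roots = [s for s in self.states if s.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        ids = [s.state_id for s in self.states]
        if len(set(ids)) != len(ids):
            raise ValueError("state ids must be unique")
        for s in self.states:
            if s.parent_id is not None:
                parent = self._by_id.get(s.parent_id)
                if parent is None:
                    raise ValueError(f"unknown parent {s.parent_id!r} of {s.state_id!r}")
                if not s.birth_time > parent.birth_time:
                    raise ValueError(
                        f"child {s.state_id!r} born at {s.birth_time} not after "
                        f"parent {parent.state_id!r} born at {parent.birth_time}"
                    )
            if np.any(s.program < 0):
                raise ValueError(f"program of {s.state_id!r} has negative entries")
            g = self.growth.get(s.state_id)
            if g is None or not np.isfinite(g) or g <= 0:
                raise ValueError(f"growth rate of {s.state_id!r} must be finite and > 0")
        for sid, ch in self._children.items():
            if ch and sid not in self.branch_times:
                raise ValueError(f"non-terminal state {sid!r} lacks a branch time")


@dataclass
class TimecourseDataset:
    """Counts plus per-cell/per-gene metadata for a multi-time-point experiment.

    ``cell_table`` must carry ``cell_id``, ``time_point``, ``batch_id`` and
    ``section_id``; ``time_point`` values live on ``time_grid`` (days).
    """

    counts: sp.csr_matrix
    cell_table: pd.DataFrame
    gene_table: pd.DataFrame
    time_grid: list[float]
    normalized: Optional[np.ndarray] = None
    embedding: Optional[np.ndarray] = None
    true_fate_probs: Optional[pd.DataFrame] = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    # -- basic facts -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cell_table["cell_id"].to_numpy()

    @property
    def time_points(self) -> np.ndarray:
        return self.cell_table["time_point"].to_numpy()

    def cells_at(self, time_point: float) -> np.ndarray:
        """Integer indices of cells sampled at ``time_point``."""
        return np.flatnonzero(np.asarray(self.time_points) == time_point)

    def validate(self) -> None:
        n, _ = self.counts.shape
        if len(self.cell_table) != n:
            raise ValueError("cell_table length does not match counts rows")
        if len(self.gene_table) != self.counts.shape[1]:
            raise ValueError("gene_table length does not match counts columns")
        for col in MANDATORY_CELL_COLUMNS:
            if col not in self.cell_table.columns:
                raise ValueError(f"cell_table missing mandatory column {col!r}")
        ids = self.cell_table["cell_id"]
        if ids.duplicated().any():
            raise ValueError("cell_ids must be unique")
        if n:
            data = self.counts.data
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ValueError("counts must be nonnegative integers")
            grid = np.asarray(self.time_grid, dtype=float)
            tps = self.cell_table["time_point"].to_numpy(dtype=float)
            if not np.isin(tps, grid).all():
                off = sorted(set(tps) - set(grid))
                raise ValueError(f"time points {off} not on the declared grid")
        if self.true_fate_probs is not None and len(self.true_fate_probs):
            sums = self.true_fate_probs.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("true fate probability rows must sum to 1")

    def subset(self, mask: np.ndarray) -> "TimecourseDataset":
        """Row-subset every aligned structure; metadata carried forward."""
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return TimecourseDataset(
            counts=self.counts[idx],
            cell_table=self.cell_table.iloc[idx].reset_index(drop=True),
            gene_table=self.gene_table.copy(),
            time_grid=list(self.time_grid),
            normalized=None if self.normalized is None else self.normalized[idx],
            embedding=None if self.embedding is None else self.embedding[idx],
            true_fate_probs=None
            if self.true_fate_probs is None
            else self.true_fate_probs.iloc[idx].reset_index(drop=True),
            attrs=dict(self.attrs),
        )

    def copy(self) -> "TimecourseDataset":
        return self.subset(np.arange(self.n_cells))

    def with_counts(self, counts: sp.spmatrix) -> "TimecourseDataset":
        return replace(self, counts=sp.csr_matrix(counts))

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (counts in X, ground truth in obsm)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_table.set_index("cell_id"),
            var=self.gene_table.set_index("gene_id"),
        )
        if self.normalized is not None:
            adata.layers["lognorm"] = self.normalized.copy()
        if self.embedding is not None:
            adata.obsm["X_corrected"] = self.embedding.copy()
        if self.true_fate_probs is not None:
            adata.obsm["true_fate_probs"] = self.true_fate_probs.to_numpy().copy()
            adata.uns["fate_names"] = list(self.true_fate_probs.columns)
        adata.uns["time_grid"] = list(self.time_grid)
        return adata


def empty_dataset(n_genes: int, time_grid: list[float]) -> TimecourseDataset:
    """A valid dataset with zero cells (schema intact)."""
    return TimecourseDataset(
        counts=sp.csr_matrix((0, n_genes), dtype=np.int64),
        cell_table=pd.DataFrame(
            {c: pd.Series(dtype=object) for c in MANDATORY_CELL_COLUMNS}
        ),
        gene_table=pd.DataFrame({"gene_id": [f"g{i:04d}" for i in range(n_genes)]}),
        time_grid=list(time_grid),
    )
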