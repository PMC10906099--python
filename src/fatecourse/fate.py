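"""Fate matrices, log-odds fate bias, landscape selection, descendant allocation.

A fate matrix is a row-stochastic table of probabilities that each cell's
descendants end in each named terminal population: the row of the composed
transition matrix is summed within each target set, the remainder going to an
implicit "other fate" column.  The fate-bias statistic is the natural log
odds ln(p/(1-p)) of the summed probability p of the fates of interest; cells
above a strict threshold (conventionally 0, relaxed to -0.5 or -1 for
complex landscapes) form the landscape subset.  Descendants of named source
populations are allocated to whichever population pushes the most mass onto
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import TimecourseDataset
from .transport import TransportMap, compose_maps, push

__all__ = [
    "TargetSets",
    "FateMatrix",
    "compute_fate_matrix",
    "log_odds",
    "select_landscape",
    "allocate_descendants",
]

OTHER_FATE = "other_fate"


@dataclass
class TargetSets:
    """Named, disjoint sets of target cell ids at a reference time point."""

    reference_time: float
    sets: dict[str, list]

    def __post_init__(self) -> None:
        seen: set = set()
        for name, ids in self.sets.items():
            if not ids:
                raise ValueError(f"target set {name!r} is empty")
            overlap = seen & set(ids)
            if overlap:
                raise ValueError(
                    f"target sets must be disjoint; {sorted(map(str, overlap))[:5]} reused"
                )
            seen |= set(ids)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class FateMatrix:
    """Cells x (named fates + other_fate) probability table; rows sum to 1."""

    probs: pd.DataFrame  # indexed by cell_id
    reference_time: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.probs.to_numpy()
        if vals.size:
            if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
                raise ValueError("fate probabilities must lie in [0, 1]")
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                worst = float(np.abs(sums - 1).max())
                raise ValueError(f"fate matrix rows must sum to 1 (max deviation {worst:.2e})")

    @property
    def fate_names(self) -> list[str]:
        return list(self.probs.columns)

    def row(self, cell_id) -> pd.Series:
        return self.probs.loc[cell_id]


def compute_fate_matrix(
    ds: TimecourseDataset,
    maps: list[TransportMap],
    targets: TargetSets,
) -> FateMatrix:
    """Fate probabilities for every cell toward each target set.

    ``maps`` chain consecutive time points up to (at least) the reference
    time.  For each earlier time point the maps are composed into a transition
    matrix to the reference time and row-sums are taken within each target
    set; cells at the reference time get indicator rows.
    """
    grid = sorted(set(map(float, ds.time_grid)))
    t_ref = float(targets.reference_time)
    if t_ref not in grid:
        raise ValueError(f"reference time {t_ref} not on the time grid {grid}")
    ref_pos = grid.index(t_ref)
    ref_idx = ds.cells_at(t_ref)
    ref_ids = ds.cell_ids[ref_idx]
    id_to_col = {cid: j for j, cid in enumerate(ref_ids)}
    missing = [
        str(cid) for ids in targets.sets.values() for cid in ids if cid not in id_to_col
    ]
    if missing:
        raise ValueError(
            f"target cell ids absent at reference time {t_ref}: {missing[:10]}"
        )
    names = targets.names
    cols = names + [OTHER_FATE]
    membership = np.zeros((ref_ids.size, len(cols)))
    membership[:, -1] = 1.0
    for k, name in enumerate(names):
        for cid in targets.sets[name]:
            j = id_to_col[cid]
            membership[j, k] = 1.0
            membership[j, -1] = 0.0

    rows, index = [], []
    for pos, t in enumerate(grid[: ref_pos + 1]):
        idx = ds.cells_at(t)
        if idx.size == 0:
            continue
        if pos == ref_pos:
            block = membership
        else:
            chain = maps[pos:ref_pos]
            if not chain or chain[0].gamma.shape[0] != idx.size:
                raise ValueError(
                    f"transport maps do not chain from time {t} to {t_ref}"
                )
            block = compose_maps(chain) @ membership
        rows.append(block)
        index.extend(ds.cell_ids[idx])
    probs = pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="cell_id"), columns=cols)
    # guard accumulated floating error before the strict row-sum contract
    probs = probs.div(probs.to_numpy().sum(axis=1), axis=0)
    return FateMatrix(
        probs=probs,
        reference_time=t_ref,
        provenance={"n_maps": len(maps), "targets": {k: len(v) for k, v in targets.sets.items()}},
    )


def log_odds(
    fm: FateMatrix, fate_subset: list[str], clip: float = 1e-12
) -> pd.Series:
    """Natural-log odds ln(p/(1-p)) of the summed probability of a fate subset.

    p is clipped to [clip, 1-clip] so the statistic stays finite at p in {0,1};
    exactly zero when p = 0.5.
    """
    if not fate_subset:
        raise ValueError("fate_subset must be non-empty")
    if not 0 < clip < 0.5:
        raise ValueError("clip must lie in (0, 0.5)")
    unknown = [f for f in fate_subset if f not in fm.fate_names]
    if unknown:
        raise ValueError(f"unknown fate names: {unknown} (have {fm.fate_names})")
    p = fm.probs[list(fate_subset)].sum(axis=1).clip(clip, 1 - clip)
    out = np.log(p / (1 - p))
    out.name = "log_odds"
    return out


def select_landscape(
    ds: TimecourseDataset,
    lo: pd.Series,
    threshold: float,
    eligible_states: list[str] | None = None,
) -> tuple[np.ndarray, TimecourseDataset]:
    """Strict-inequality mask ``log_odds > threshold`` plus the subset dataset.

    ``eligible_states`` optionally restricts the selection to cells whose
    ``state_label`` annotation is listed (e.g. pluripotent and mesodermal
    states only).  The subset carries all metadata forward; re-deriving HVGs
    and a corrected embedding on it is the caller's next step.
    """
    lo_vals = lo.reindex(ds.cell_ids).to_numpy()
    mask = lo_vals > threshold
    if eligible_states is not None:
        if "state_label" not in ds.cell_table.columns:
            raise ValueError("dataset has no state_label column to restrict on")
        mask &= ds.cell_table["state_label"].isin(eligible_states).to_numpy()
    if not mask.any():
        raise ValueError(
            f"no cells exceed log-odds threshold {threshold}; try a lower threshold"
        )
    return mask, ds.subset(mask)


def allocate_descendants(
    ds: TimecourseDataset,
    maps: list[TransportMap],
    source_populations: dict[str, list],
    source_time: float,
    later_times: list[float],
    normalize_populations: bool = False,
) -> pd.DataFrame:
    """Assign every cell at each later time to the source population pushing
    maximal mass onto it.

    Each population's indicator distribution at ``source_time`` is pushed
    forward through the coupling chain to each later time; a later cell is
    assigned the population with the largest pushed mass, ties broken to the
    lexicographically first name and flagged.  With
    ``normalize_populations=True`` each population's pushed mass is divided by
    its size first.
    """
    grid = sorted(set(map(float, ds.time_grid)))
    t0 = float(source_time)
    if t0 not in grid:
        raise ValueError(f"source time {t0} not on grid")
    pos0 = grid.index(t0)
    src_idx = ds.cells_at(t0)
    src_ids = list(ds.cell_ids[src_idx])
    id_to_row = {cid: i for i, cid in enumerate(src_ids)}
    names = sorted(source_populations)
    indicators = {}
    for name in names:
        ids = source_populations[name]
        if not ids:
            raise ValueError(f"source population {name!r} is empty")
        vec = np.zeros(len(src_ids))
        for cid in ids:
            if cid not in id_to_row:
                raise ValueError(f"cell {cid!r} not present at time {t0}")
            vec[id_to_row[cid]] = 1.0
        indicators[name] = vec / vec.sum()

    records = []
    for t in sorted(map(float, later_times)):
        if t not in grid or t <= t0:
            raise ValueError(f"later time {t} not after {t0} on the grid")
        pos = grid.index(t)
        chain = maps[pos0:pos]
        masses = np.stack(
            [
                push(indicators[n], chain, "forward")
                * (1.0 / len(source_populations[n]) if normalize_populations else 1.0)
                for n in names
            ]
        )  # populations x later cells
        best = masses.argmax(axis=0)
        top = masses.max(axis=0)
        tie = (masses == top[None, :]).sum(axis=0) > 1
        # argmax returns the first (lexicographically first name) on ties
        ids_t = ds.cell_ids[ds.cells_at(t)]
        for j, cid in enumerate(ids_t):
            records.append(
                {
                    "cell_id": cid,
                    "time_point": t,
                    "assigned_population": names[best[j]],
                    "mass": top[j],
                    "tie": bool(tie[j]),
                }
            )
    return pd.DataFrame(records)
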