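"""Synthetic branching-differentiation timecourses with analytic ground truth.

The generator emulates the statistical structure a timecourse fate-inference
analysis assumes: a rooted tree of transcriptional states sampled at fixed
intervals, per-state exponential growth (so branches expand at different
rates), continuous within-branch drift of the expression program, negative-
binomial count noise, batch structure with optional injected shifts, and
anatomical section labels assigned per terminal-lineage subtree.

Ground truth comes from the multi-type branching process itself: a cell in
state ``s`` at time ``t`` will leave descendant mass in each terminal state in
proportion to exponentially grown, branch-split expected counts, which this
module computes in closed form (:func:`terminal_fate_probabilities`) and which
tests cross-check against direct numerical integration of the growth
equations.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import LineageTree, State, TimecourseDataset, empty_dataset

__all__ = [
    "build_lineage_tree",
    "simulate_timecourse",
    "inject_batch_effect",
    "terminal_fate_probabilities",
    "state_occupancy",
    "write_fixture",
    "read_fixture",
]


def build_lineage_tree(
    n_states: int,
    n_genes: int = 100,
    depth: int = 2,
    seed: int = 0,
    span: float = 3.0,
    growth_range: tuple[float, float] = (0.7, 2.0),
    program_scale: float = 20.0,
    divergence: float = 0.25,
) -> LineageTree:
    """Construct a random rooted lineage tree.

    States are added by repeatedly splitting a leaf (breadth-first, capped at
    ``depth`` levels) until ``n_states`` states exist; level ``l`` states are
    born at ``l * span / depth`` days.  Each child's expression program is its
    parent's with a random ``divergence`` fraction of genes redrawn, so sibling
    programs differ in well over 10% of genes.  Growth rates are drawn
    uniformly from ``growth_range`` (per day).  Deterministic given ``seed``.
    """
    if n_states < 2:
        raise ValueError(
            f"n_states={n_states}: at least 2 states are needed to form a branching tree"
        )
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    level_dt = span / depth

    def draw_program() -> np.ndarray:
        return rng.gamma(shape=2.0, scale=program_scale / 2.0, size=n_genes)

    root = State("s0", None, 0.0, draw_program())
    states = [root]
    levels = {"s0": 0}
    growth = {"s0": float(rng.uniform(*growth_range))}
    branch_times: dict[str, float] = {}
    # leaves eligible for splitting, kept in breadth-first order
    frontier = ["s0"]
    counter = 1
    while len(states) < n_states:
        frontier = [sid for sid in frontier if levels[sid] < depth]
        if not frontier:
            raise ValueError(
                f"cannot place {n_states} states within depth {depth}; increase depth"
            )
        parent_id = frontier.pop(0)
        parent = next(s for s in states if s.state_id == parent_id)
        level = levels[parent_id] + 1
        birth = level * level_dt
        branch_times[parent_id] = birth
        n_children = min(2, n_states - len(states))
        for _ in range(n_children):
            prog = parent.program.copy()
            flip = rng.random(n_genes) < divergence
            if not flip.any():  # guarantee sibling divergence even at tiny n_genes
                flip[rng.integers(n_genes)] = True
            prog[flip] = rng.gamma(shape=2.0, scale=program_scale / 2.0, size=int(flip.sum()))
            sid = f"s{counter}"
            counter += 1
            states.append(State(sid, parent_id, birth, prog))
            levels[sid] = level
            growth[sid] = float(rng.uniform(*growth_range))
            frontier.append(sid)
    return LineageTree(states=states, growth=growth, branch_times=branch_times)


# ---------------------------------------------------------------------------
# branching-process analytics
# ---------------------------------------------------------------------------

def _expected_terminal_mass(tree: LineageTree, state_id: str, t: float, horizon: float) -> dict[str, float]:
    """Expected descendant mass per terminal state at ``horizon`` for a unit
    cell sitting in ``state_id`` at time ``t``.

    Mass grows as ``exp(g dt)`` within a state and splits equally among
    children at the branch time (each lineage commits to one child with equal
    probability; differential growth afterwards is what skews fates).
    """
    g = tree.growth[state_id]
    children = tree.children(state_id)
    if not children:
        return {state_id: float(np.exp(g * (horizon - t)))}
    b = tree.branch_times[state_id]
    grow = float(np.exp(g * (b - t)))
    out: dict[str, float] = {}
    w = 1.0 / len(children)
    for c in children:
        for fate, m in _expected_terminal_mass(tree, c, b, horizon).items():
            out[fate] = out.get(fate, 0.0) + w * grow * m
    return out


def terminal_fate_probabilities(
    tree: LineageTree, state_id: str, t: float, horizon: float
) -> pd.Series:
    """Probability that a cell in ``state_id`` at time ``t`` ends in each
    terminal state, measured as its share of expected descendant mass at
    ``horizon`` (at least the last branch time)."""
    horizon = max(horizon, tree.max_branch_time())
    mass = _expected_terminal_mass(tree, state_id, t, horizon)
    fates = tree.terminal_states
    v = np.array([mass.get(f, 0.0) for f in fates])
    return pd.Series(v / v.sum(), index=fates)


def state_occupancy(tree: LineageTree, t: float, horizon: float) -> pd.Series:
    """Expected population share of each state alive at time ``t``.

    Forward propagation of mass: the root starts with unit mass at its birth;
    within a state mass grows exponentially; at a branch time the state's mass
    splits equally among children.
    """
    root = tree.root
    if t < root.birth_time:
        raise ValueError(f"time {t} precedes root birth {root.birth_time}")
    mass_in: dict[str, float] = {root.state_id: 1.0}
    occ: dict[str, float] = {}
    stack = [root.state_id]
    while stack:
        sid = stack.pop()
        s = tree.state(sid)
        g = tree.growth[sid]
        end = tree.end_time(sid, horizon=max(horizon, t))
        children = tree.children(sid)
        alive_until = end if children else np.inf
        if s.birth_time <= t < alive_until or (not children and s.birth_time <= t):
            occ[sid] = mass_in[sid] * float(np.exp(g * (t - s.birth_time)))
        if children and tree.branch_times[sid] <= t:
            b = tree.branch_times[sid]
            out = mass_in[sid] * float(np.exp(g * (b - s.birth_time)))
            for c in children:
                mass_in[c] = out / len(children)
                stack.append(c)
    ser = pd.Series(occ).sort_index()
    return ser / ser.sum()


def _section_map(tree: LineageTree) -> dict[str, str]:
    """Assign each state a section label from its depth-1 ancestor's subtree,
    mimicking anatomical sub-dissection of the major lineages."""
    root_id = tree.root.state_id
    top = tree.children(root_id)
    section = {root_id: "sec_root"}
    for i, t in enumerate(top):
        label = f"sec_{chr(ord('A') + i)}"
        stack = [t]
        while stack:
            sid = stack.pop()
            section[sid] = label
            stack.extend(tree.children(sid))
    return section


def _latent_mean(tree: LineageTree, state_id: str, t: float, horizon: float) -> np.ndarray:
    """Within-branch drift: linear interpolation from the parent's program to
    the state's own program across the state's lifetime."""
    s = tree.state(state_id)
    if s.parent_id is None:
        return s.program
    start = s.birth_time
    end = tree.end_time(state_id, horizon)
    alpha = 1.0 if end <= start else float(np.clip((t - start) / (end - start), 0.0, 1.0))
    parent = tree.state(s.parent_id).program
    return (1.0 - alpha) * parent + alpha * s.program


def simulate_timecourse(
    tree: LineageTree,
    time_grid: list[float],
    cells_per_timepoint: int,
    count_depth: int = 2000,
    dispersion: float = 0.15,
    n_batches: int = 2,
    seed: int = 0,
    section_map: dict[str, str] | None = None,
) -> TimecourseDataset:
    """Sample a timecourse dataset from the branching process.

    At each grid time, cells are assigned latent states with probability
    proportional to the growth-weighted branch mass (:func:`state_occupancy`);
    expression is drawn as negative-binomial counts (variance
    ``mu + dispersion * mu^2``) around the drifting state program scaled to
    ``count_depth`` total counts.  Each cell's terminal-fate probabilities are
    filled in analytically.  Deterministic given ``seed``.
    """
    grid = [float(t) for t in time_grid]
    if any(b >= a for a, b in zip(grid[1:], grid[:-1])):
        raise ValueError("time_grid must be strictly increasing")
    if grid[0] < tree.root.birth_time:
        raise ValueError(
            f"time_grid starts at {grid[0]}, before the root state is born "
            f"({tree.root.birth_time})"
        )
    if count_depth <= 0:
        raise ValueError("count_depth must be positive")
    if cells_per_timepoint == 0:
        return empty_dataset(tree.n_genes, grid)
    if cells_per_timepoint < 0:
        raise ValueError("cells_per_timepoint must be >= 0")

    rng = np.random.default_rng(seed)
    horizon = max(grid[-1], tree.max_branch_time())
    sections = dict(section_map) if section_map else _section_map(tree)
    fates = tree.terminal_states

    rows, cells, fate_rows = [], [], []
    for t in grid:
        occ = state_occupancy(tree, t, horizon)
        means = {
            sid: (lambda m: m / m.sum() * count_depth)(_latent_mean(tree, sid, t, horizon))
            for sid in occ.index
        }
        fate_by_state = {
            sid: terminal_fate_probabilities(tree, sid, t, horizon).to_numpy()
            for sid in occ.index
        }
        assignment = rng.choice(len(occ), size=cells_per_timepoint, p=occ.to_numpy())
        batch = rng.integers(n_batches, size=cells_per_timepoint)
        for i, a in enumerate(assignment):
            sid = occ.index[a]
            mu = means[sid]
            if dispersion > 0:
                lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            else:
                lam = mu
            rows.append(rng.poisson(lam))
            cells.append(
                {
                    "cell_id": f"c_t{t:g}_{i:05d}",
                    "time_point": t,
                    "batch_id": f"b{batch[i]}",
                    "section_id": sections.get(sid, "sec_root"),
                    "state_label": sid,
                }
            )
            fate_rows.append(fate_by_state[sid])

    counts = sp.csr_matrix(np.vstack(rows).astype(np.int64))
    cell_table = pd.DataFrame(cells)
    gene_table = pd.DataFrame({"gene_id": [f"g{i:04d}" for i in range(tree.n_genes)]})
    fate_df = pd.DataFrame(np.vstack(fate_rows), columns=fates)
    fate_df = fate_df.div(fate_df.sum(axis=1), axis=0)  # guard rounding
    return TimecourseDataset(
        counts=counts,
        cell_table=cell_table,
        gene_table=gene_table,
        time_grid=grid,
        true_fate_probs=fate_df,
        attrs={"count_depth": count_depth, "dispersion": dispersion, "seed": seed},
    )


def inject_batch_effect(
    ds: TimecourseDataset, magnitude: float, seed: int = 0
) -> TimecourseDataset:
    """Add a batch-specific per-gene multiplicative offset (log2 scale).

    The first batch (lexicographically) is the untouched reference; every
    other batch ``b`` gets a per-gene offset drawn from ``N(0, magnitude^2)``
    on the log2 scale, applied multiplicatively and re-rounded to integer
    counts.  The offsets are stored in ``attrs['batch_offsets']`` so the
    correction can be checked against them.  ``magnitude=0`` is the identity.
    """
    batches = sorted(ds.cell_table["batch_id"].unique())
    if len(batches) < 2:
        warnings.warn("single batch present: inject_batch_effect is a no-op")
        return ds.copy()
    if magnitude == 0:
        out = ds.copy()
        out.attrs["batch_offsets"] = {b: np.zeros(ds.n_genes) for b in batches}
        return out
    rng = np.random.default_rng(seed)
    dense = ds.counts.toarray().astype(float)
    offsets: dict[str, np.ndarray] = {batches[0]: np.zeros(ds.n_genes)}
    for b in batches[1:]:
        delta = rng.normal(0.0, magnitude, size=ds.n_genes)
        offsets[b] = delta
        mask = (ds.cell_table["batch_id"] == b).to_numpy()
        dense[mask] *= np.exp2(delta)[None, :]
    out = ds.with_counts(sp.csr_matrix(np.rint(dense).astype(np.int64)))
    out.attrs = dict(ds.attrs)
    out.attrs["batch_offsets"] = offsets
    return out


# ---------------------------------------------------------------------------
# fixture I/O: Matrix Market counts + TSV tables + JSON ground-truth sidecar
# ---------------------------------------------------------------------------

def write_fixture(ds: TimecourseDataset, path: str | Path) -> dict[str, Path]:
    """Write ``counts.mtx``, ``cells.tsv``, ``genes.tsv`` and a JSON sidecar
    (time grid, attrs, ground-truth fate probabilities) under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "counts": path / "counts.mtx",
        "cells": path / "cells.tsv",
        "genes": path / "genes.tsv",
        "sidecar": path / "ground_truth.json",
    }
    from scipy.io import mmwrite

    mmwrite(files["counts"], sp.coo_matrix(ds.counts), field="integer")
    ds.cell_table.to_csv(files["cells"], sep="\t", index=False)
    ds.gene_table.to_csv(files["genes"], sep="\t", index=False)
    sidecar = {
        "time_grid": list(map(float, ds.time_grid)),
        "attrs": {
            k: v for k, v in ds.attrs.items() if isinstance(v, (int, float, str, bool))
        },
    }
    if ds.true_fate_probs is not None:
        sidecar["fate_names"] = list(ds.true_fate_probs.columns)
        sidecar["fate_probs"] = ds.true_fate_probs.to_numpy().tolist()
    if "batch_offsets" in ds.attrs:
        sidecar["batch_offsets"] = {
            b: np.asarray(v).tolist() for b, v in ds.attrs["batch_offsets"].items()
        }
    files["sidecar"].write_text(json.dumps(sidecar))
    return files


def read_fixture(path: str | Path) -> TimecourseDataset:
    """Read a dataset written by :func:`write_fixture`; the sidecar is optional
    (ground truth is simply absent without it)."""
    from scipy.io import mmread

    path = Path(path)

    def resolve(stem: str) -> Path:
        for cand in (path / stem, path / f"{stem}.gz"):
            if cand.exists():
                return cand
        raise FileNotFoundError(f"{stem}(.gz) not found under {path}")

    mtx = resolve("counts.mtx")
    try:
        counts = sp.csr_matrix(mmread(mtx))
    except ValueError as e:
        raise ValueError(f"malformed Matrix Market file {mtx}: {e}") from e
    cell_table = pd.read_csv(resolve("cells.tsv"), sep="\t")
    gene_table = pd.read_csv(resolve("genes.tsv"), sep="\t")
    sidecar_path = path / "ground_truth.json"
    time_grid = sorted(cell_table["time_point"].unique().tolist()) if len(cell_table) else []
    fate_probs = None
    attrs: dict = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        time_grid = sidecar.get("time_grid", time_grid)
        attrs = dict(sidecar.get("attrs", {}))
        if "fate_probs" in sidecar:
            fate_probs = pd.DataFrame(
                np.asarray(sidecar["fate_probs"]), columns=sidecar["fate_names"]
            )
        if "batch_offsets" in sidecar:
            attrs["batch_offsets"] = {
                b: np.asarray(v) for b, v in sidecar["batch_offsets"].items()
            }
    return TimecourseDataset(
        counts=counts.astype(np.int64),
        cell_table=cell_table,
        gene_table=gene_table,
        time_grid=[float(t) for t in time_grid],
        true_fate_probs=fate_probs,
        attrs=attrs,
    )
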