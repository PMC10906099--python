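"""Unbalanced entropic optimal transport between consecutive time points.

The coupling gamma between cells at time t (marginal ``a``) and time t+dt
(marginal ``b``) minimizes

    <gamma, C> + eps * KL(gamma || a x b)
      + lambda_s * KL(gamma 1 || a) + lambda_t * KL(gamma^T 1 || b)

where C is squared Euclidean distance in the batch-corrected principal-
component space.  The solver runs entirely in the log domain: with potentials
f, g and gamma_ij = exp((f_i + g_j - C_ij)/eps), the alternating updates are

    f_i <- tau_s * eps * (log a_i - logsumexp_j((g_j - C_ij)/eps)),
    g_j <- tau_t * eps * (log b_i - logsumexp_i((f_i - C_ij)/eps)),

with tau = lambda/(lambda+eps) (tau = 1 recovers hard marginal constraints).
Growth is learned iteratively: source weights are set proportional to
``g_i^dt``, the coupling is solved, and each cell's growth is re-estimated
from its realized row mass; by default three such iterations are run.

Couplings are composed by row-normalizing each map into a transition matrix
and multiplying left to right; distributions are pushed forward through the
row-normalized chain and pulled backward through the column-normalized chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .datasets import TimecourseDataset

__all__ = [
    "TransportConfig",
    "GrowthRates",
    "TransportMap",
    "collapse_timepoints",
    "cost_matrix",
    "unbalanced_sinkhorn",
    "learn_growth_rates",
    "compose_maps",
    "push",
]


@dataclass(frozen=True)
class TransportConfig:
    """Solver settings; ``lambda_* = inf`` means a hard marginal constraint."""

    epsilon: float = 0.05
    lambda_source: float = 1.0
    lambda_target: float = 50.0
    max_iterations: int = 5000
    tolerance: float = 1e-8
    growth_iterations: int = 3
    normalize_cost: bool = True  # divide cost by its median for a scale-free epsilon

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.growth_iterations < 0:
            raise ValueError("growth_iterations must be >= 0")


@dataclass
class GrowthRates:
    """Per-source-cell proliferation rate (per day) over an interval of length dt."""

    rates: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.dt <= 0:
            raise ValueError("interval length dt must be positive")
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates <= 0):
            raise ValueError("growth rates must be finite and strictly positive")


@dataclass
class TransportMap:
    """A coupling between source cells (time t) and target cells (time t+dt)."""

    gamma: np.ndarray
    source_ids: np.ndarray
    target_ids: np.ndarray
    config: TransportConfig
    growth: GrowthRates | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(self.gamma < 0):
            raise ValueError("coupling must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.gamma.shape

    def transition_matrix(self) -> np.ndarray:
        """Row-normalized coupling: P(target j | source i)."""
        rs = self.gamma.sum(axis=1, keepdims=True)
        return self.gamma / np.where(rs > 0, rs, 1.0)

    def pullback_matrix(self) -> np.ndarray:
        """Column-normalized coupling: P(source i | target j), transposed to rows."""
        cs = self.gamma.sum(axis=0, keepdims=True)
        return (self.gamma / np.where(cs > 0, cs, 1.0)).T


def collapse_timepoints(
    ds: TimecourseDataset, groups: dict[float, float]
) -> TimecourseDataset:
    """Relabel time points (e.g. merge two adjacent stages into one).

    ``groups`` maps original time points to their merged value; counts are
    untouched.  Merging non-adjacent time points is allowed but logged.
    """
    if not groups:
        return ds.copy()
    present = set(map(float, ds.time_grid))
    unknown = sorted(set(map(float, groups)) - present)
    if unknown:
        raise ValueError(f"groups refer to absent time points: {unknown}")
    grid = sorted(ds.time_grid)
    by_target: dict[float, list[float]] = {}
    for src, dst in groups.items():
        by_target.setdefault(float(dst), []).append(float(src))
    for dst, srcs in by_target.items():
        pos = sorted(grid.index(s) for s in srcs)
        if pos and pos[-1] - pos[0] != len(pos) - 1:
            warnings.warn(f"collapsing non-adjacent time points {sorted(srcs)} -> {dst}")
    out = ds.copy()
    tps = out.cell_table["time_point"].astype(float).replace(
        {float(k): float(v) for k, v in groups.items()}
    )
    out.cell_table["time_point"] = tps
    new_grid = sorted({float(groups.get(t, t)) for t in ds.time_grid})
    out.time_grid = new_grid
    return out


def cost_matrix(
    emb_source: np.ndarray, emb_target: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Squared Euclidean distances, optionally divided by the median
    (scale-free epsilon)."""
    a = np.asarray(emb_source, dtype=float)
    b = np.asarray(emb_target, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"component dimension mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    sq = (
        (a**2).sum(axis=1)[:, None]
        + (b**2).sum(axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    np.maximum(sq, 0.0, out=sq)
    if normalize:
        med = np.median(sq)
        if med > 0:
            sq = sq / med
    return sq


def unbalanced_sinkhorn(
    cost: np.ndarray,
    source_weights: np.ndarray,
    target_weights: np.ndarray,
    config: TransportConfig | None = None,
    source_ids: np.ndarray | None = None,
    target_ids: np.ndarray | None = None,
) -> TransportMap:
    """Solve the (un)balanced entropic transport problem by log-domain scaling.

    Fully deterministic.  Non-convergence within ``max_iterations`` returns
    the current iterate flagged ``converged=False`` with a warning; NaN in the
    potentials raises with advice to increase epsilon.
    """
    config = config or TransportConfig()
    C = np.asarray(cost, dtype=float)
    a = np.asarray(source_weights, dtype=float)
    b = np.asarray(target_weights, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0) or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("marginal weights must be positive and finite")
    if not np.isfinite(C).all():
        raise ValueError("cost matrix must be finite")
    eps = config.epsilon
    tau_s = 1.0 if np.isinf(config.lambda_source) else config.lambda_source / (config.lambda_source + eps)
    tau_t = 1.0 if np.isinf(config.lambda_target) else config.lambda_target / (config.lambda_target + eps)
    log_a, log_b = np.log(a), np.log(b)
    f = np.zeros_like(a)
    g = np.zeros_like(b)
    Ce = C / eps
    it = 0
    err = np.inf
    for it in range(1, config.max_iterations + 1):
        f_prev, g_prev = f, g
        f = tau_s * eps * (log_a - logsumexp(g[None, :] / eps - Ce, axis=1))
        g = tau_t * eps * (log_b - logsumexp(f[:, None] / eps - Ce, axis=0))
        if np.any(np.isnan(f)) or np.any(np.isnan(g)):
            raise FloatingPointError(
                "NaN encountered in scaling potentials; increase epsilon"
            )
        err = max(np.abs(f - f_prev).max(), np.abs(g - g_prev).max())
        if err < config.tolerance:
            break
    converged = err < config.tolerance
    if not converged:
        warnings.warn(
            f"Sinkhorn did not converge in {config.max_iterations} iterations "
            f"(last change {err:.2e})"
        )
    gamma = np.exp(f[:, None] / eps + g[None, :] / eps - Ce)
    marg_err = float(
        max(
            np.abs(gamma.sum(axis=1) - a).max() if tau_s == 1.0 else 0.0,
            np.abs(gamma.sum(axis=0) - b).max() if tau_t == 1.0 else 0.0,
        )
    )
    n, m = C.shape
    return TransportMap(
        gamma=gamma,
        source_ids=np.arange(n) if source_ids is None else np.asarray(source_ids),
        target_ids=np.arange(m) if target_ids is None else np.asarray(target_ids),
        config=config,
        diagnostics={
            "iterations": it,
            "converged": bool(converged),
            "final_change": float(err),
            "marginal_error": marg_err,
        },
    )


def learn_growth_rates(
    cost: np.ndarray,
    initial_growth: GrowthRates,
    config: TransportConfig | None = None,
    target_weights: np.ndarray | None = None,
    source_ids: np.ndarray | None = None,
    target_ids: np.ndarray | None = None,
    growth_floor: float = 1e-3,
) -> tuple[GrowthRates, TransportMap]:
    """Iterate coupling solves with growth-rate re-estimation.

    Each iteration sets source weights proportional to ``g_i^dt`` (normalized),
    solves the unbalanced problem, and updates ``g_i`` from the realized row
    mass of the coupling: ``g_new = (row_mass / uniform_mass)^(1/dt)``, floored
    at a small positive constant.  ``growth_iterations=0`` performs a single
    solve with the initial rates unchanged.
    """
    config = config or TransportConfig()
    C = np.asarray(cost, dtype=float)
    n, m = C.shape
    g = GrowthRates(initial_growth.rates.copy(), initial_growth.dt)
    if g.rates.shape != (n,):
        raise ValueError("initial growth length must match the number of source cells")
    b = (
        np.full(m, 1.0 / m)
        if target_weights is None
        else np.asarray(target_weights, dtype=float) / np.sum(target_weights)
    )
    dt = g.dt
    tmap: TransportMap | None = None
    n_solves = max(config.growth_iterations, 0) + 1
    for step in range(n_solves):
        a = g.rates**dt
        a = a / a.sum()
        tmap = unbalanced_sinkhorn(C, a, b, config, source_ids, target_ids)
        if step == config.growth_iterations:
            break
        row_mass = tmap.gamma.sum(axis=1)
        total = row_mass.sum()
        rel = row_mass / total * n  # ratio to uniform mass 1/n
        g = GrowthRates(np.maximum(rel, growth_floor) ** (1.0 / dt), dt)
    assert tmap is not None
    tmap.growth = g
    return g, tmap


def compose_maps(maps: list[TransportMap]) -> np.ndarray:
    """Row-normalize each coupling and chain-multiply into a transition matrix
    from the first map's sources to the last map's targets."""
    if not maps:
        raise ValueError("need at least one map to compose")
    for prev, nxt in zip(maps, maps[1:]):
        if prev.gamma.shape[1] != nxt.gamma.shape[0] or not np.array_equal(
            prev.target_ids, nxt.source_ids
        ):
            raise ValueError(
                "transport chain break: targets of one map are not the sources of "
                f"the next ({prev.gamma.shape[1]} targets vs {nxt.gamma.shape[0]} sources)"
            )
    out = maps[0].transition_matrix()
    for m in maps[1:]:
        out = out @ m.transition_matrix()
    return out


def push(
    distribution: np.ndarray,
    maps: list[TransportMap],
    direction: str = "forward",
) -> np.ndarray:
    """Push a probability distribution through a chain of couplings.

    ``forward`` propagates through the row-normalized chain (descendants);
    ``backward`` expects a distribution over the *last* map's targets and
    propagates through the column-normalized chain reversed (ancestors).
    The output sums to one.
    """
    d = np.asarray(distribution, dtype=float)
    if np.any(d < 0) or not np.isclose(d.sum(), 1.0, atol=1e-6):
        raise ValueError("distribution must be nonnegative and sum to 1")
    if direction == "forward":
        expected = maps[0].gamma.shape[0]
        if d.size != expected:
            raise ValueError(f"distribution has {d.size} entries, sources have {expected}")
        for m in maps:
            d = d @ m.transition_matrix()
    elif direction == "backward":
        expected = maps[-1].gamma.shape[1]
        if d.size != expected:
            raise ValueError(f"distribution has {d.size} entries, targets have {expected}")
        for m in reversed(maps):
            d = d @ m.pullback_matrix()
    else:
        raise ValueError("direction must be 'forward' or 'backward'")
    s = d.sum()
    return d / s if s > 0 else d


def fit_interval_maps(
    ds: TimecourseDataset,
    config: TransportConfig | None = None,
    initial_growth: dict[float, np.ndarray] | None = None,
) -> list[TransportMap]:
    """Fit one growth-learned coupling per consecutive pair of time points,
    using the dataset's (batch-corrected) embedding; cell ids index the maps."""
    config = config or TransportConfig()
    if ds.embedding is None:
        raise ValueError("dataset has no embedding; run preprocessing first")
    grid = sorted(set(map(float, ds.time_grid)))
    maps: list[TransportMap] = []
    for t0, t1 in zip(grid, grid[1:]):
        i0, i1 = ds.cells_at(t0), ds.cells_at(t1)
        if i0.size == 0 or i1.size == 0:
            raise ValueError(f"no cells at time point {t0 if i0.size == 0 else t1}")
        C = cost_matrix(ds.embedding[i0], ds.embedding[i1], normalize=config.normalize_cost)
        dt = t1 - t0
        g0 = (
            np.ones(i0.size)
            if initial_growth is None or t0 not in initial_growth
            else np.asarray(initial_growth[t0], dtype=float)
        )
        _, tmap = learn_growth_rates(
            C,
            GrowthRates(g0, dt),
            config,
            source_ids=ds.cell_ids[i0],
            target_ids=ds.cell_ids[i1],
        )
        maps.append(tmap)
    return maps
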