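import numpy as np
import pytest

from fatecourse.config import PipelineConfig
from fatecourse.datasets import LineageTree, State
from fatecourse.model import TimecourseFateModel
from fatecourse.pipeline import simulate_from_config
from fatecourse.simulate import simulate_timecourse

GRID = [0.0, 0.75, 1.5, 2.25, 3.0]


def make_symmetric_tree(n_genes: int = 100, growth_a: float = 1.0, growth_b: float = 1.0) -> LineageTree:
    """Root splits at day 1.5 into two terminal branches with orthogonal
    program shifts; equal growth unless overridden."""
    root = np.full(n_genes, 10.0)
    pa, pb = root.copy(), root.copy()
    pa[: n_genes // 3] = 30.0
    pb[n_genes // 3 : 2 * n_genes // 3] = 30.0
    return LineageTree(
        states=[
            State("root", None, 0.0, root),
            State("A", "root", 1.5, pa),
            State("B", "root", 1.5, pb),
        ],
        growth={"root": 1.0, "A": growth_a, "B": growth_b},
        branch_times={"root": 1.5},
    )


def make_chain_tree(n_levels: int = 5, n_genes: int = 200, seed: int = 42) -> LineageTree:
    """Linear (non-branching) chain with an independent program per level, so
    each time point forms a well-separated cluster."""
    rng = np.random.default_rng(seed)
    progs = [rng.gamma(2.0, 10.0, size=n_genes) for _ in range(n_levels)]
    states = [State("s0", None, 0.0, progs[0])] + [
        State(f"s{i}", f"s{i-1}", 0.15 + 0.75 * (i - 1), progs[i])
        for i in range(1, n_levels)
    ]
    return LineageTree(
        states=states,
        growth={f"s{i}": 1.0 for i in range(n_levels)},
        branch_times={f"s{i}": 0.15 + 0.75 * i for i in range(n_levels - 1)},
    )


@pytest.fixture(scope="session")
def symmetric_tree() -> LineageTree:
    return make_symmetric_tree()


@pytest.fixture(scope="session")
def staged_dataset():
    """Well-separated time-point clusters (chain tree, low noise)."""
    return simulate_timecourse(make_chain_tree(), GRID, 150, dispersion=0.05, seed=5)


@pytest.fixture(scope="session")
def default_results():
    """The default synthetic study conditions, fitted once per session:
    5 time points x 500 cells, 300 genes, two terminal fates."""
    cfg = PipelineConfig()
    ds = simulate_from_config(cfg)
    return TimecourseFateModel(ds).fit()


@pytest.fixture(scope="session")
def small_results(symmetric_tree):
    """Symmetric two-branch timecourse at modest size, fitted once."""
    ds = simulate_timecourse(symmetric_tree, GRID, 300, seed=3)
    return TimecourseFateModel(ds).fit()
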