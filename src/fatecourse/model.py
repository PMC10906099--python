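"""Model/Results front door for timecourse fate inference.

:class:`TimecourseFateModel` is built from a :class:`TimecourseDataset` plus
target-set and solver configuration; :meth:`~TimecourseFateModel.fit` runs
preprocessing (if the dataset lacks an embedding), fits one growth-learned
unbalanced optimal-transport coupling per consecutive interval, builds the
fate matrix toward the configured target sets and returns a
:class:`TimecourseFateResults` carrying the couplings, learned growth rates,
fate probabilities, convergence diagnostics and a text ``summary()``.
Landscape selection, descendant allocation and query-fate prediction hang
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fate as fate_mod
from . import predict as predict_mod
from .datasets import TimecourseDataset
from .preprocess import run_preprocess
from .transport import TransportConfig, TransportMap, fit_interval_maps

__all__ = ["TimecourseFateModel", "TimecourseFateResults"]


class TimecourseFateModel:
    """Unbalanced-OT fate-inference model over a multi-time-point dataset.

    Parameters
    ----------
    dataset
        Timecourse counts + metadata; if ``dataset.embedding`` is missing it
        is derived at fit time (normalization, HVGs, PCA, MNN correction).
    targets
        Named disjoint terminal target sets.  Defaults to one set per true
        terminal state when the dataset carries simulation ground truth with
        state labels, otherwise must be given.
    config
        Transport solver settings (entropic regularization, marginal
        relaxation, growth-learning iterations).
    """

    def __init__(
        self,
        dataset: TimecourseDataset,
        targets: fate_mod.TargetSets | None = None,
        config: TransportConfig | None = None,
        n_components: int = 50,
        preprocess_kwargs: dict | None = None,
    ):
        self.dataset = dataset
        self.config = config or TransportConfig()
        self.n_components = n_components
        self.preprocess_kwargs = dict(preprocess_kwargs or {})
        self.targets = targets if targets is not None else self._default_targets()

    @classmethod
    def from_dataframe(
        cls,
        counts,
        cell_table: pd.DataFrame,
        gene_table: pd.DataFrame | None = None,
        **kwargs,
    ) -> "TimecourseFateModel":
        """Build from raw components (counts matrix + per-cell metadata)."""
        import scipy.sparse as sp

        counts = sp.csr_matrix(counts)
        if gene_table is None:
            gene_table = pd.DataFrame(
                {"gene_id": [f"g{i:04d}" for i in range(counts.shape[1])]}
            )
        grid = sorted(pd.unique(cell_table["time_point"]).astype(float))
        ds = TimecourseDataset(
            counts=counts,
            cell_table=cell_table.reset_index(drop=True),
            gene_table=gene_table,
            time_grid=grid,
        )
        return cls(ds, **kwargs)

    def _default_targets(self) -> fate_mod.TargetSets | None:
        ds = self.dataset
        if "state_label" not in ds.cell_table.columns or ds.true_fate_probs is None:
            return None
        t_ref = max(ds.time_grid)
        at_ref = ds.cell_table["time_point"].astype(float) == t_ref
        fates = list(ds.true_fate_probs.columns)
        sets = {}
        for f in fates:
            ids = ds.cell_table.loc[
                at_ref & (ds.cell_table["state_label"] == f), "cell_id"
            ].tolist()
            if ids:
                sets[f] = ids
        if not sets:
            return None
        return fate_mod.TargetSets(reference_time=t_ref, sets=sets)

    def fit(self) -> "TimecourseFateResults":
        ds = self.dataset
        qc_report = hvg_table = None
        if ds.embedding is None:
            ds, qc_report, hvg_table = run_preprocess(
                ds, n_components=self.n_components, **self.preprocess_kwargs
            )
        maps = fit_interval_maps(ds, self.config)
        fm = None
        if self.targets is not None:
            fm = fate_mod.compute_fate_matrix(ds, maps, self.targets)
        return TimecourseFateResults(
            model=self,
            dataset=ds,
            maps=maps,
            fate_matrix=fm,
            qc_report=qc_report,
            hvg_table=hvg_table,
        )


@dataclass
class TimecourseFateResults:
    """Fitted couplings, growth rates and fate probabilities."""

    model: TimecourseFateModel
    dataset: TimecourseDataset
    maps: list[TransportMap]
    fate_matrix: fate_mod.FateMatrix | None
    qc_report: pd.DataFrame | None = None
    hvg_table: pd.DataFrame | None = None
    _growth: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def growth_rates(self) -> pd.DataFrame:
        """Learned per-cell growth rates (per day), one row per source cell
        of each interval."""
        if self._growth is None:
            frames = []
            for m in self.maps:
                if m.growth is None:
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "cell_id": m.source_ids,
                            "growth_rate": m.growth.rates,
                            "dt": m.growth.dt,
                        }
                    )
                )
            self._growth = (
                pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            )
        return self._growth

    def log_odds(self, fate_subset: list[str], clip: float = 1e-12) -> pd.Series:
        if self.fate_matrix is None:
            raise ValueError("model was fitted without target sets")
        return fate_mod.log_odds(self.fate_matrix, fate_subset, clip)

    def select_landscape(self, fate_subset: list[str], threshold: float = 0.0, **kw):
        lo = self.log_odds(fate_subset)
        return fate_mod.select_landscape(self.dataset, lo, threshold, **kw)

    def allocate_descendants(self, source_populations, source_time, later_times, **kw):
        return fate_mod.allocate_descendants(
            self.dataset, self.maps, source_populations, source_time, later_times, **kw
        )

    def predict_query_fates(self, transfer: pd.DataFrame) -> pd.DataFrame:
        if self.fate_matrix is None:
            raise ValueError("model was fitted without target sets")
        return predict_mod.predict_query_fates(transfer, self.fate_matrix)

    def summary(self) -> str:
        """Plain-text summary of the fitted model."""
        ds = self.dataset
        lines = [
            "Timecourse fate-inference model",
            "=" * 47,
            f"cells: {ds.n_cells}   genes: {ds.n_genes}   "
            f"time points: {len(set(ds.time_grid))}",
            f"epsilon: {self.model.config.epsilon}   "
            f"lambda: ({self.model.config.lambda_source}, {self.model.config.lambda_target})   "
            f"growth iterations: {self.model.config.growth_iterations}",
            "-" * 47,
            "interval    cells      iters  converged  growth mean",
        ]
        grid = sorted(set(map(float, ds.time_grid)))
        for (t0, t1), m in zip(zip(grid, grid[1:]), self.maps):
            d = m.diagnostics
            gmean = float(np.mean(m.growth.rates)) if m.growth is not None else float("nan")
            lines.append(
                f"{t0:g}->{t1:g}".ljust(12)
                + f"{m.shape[0]}x{m.shape[1]}".ljust(11)
                + f"{d.get('iterations', '-')}".ljust(7)
                + f"{d.get('converged', '-')}".ljust(11)
                + f"{gmean:.3f}"
            )
        if self.fate_matrix is not None:
            lines.append("-" * 47)
            lines.append(
                f"fate matrix: {self.fate_matrix.probs.shape[0]} cells x "
                f"{len(self.fate_matrix.fate_names)} fates "
                f"(reference time {self.fate_matrix.reference_time:g})"
            )
            dev = float(np.abs(self.fate_matrix.probs.to_numpy().sum(axis=1) - 1).max())
            lines.append(f"max |row sum - 1|: {dev:.2e}")
            means = self.fate_matrix.probs.mean(axis=0)
            for name, v in means.items():
                lines.append(f"  mean P({name}): {v:.4f}")
        return "\n".join(lines)
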