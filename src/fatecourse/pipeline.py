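"""End-to-end pipeline orchestration with a checksum manifest.

Stages: simulate (or load) -> preprocess -> transport -> fate -> markers
(optional) -> report.  Each stage records its output files and their SHA-256
checksums in ``manifest.json``; a re-run skips stages whose outputs are
intact and recomputes anything missing or corrupted.  All TSV outputs carry
a provenance header (config hash, seed, version).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import fate as fate_mod
from .config import PipelineConfig
from .datasets import TimecourseDataset
from .io import (
    file_checksum,
    load_transport_map,
    read_dataset,
    save_transport_map,
    write_dataset,
    write_tsv,
)
from .markers import markers_onevsrest, markers_pairwise
from .model import TimecourseFateModel
from .preprocess import run_preprocess
from .simulate import build_lineage_tree, inject_batch_effect, simulate_timecourse
from .transport import TransportConfig, collapse_timepoints, fit_interval_maps

log = logging.getLogger("fatecourse")

__all__ = ["run_pipeline", "report", "simulate_from_config"]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_intact(self, name: str) -> bool:
        rec = self.data["stages"].get(name)
        if not rec:
            return False
        for f, digest in rec["files"].items():
            p = Path(f)
            if not p.exists() or file_checksum(p) != digest:
                log.warning("stage %s: %s missing or checksum mismatch; recomputing", name, f)
                return False
        return True

    def record(self, name: str, files: list[Path], seconds: float) -> None:
        self.data["stages"][name] = {
            "files": {str(f): file_checksum(f) for f in files},
            "seconds": round(seconds, 2),
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def simulate_from_config(cfg: PipelineConfig) -> TimecourseDataset:
    s = cfg.simulate
    tree = build_lineage_tree(
        n_states=s.n_states, n_genes=s.n_genes, depth=s.depth, seed=s.seed, span=s.span
    )
    ds = simulate_timecourse(
        tree,
        s.time_grid,
        s.cells_per_timepoint,
        s.count_depth,
        s.dispersion,
        n_batches=s.n_batches,
        seed=s.seed + 1,
    )
    if s.batch_magnitude > 0 and s.n_batches > 1:
        ds = inject_batch_effect(ds, s.batch_magnitude, seed=s.seed + 2)
    return ds


def _default_targets(ds: TimecourseDataset, cfg: PipelineConfig) -> fate_mod.TargetSets:
    f = cfg.fate
    t_ref = f.reference_time if f.reference_time is not None else max(ds.time_grid)
    if f.targets:
        return fate_mod.TargetSets(reference_time=t_ref, sets=dict(f.targets))
    model = TimecourseFateModel(ds)
    targets = model._default_targets()
    if targets is None:
        raise ValueError(
            "no target sets configured and the dataset carries no ground-truth "
            "terminal states to derive them from"
        )
    return targets


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured stages under ``cfg.output_dir``; resumable."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    prov = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    cfg.to_yaml(out / "config.yaml")

    # -- stage: dataset ----------------------------------------------------
    ds_dir = out / "dataset"
    t0 = time.time()
    if cfg.dataset_path is not None:
        ds = read_dataset(cfg.dataset_path)
    elif manifest.stage_intact("dataset"):
        ds = read_dataset(ds_dir)
    else:
        ds = simulate_from_config(cfg)
        files = write_dataset(ds, ds_dir)
        manifest.record("dataset", list(files.values()), time.time() - t0)
    log.info("dataset: %d cells x %d genes", ds.n_cells, ds.n_genes)

    # -- stage: preprocess -------------------------------------------------
    t0 = time.time()
    p = cfg.preprocess
    ds, qc_report, hvg = run_preprocess(
        ds,
        min_total_counts=p.min_total_counts,
        max_mito_fraction=p.max_mito_fraction,
        pseudocount=p.pseudocount,
        trend_span=p.trend_span,
        fdr=p.fdr,
        min_mean=p.min_mean,
        blacklist=p.blacklist,
        n_components=p.n_components,
        k_mnn=p.k_mnn,
    )
    pre_dir = out / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    emb_df = pd.DataFrame(
        ds.embedding, columns=[f"PC{i + 1}" for i in range(ds.embedding.shape[1])]
    )
    emb_df.insert(0, "cell_id", ds.cell_ids)
    files = [
        write_tsv(qc_report, pre_dir / "qc_report.tsv", prov),
        write_tsv(hvg, pre_dir / "hvgs.tsv", prov),
        write_tsv(emb_df, pre_dir / "embedding.tsv", prov),
    ]
    manifest.record("preprocess", files, time.time() - t0)

    # -- stage: transport --------------------------------------------------
    t0 = time.time()
    tcfg = cfg.transport
    if tcfg.collapse:
        ds = collapse_timepoints(ds, tcfg.collapse)
    config = TransportConfig(
        epsilon=tcfg.epsilon,
        lambda_source=tcfg.lambda_source,
        lambda_target=tcfg.lambda_target,
        max_iterations=tcfg.max_iterations,
        tolerance=tcfg.tolerance,
        growth_iterations=tcfg.growth_iterations,
    )
    tr_dir = out / "transport"
    grid = sorted(set(map(float, ds.time_grid)))
    map_paths = [tr_dir / f"map_{t0_:g}_{t1_:g}.npz" for t0_, t1_ in zip(grid, grid[1:])]
    if manifest.stage_intact("transport"):
        maps = [load_transport_map(p_) for p_ in map_paths]
    else:
        maps = fit_interval_maps(ds, config)
        for m, p_ in zip(maps, map_paths):
            save_transport_map(m, p_)
            if not m.diagnostics.get("converged", True):
                log.warning("transport map %s did not converge", p_.name)
        manifest.record("transport", map_paths, time.time() - t0)

    # -- stage: fate ---------------------------------------------------------
    t0 = time.time()
    targets = _default_targets(ds, cfg)
    fm = fate_mod.compute_fate_matrix(ds, maps, targets)
    fate_dir = out / "fate"
    fate_dir.mkdir(exist_ok=True)
    files = [
        write_tsv(fm.probs.reset_index(), fate_dir / "fate_matrix.tsv", prov)
    ]
    subset = cfg.fate.fate_subset or [targets.names[0]]
    lo = fate_mod.log_odds(fm, subset, cfg.fate.clip)
    lo_df = lo.rename_axis("cell_id").reset_index()
    files.append(write_tsv(lo_df, fate_dir / "log_odds.tsv", prov))
    try:
        mask, _ = fate_mod.select_landscape(ds, lo, cfg.fate.threshold)
    except ValueError:
        mask = np.zeros(ds.n_cells, dtype=bool)
    files.append(
        write_tsv(
            pd.DataFrame({"cell_id": ds.cell_ids, "selected": mask}),
            fate_dir / "landscape_mask.tsv",
            prov,
        )
    )
    manifest.record("fate", files, time.time() - t0)

    # -- stage: markers (optional) -----------------------------------------
    if cfg.markers.enabled:
        t0 = time.time()
        m = cfg.markers
        labels = ds.cell_table[m.label_column].to_numpy()
        gene_ids = ds.gene_table["gene_id"].tolist()
        if m.mode == "pairwise":
            table = markers_pairwise(ds.normalized, labels, gene_ids)
        else:
            table = markers_onevsrest(
                ds.normalized, labels, gene_ids, m.min_frac, m.min_lfc
            )
        mk_dir = out / "markers"
        mk_dir.mkdir(exist_ok=True)
        manifest.record(
            "markers",
            [write_tsv(table, mk_dir / "markers.tsv", prov)],
            time.time() - t0,
        )

    report(out)
    return out


def report(run_dir: str | Path) -> dict:
    """Collate a summary JSON from whatever artifacts a run produced;
    missing stages are flagged rather than fatal.  Idempotent."""
    run_dir = Path(run_dir)
    summary: dict = {"run_dir": str(run_dir), "missing": []}
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        summary["stage_seconds"] = {
            k: v.get("seconds") for k, v in manifest.get("stages", {}).items()
        }
    qc = run_dir / "preprocess" / "qc_report.tsv"
    if qc.exists():
        df = pd.read_csv(qc, sep="\t", comment="#")
        summary["qc"] = {
            "n_cells": int(len(df)),
            "n_pass": int(df["pass"].sum()),
            "median_total_counts": float(df["total_counts"].median()),
        }
    else:
        summary["missing"].append("preprocess")
    tr_dir = run_dir / "transport"
    if tr_dir.exists():
        diags = []
        for sidecar in sorted(tr_dir.glob("*.npz.json")):
            diags.append(json.loads(sidecar.read_text()).get("diagnostics", {}))
        summary["transport"] = {
            "n_maps": len(diags),
            "all_converged": all(d.get("converged", False) for d in diags),
            "max_iterations_used": max((d.get("iterations", 0) for d in diags), default=0),
        }
    else:
        summary["missing"].append("transport")
    fate_path = run_dir / "fate" / "fate_matrix.tsv"
    if fate_path.exists():
        fm = pd.read_csv(fate_path, sep="\t", comment="#", index_col=0)
        sums = fm.to_numpy().sum(axis=1)
        lo = pd.read_csv(run_dir / "fate" / "log_odds.tsv", sep="\t", comment="#")
        summary["fate"] = {
            "n_cells": int(fm.shape[0]),
            "n_fates": int(fm.shape[1]),
            "max_row_sum_deviation": float(np.abs(sums - 1).max()),
            "landscape_sizes": {
                str(th): int((lo["log_odds"] > th).sum()) for th in (0.0, -0.5, -1.0)
            },
        }
    else:
        summary["missing"].append("fate")
    (run_dir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
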