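"""Dataset and artifact serialization.

Datasets live on disk as a directory of Matrix Market counts plus TSV
cell/gene tables and an optional JSON ground-truth sidecar; gzip-compressed
variants (``counts.mtx.gz``, ``cells.tsv.gz``, ...) are accepted
transparently.  Stage outputs are TSV files with a provenance comment header
(config hash, seed, package version) and transport maps are NPZ archives
with a JSON config sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import MANDATORY_CELL_COLUMNS, TimecourseDataset
from .simulate import read_fixture, write_fixture
from .transport import GrowthRates, TransportConfig, TransportMap

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_tsv",
    "read_tsv",
    "save_transport_map",
    "load_transport_map",
    "file_checksum",
]


def _find(path: Path, stem: str) -> Path:
    for cand in (path / stem, path / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"{stem}(.gz) not found under {path}")


def read_dataset(path: str | Path) -> TimecourseDataset:
    """Read a dataset directory with strict schema validation."""
    path = Path(path)
    _find(path, "counts.mtx")
    cells = pd.read_csv(_find(path, "cells.tsv"), sep="\t")
    for col in MANDATORY_CELL_COLUMNS:
        if col not in cells.columns:
            raise ValueError(
                f"cells table {path / 'cells.tsv'} missing mandatory column {col!r} "
                f"(has {list(cells.columns)})"
            )
    return read_fixture(path)


def write_dataset(ds: TimecourseDataset, path: str | Path) -> dict[str, Path]:
    """Write the Matrix Market + TSV + JSON-sidecar layout; lossless roundtrip."""
    return write_fixture(ds, path)


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: dict | None = None, index: bool = False) -> Path:
    """TSV with a ``#``-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = dict(provenance or {})
    header.setdefault("version", __version__)
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def save_transport_map(tmap: TransportMap, path: str | Path) -> Path:
    """NPZ archive (coupling, ids, growth) + JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        gamma=tmap.gamma,
        source_ids=np.asarray(tmap.source_ids, dtype=str),
        target_ids=np.asarray(tmap.target_ids, dtype=str),
        growth=tmap.growth.rates if tmap.growth is not None else np.array([]),
        dt=np.array([tmap.growth.dt if tmap.growth is not None else np.nan]),
    )
    sidecar = {
        "config": vars(tmap.config).copy() if tmap.config else {},
        "diagnostics": tmap.diagnostics,
        "version": __version__,
    }
    # inf is not valid JSON; encode as string
    sidecar["config"] = {
        k: ("inf" if isinstance(v, float) and np.isinf(v) else v)
        for k, v in sidecar["config"].items()
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return Path(str(path) if str(path).endswith(".npz") else str(path) + ".npz")


def load_transport_map(path: str | Path) -> TransportMap:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else Path(str(path) + ".npz"))
    sidecar_path = Path(str(path) + ".json")
    config = TransportConfig()
    diagnostics: dict = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        cfg = {
            k: (np.inf if v == "inf" else v) for k, v in sidecar.get("config", {}).items()
        }
        config = TransportConfig(**cfg)
        diagnostics = sidecar.get("diagnostics", {})
    growth = None
    if data["growth"].size:
        growth = GrowthRates(data["growth"], float(data["dt"][0]))
    return TransportMap(
        gamma=data["gamma"],
        source_ids=data["source_ids"],
        target_ids=data["target_ids"],
        config=config,
        growth=growth,
        diagnostics=diagnostics,
    )


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()
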