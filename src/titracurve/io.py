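"""Readers, writers and run configuration.

Tables are TSV; the sparse cell matrix is MatrixMarket (genes x cells) with
sidecar TSVs for cell metadata (library, cluster) and gene names; the run
configuration round-trips through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import sparse
from scipy.io import mmread, mmwrite

from .dose_response import CriticalWindow

__all__ = [
    "PipelineConfig",
    "read_counts",
    "read_metadata",
    "read_dataset",
    "write_counts",
    "write_metadata",
    "write_cell_matrix",
    "read_cell_matrix",
]

META_COLUMNS = ("concentration_uM", "replicate", "timepoint_hpa")


@dataclass
class PipelineConfig:
    """End-to-end run settings; serializes losslessly to YAML."""

    seed: int = 0
    # synthetic panel
    n_sigmoidal: int = 60
    n_biphasic: int = 30
    n_flat: int = 10
    noise_cv: float = 0.1
    grid: Sequence[float] = (0.0, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0)
    n_replicates: int = 4
    timepoints: Sequence[float] = (6.0,)
    # classification
    threshold: float = 0.4
    window_low: float = 0.05
    window_high: float = 0.5
    axis: str = "linear"
    error_kind: str = "normalized_sse"
    # differential expression
    alpha_q: float = 0.1
    # single-nuclei stage
    n_clusters: int = 8
    n_cells_per_stratum: int = 400
    min_prop: float = 0.05
    tie_tol: float = 0.0
    expression_floor: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.window_low < self.window_high):
            raise ValueError("window bounds must satisfy 0 < low < high")
        if not (0 < self.threshold):
            raise ValueError("threshold must be positive")
        if not (0 <= self.alpha_q <= 1):
            raise ValueError("alpha_q must lie in [0, 1]")
        if not (0 <= self.min_prop < 1):
            raise ValueError("min_prop must lie in [0, 1)")

    @property
    def window(self) -> CriticalWindow:
        return CriticalWindow(self.window_low, self.window_high)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid"] = [float(g) for g in self.grid]
        d["timepoints"] = [float(t) for t in self.timepoints]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["grid"] = tuple(d.get("grid", cls.grid))
        d["timepoints"] = tuple(d.get("timepoints", cls.timepoints))
        return cls(**d)


# ---------------------------------------------------------------------------
# count tables


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample count table from TSV; validates gene ids and numerics."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicated gene id(s): {dup}")
    bad_cols = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad_cols:
        raise ValueError(f"non-numeric counts in column(s): {bad_cols}")
    df.index.name = "gene"
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {missing}")
    return meta


def read_dataset(
    counts_path: str | Path, meta_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts + metadata, cross-validated (every sample column described)."""
    counts = read_counts(counts_path)
    meta = read_metadata(meta_path)
    orphans = [c for c in counts.columns if c not in meta.index]
    if orphans:
        raise ValueError(f"sample column(s) without metadata: {orphans}")
    return counts, meta


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sparse cell matrix


def write_cell_matrix(cells: AnnData, prefix: str | Path) -> None:
    """Write genes x cells MTX plus ``<prefix>.cells.tsv`` (library, cluster)
    and ``<prefix>.genes.tsv`` sidecars."""
    prefix = Path(prefix)
    X = cells.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    mmwrite(str(prefix) + ".mtx", X.T.tocoo())
    cells.obs[["library", "cluster"]].to_csv(str(prefix) + ".cells.tsv", sep="\t")
    pd.DataFrame(index=cells.var_names).to_csv(str(prefix) + ".genes.tsv", sep="\t")


def read_cell_matrix(prefix: str | Path) -> AnnData:
    prefix = Path(prefix)
    X = sparse.csr_matrix(mmread(str(prefix) + ".mtx").T)
    obs = pd.read_csv(str(prefix) + ".cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(str(prefix) + ".genes.tsv", sep="\t", index_col=0)
    for col in ("library", "cluster"):
        if col not in obs.columns:
            raise ValueError(f"cell metadata sidecar missing column {col!r}")
    adata = AnnData(X=X, obs=obs, var=var)
    return adata
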