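"""Fold-change concordance between tissue-level counts and single-nuclei
pseudobulk.

The single-nuclei libraries are aggregated to pseudobulk profiles (per-gene
count sums scaled to counts per million), log2 fold changes between the
drug-treated and control 6 HPA libraries are computed with a pseudocount of
1, and their Pearson correlation with the tissue-level (bulk panel) log2
fold changes measures cross-platform agreement for a designated gene set —
typically the genes validated as drug-responsive at the tissue level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats

__all__ = ["FoldChangePair", "pseudobulk", "fold_change_pairs", "concordance"]


@dataclass(frozen=True)
class FoldChangePair:
    gene: str
    log2fc_tissue: float
    log2fc_pseudobulk: float


def pseudobulk(cells: AnnData, library: str) -> pd.Series:
    """Per-gene pseudobulk of one library: summed counts scaled to CPM."""
    mask = (cells.obs["library"] == library).to_numpy()
    if not mask.any():
        raise ValueError(f"library {library!r} has no cells")
    X = cells.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    totals = np.asarray(X[mask].sum(axis=0)).ravel().astype(float)
    depth = totals.sum()
    if depth == 0:
        raise ValueError(f"library {library!r} has zero total counts")
    return pd.Series(totals / depth * 1e6, index=cells.var_names, name=library)


def fold_change_pairs(
    tissue_log2fc: pd.Series,
    cells: AnnData,
    treated_library: str = "Rom6HPA",
    control_library: str = "Cont6HPA",
    genes: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pair tissue-level log2 fold changes with pseudobulk log2 fold changes.

    ``tissue_log2fc`` is indexed by gene (e.g. the ``log2fc`` column of the
    differential-expression table at the concentration assayed by the
    single-nuclei experiment).  ``genes`` restricts the comparison (defaults
    to the intersection of the two platforms).
    """
    cpm_t = pseudobulk(cells, treated_library)
    cpm_c = pseudobulk(cells, control_library)
    if genes is None:
        genes = [g for g in tissue_log2fc.index if g in cpm_t.index]
    missing = [g for g in genes if g not in cpm_t.index or g not in tissue_log2fc.index]
    if missing:
        raise ValueError(f"genes absent from one platform: {missing}")
    lfc_pb = np.log2(cpm_t[genes] + pseudocount) - np.log2(cpm_c[genes] + pseudocount)
    return pd.DataFrame(
        {
            "gene": list(genes),
            "log2fc_tissue": tissue_log2fc[genes].to_numpy(float),
            "log2fc_pseudobulk": lfc_pb.to_numpy(float),
        }
    )


def concordance(pairs: pd.DataFrame) -> float:
    """Pearson correlation of tissue vs pseudobulk log2 fold changes.

    Requires at least 3 pairs; returns NaN (with a warning) when either
    vector has zero variance.
    """
    x = pairs["log2fc_tissue"].to_numpy(float)
    y = pairs["log2fc_pseudobulk"].to_numpy(float)
    if x.size < 3:
        raise ValueError("need at least 3 fold-change pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in a fold-change vector; r undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
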