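"""Expressing-cell proportions and rank ordering across single-nuclei libraries.

For each (gene, cluster, library) stratum the proportion of cells expressing
the gene (count above a floor, default 0) is computed.  Genes whose maximum
proportion over all strata does not exceed a minimum (default 5%, strict)
are filtered out.  Each retained (gene, cluster) pair is then classified by
the descending rank order of its proportions across the three libraries —
one of the 3! = 6 permutations, or a tie-annotated variant when proportions
are within a tolerance of each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

__all__ = [
    "ProportionTable",
    "RankOrderResult",
    "proportion_expressing",
    "apply_gene_filter",
    "rank_order_classify",
    "ordering_summary",
]


@dataclass
class ProportionTable:
    """Expressing-cell proportions per (gene, cluster, library).

    ``proportions``: genes x (cluster, library) MultiIndex columns; NaN marks
    strata with zero cells (no information, not zero expression).
    ``n_cells``: cluster x library cell counts.
    ``expression_floor``: a cell expresses a gene when count > floor.
    """

    proportions: pd.DataFrame
    n_cells: pd.DataFrame
    expression_floor: float = 0.0

    @property
    def libraries(self) -> list[str]:
        return list(self.n_cells.columns)

    @property
    def clusters(self) -> list:
        return list(self.n_cells.index)


@dataclass(frozen=True)
class RankOrderResult:
    """Rank ordering of one (gene, cluster): e.g. ``"Rom6HPA>Cont6HPA>0HPA"``.
    Libraries whose proportions differ by at most the tie tolerance are
    joined with ``=``.  ``classifiable`` is False when any stratum is
    missing."""

    gene: str
    cluster: object
    ordering: str
    proportions: tuple[float, ...]
    classifiable: bool = True


def proportion_expressing(
    cells: AnnData, expression_floor: float = 0.0
) -> ProportionTable:
    """Fraction of expressing cells for every (gene, cluster, library).

    A cell expresses a gene when its count exceeds ``expression_floor``.
    Strata with zero cells are reported as NaN.
    """
    for col in ("library", "cluster"):
        if col not in cells.obs.columns:
            raise ValueError(f"cell metadata must include a {col!r} column")
    X = cells.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    genes = list(cells.var_names)
    libraries = list(
        cells.obs["library"].cat.categories
        if isinstance(cells.obs["library"].dtype, pd.CategoricalDtype)
        else pd.unique(cells.obs["library"])
    )
    clusters = sorted(pd.unique(cells.obs["cluster"]))

    cols, props, ncells = [], [], {}
    lib_arr = cells.obs["library"].to_numpy()
    clu_arr = cells.obs["cluster"].to_numpy()
    expressed = X > expression_floor
    for cl in clusters:
        for lib in libraries:
            mask = (clu_arr == cl) & (lib_arr == lib)
            n = int(mask.sum())
            ncells[(cl, lib)] = n
            cols.append((cl, lib))
            if n == 0:
                props.append(np.full(len(genes), np.nan))
            else:
                frac = np.asarray(expressed[mask].sum(axis=0)).ravel() / n
                props.append(frac)
    table = pd.DataFrame(
        np.column_stack(props),
        index=pd.Index(genes, name="gene"),
        columns=pd.MultiIndex.from_tuples(cols, names=["cluster", "library"]),
    )
    n_cells = pd.DataFrame(
        {lib: [ncells[(cl, lib)] for cl in clusters] for lib in libraries},
        index=pd.Index(clusters, name="cluster"),
    )
    return ProportionTable(table, n_cells, expression_floor)


def apply_gene_filter(
    table: ProportionTable, min_prop: float = 0.05, pooled: bool = False
) -> list[str]:
    """Genes expressed in more than ``min_prop`` of cells in at least one
    stratum (strict inequality).

    By default the strata are (cluster, library) combinations; with
    ``pooled=True`` libraries are pooled within each cluster (cell-count
    weighted) before applying the floor.
    """
    props = table.proportions
    if pooled:
        pooled_cols = {}
        for cl in table.clusters:
            w = table.n_cells.loc[cl]
            sub = props[cl]
            num = (sub * w).sum(axis=1, skipna=True)
            den = sum(
                w[lib] for lib in table.libraries if sub[lib].notna().any()
            )
            pooled_cols[cl] = num / den if den else np.nan
        props = pd.DataFrame(pooled_cols)
    best = props.max(axis=1, skipna=True)
    return list(props.index[best > min_prop])


def _ordering_string(
    libraries: Sequence[str], values: np.ndarray, tie_tol: float
) -> str:
    order = np.argsort(-values, kind="stable")
    parts = [str(libraries[order[0]])]
    for prev, cur in zip(order[:-1], order[1:]):
        sep = "=" if values[prev] - values[cur] <= tie_tol else ">"
        parts.append(sep + str(libraries[cur]))
    return "".join(parts)


def rank_order_classify(
    table: ProportionTable,
    gene: str,
    cluster,
    tie_tol: float = 0.0,
) -> RankOrderResult:
    """Classify one (gene, cluster) by descending expressing-cell proportion
    across the libraries.  Proportions within ``tie_tol`` of each other are
    annotated as tied rather than ordered arbitrarily; clusters with any
    missing stratum are unclassifiable."""
    libs = table.libraries
    values = np.array(
        [table.proportions.loc[gene, (cluster, lib)] for lib in libs], dtype=float
    )
    if np.any(~np.isfinite(values)):
        return RankOrderResult(gene, cluster, "", tuple(values), classifiable=False)
    return RankOrderResult(
        gene, cluster, _ordering_string(libs, values, tie_tol), tuple(values)
    )


def ordering_summary(results: Iterable[RankOrderResult]) -> pd.DataFrame:
    """Count ordering categories per gene across clusters.

    Rows are genes, columns ordering categories; entries count the clusters
    in which the gene realized that ordering.  Unclassifiable results are
    excluded, so the grand total equals the number of classifiable
    (gene, cluster) pairs.
    """
    rows = [
        {"gene": r.gene, "ordering": r.ordering}
        for r in results
        if r.classifiable
    ]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return (
        df.groupby(["gene", "ordering"]).size().unstack(fill_value=0).sort_index()
    )
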