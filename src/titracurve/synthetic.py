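"""Synthetic data with planted dose-response and single-nuclei structure.

Two generators cover the two experimental designs the analysis assumes:

* :func:`generate_counts` emulates a normalized-count gene panel measured
  across the chemical concentration gradient {0, 0.05, 0.1, 0.5, 1, 5, 10} uM
  with four replicates per dose: each gene follows a planted sigmoidal,
  biphasic or flat response function, multiplied by unit-mean lognormal noise
  parameterized by its coefficient of variation.  A truth table recording
  every planted shape and parameter set accompanies each dataset.

* :func:`generate_cell_matrix` emulates a sparse single-nuclei experiment
  with three libraries (0HPA, Cont6HPA, Rom6HPA) and a configurable number of
  cell clusters: for each (gene, cluster, library) stratum a planted
  probability governs whether a cell expresses the gene; expressing cells
  receive shifted-Poisson counts whose mean can carry a planted per-library
  fold change.

Counts are emitted as non-negative reals on the normalized-count scale, not
integer reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .dose_response import (
    BiphasicParams,
    SigmoidParams,
    eval_biphasic,
    eval_sigmoid,
)

__all__ = [
    "DEFAULT_GRID",
    "LIBRARIES",
    "PlantedGeneSpec",
    "SyntheticPanel",
    "SyntheticCounts",
    "generate_counts",
    "generate_cell_matrix",
    "default_panel",
    "sample_sigmoid_spec",
    "sample_biphasic_spec",
    "sample_flat_spec",
]

#: Concentration gradient (uM) of the titration design.
DEFAULT_GRID: tuple[float, ...] = (0.0, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0)

#: The three single-nuclei libraries: time of amputation, untreated 6 h post
#: amputation, and drug-treated 6 h post amputation.
LIBRARIES: tuple[str, ...] = ("0HPA", "Cont6HPA", "Rom6HPA")


@dataclass(frozen=True)
class PlantedGeneSpec:
    """Ground truth for one synthetic gene.

    ``params`` holds :class:`SigmoidParams` for sigmoidal genes,
    :class:`BiphasicParams` for biphasic genes, and a float level for flat
    genes.  ``noise_cv`` is the coefficient of variation of the
    multiplicative replicate noise.
    """

    gene_id: str
    shape: Literal["sigmoidal", "biphasic", "flat"]
    params: SigmoidParams | BiphasicParams | float
    noise_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.shape == "flat" and not np.isscalar(self.params):
            raise ValueError("flat genes take a scalar level as params")

    def response(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shape == "flat":
            return np.full_like(x, float(self.params))  # type: ignore[arg-type]
        if self.shape == "sigmoidal":
            return np.asarray(eval_sigmoid(self.params, x))  # type: ignore[arg-type]
        return np.asarray(eval_biphasic(self.params, x))  # type: ignore[arg-type]

    def inflection_points(self) -> list[float]:
        if self.shape == "sigmoidal":
            return [self.params.th]  # type: ignore[union-attr]
        if self.shape == "biphasic":
            p = self.params
            return sorted([p.first.th, p.second.th])  # type: ignore[union-attr]
        return []


@dataclass
class SyntheticPanel:
    """A full synthetic titration experiment: grid, replication, gene specs."""

    genes: list[PlantedGeneSpec]
    grid: Sequence[float] = DEFAULT_GRID
    n_replicates: int = 4
    timepoints: Sequence[float] = (6.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("concentration grid must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not self.genes:
            raise ValueError("panel has no genes")


class SyntheticCounts(NamedTuple):
    counts: pd.DataFrame  # genes x samples
    metadata: pd.DataFrame  # sample_id index; concentration_uM, replicate, timepoint_hpa
    truth: pd.DataFrame  # one row per gene: shape, parameters, inflections


def _fmt_conc(c: float) -> str:
    return f"{c:g}"


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def _truth_row(spec: PlantedGeneSpec) -> dict:
    row: dict = {
        "gene": spec.gene_id,
        "shape": spec.shape,
        "noise_cv": spec.noise_cv,
        "inflection_points": ";".join(f"{t:.6g}" for t in spec.inflection_points()),
    }
    p = spec.params
    if spec.shape == "flat":
        row.update(level=float(p), a=np.nan, b=np.nan, k=np.nan, th=np.nan, mode="")  # type: ignore[arg-type]
    elif spec.shape == "sigmoidal":
        row.update(level=np.nan, a=p.a, b=p.b, k=p.k, th=p.th, mode="")  # type: ignore[union-attr]
    else:
        row.update(
            level=np.nan,
            a=p.first.a, b=p.first.b, k=p.first.k, th=p.first.th,  # type: ignore[union-attr]
            a2=p.second.a, b2=p.second.b, k2=p.second.k, th2=p.second.th,  # type: ignore[union-attr]
            mode=p.mode, scale=p.scale,  # type: ignore[union-attr]
        )
    return row


def generate_counts(panel: SyntheticPanel) -> SyntheticCounts:
    """Realize a count matrix (genes x samples) from a synthetic panel.

    Each entry is ``response(shape, params, concentration) * lognormal noise``
    with unit-mean noise of the gene's CV; negative model values are clipped
    at zero with a warning.  Deterministic given ``panel.seed``.
    """
    rng = np.random.default_rng(panel.seed)
    grid = np.asarray(panel.grid, dtype=float)

    sample_ids, conc_col, rep_col, tp_col = [], [], [], []
    for tp in panel.timepoints:
        for c in grid:
            for r in range(1, panel.n_replicates + 1):
                sample_ids.append(f"{_fmt_conc(c)}uM_rep{r}_{_fmt_conc(tp)}HPA")
                conc_col.append(c)
                rep_col.append(r)
                tp_col.append(tp)
    meta = pd.DataFrame(
        {
            "concentration_uM": conc_col,
            "replicate": rep_col,
            "timepoint_hpa": tp_col,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    x = meta["concentration_uM"].to_numpy(float)
    data = np.empty((len(panel.genes), len(sample_ids)))
    clipped = 0
    for i, spec in enumerate(panel.genes):
        mu = spec.response(x)
        if np.any(mu < 0):
            clipped += 1
            mu = np.clip(mu, 0.0, None)
        data[i] = mu * _lognormal_factors(rng, spec.noise_cv, mu.size)
    if clipped:
        import warnings

        warnings.warn(
            f"{clipped} gene(s) had negative model values clipped at 0",
            stacklevel=2,
        )

    counts = pd.DataFrame(
        data,
        index=pd.Index([g.gene_id for g in panel.genes], name="gene"),
        columns=sample_ids,
    )
    truth = pd.DataFrame([_truth_row(g) for g in panel.genes]).set_index("gene")
    return SyntheticCounts(counts, meta, truth)


# ---------------------------------------------------------------------------
# planted parameter samplers (study-condition defaults)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def sample_sigmoid_spec(
    gene_id: str, rng: np.random.Generator, noise_cv: float = 0.1
) -> PlantedGeneSpec:
    """A realistic monotone dose-response gene: baseline 50-500 counts,
    4-15x dynamic range, inflection log-uniform across the nonzero gradient,
    slope scaled to the inflection so the transition spans roughly one
    dilution step.  Increasing and decreasing responses are equally likely.
    """
    lo = _loguniform(rng, 50, 500)
    hi = lo * rng.uniform(4, 15)
    th = _loguniform(rng, 0.05, 5.0)
    k = rng.uniform(2.0, 6.0) / th
    a, b = (lo, hi) if rng.random() < 0.5 else (hi, lo)
    return PlantedGeneSpec(gene_id, "sigmoidal", SigmoidParams(a, b, k, th), noise_cv)


def sample_biphasic_spec(
    gene_id: str, rng: np.random.Generator, noise_cv: float = 0.1
) -> PlantedGeneSpec:
    """A non-monotonic gene: a plateau bump (product of a rising and a
    falling sigmoid) or a valley (sum of a falling and a rising sigmoid),
    with the first transition inside the critical window (0.05-0.1 uM) and
    the second between 1 and 5 uM — the plateau placement the 7-point
    gradient can resolve.
    """
    lo = rng.uniform(20, 80)
    hi = lo * rng.uniform(8, 15)
    th1 = rng.uniform(0.06, 0.09)
    th2 = rng.uniform(1.5, 4.0)
    k1 = rng.uniform(80, 160)
    k2 = rng.uniform(1.5, 3.5)
    if rng.random() < 0.5:  # bump
        params = BiphasicParams(
            first=SigmoidParams(lo, hi, k1, th1),
            second=SigmoidParams(hi, lo, k2, th2),
            mode="product",
            scale=hi,
        )
    else:  # valley
        params = BiphasicParams(
            first=SigmoidParams(hi - lo, 0.0, k1, th1),
            second=SigmoidParams(lo, hi, k2, th2),
            mode="sum",
        )
    return PlantedGeneSpec(gene_id, "biphasic", params, noise_cv)


def sample_flat_spec(
    gene_id: str, rng: np.random.Generator, noise_cv: float = 0.1
) -> PlantedGeneSpec:
    """A gene with no dose response: constant level 100-1000 counts."""
    return PlantedGeneSpec(gene_id, "flat", _loguniform(rng, 100, 1000), noise_cv)


def default_panel(
    seed: int = 0,
    n_sigmoidal: int = 60,
    n_biphasic: int = 30,
    n_flat: int = 10,
    noise_cv: float = 0.1,
    timepoints: Sequence[float] = (6.0,),
) -> SyntheticPanel:
    """The standard 100-gene study panel: 60 sigmoidal, 30 biphasic, 10 flat
    genes over the default gradient with 4 replicates."""
    rng = np.random.default_rng(seed)
    genes: list[PlantedGeneSpec] = []
    for i in range(n_sigmoidal):
        genes.append(sample_sigmoid_spec(f"sig{i:03d}", rng, noise_cv))
    for i in range(n_biphasic):
        genes.append(sample_biphasic_spec(f"bip{i:03d}", rng, noise_cv))
    for i in range(n_flat):
        genes.append(sample_flat_spec(f"flat{i:03d}", rng, noise_cv))
    return SyntheticPanel(genes=genes, timepoints=timepoints, seed=seed)


# ---------------------------------------------------------------------------
# single-nuclei matrix


def generate_cell_matrix(
    proportions: pd.DataFrame,
    n_cells: int | dict[tuple[int, str], int],
    *,
    libraries: Sequence[str] = LIBRARIES,
    clusters: Sequence[int] | None = None,
    mean_counts: pd.DataFrame | None = None,
    seed: int = 0,
) -> AnnData:
    """Realize a sparse cells x genes matrix with planted expressing fractions.

    Parameters
    ----------
    proportions
        Planted probability that a cell expresses each gene (count > 0),
        indexed by gene with a ``(cluster, library)`` column MultiIndex, or
        with library columns only (shared across clusters).
    n_cells
        Cells per (cluster, library) stratum; an int applies to every
        stratum.
    mean_counts
        Optional per (gene, library) mean count among expressing cells
        (genes x libraries); expressing cells draw ``1 + Poisson(mean - 1)``.
        Defaults to 2.0 for every stratum.
    """
    if clusters is None:
        if isinstance(proportions.columns, pd.MultiIndex):
            clusters = sorted({c for c, _ in proportions.columns})
        else:
            clusters = [1]
    if not isinstance(proportions.columns, pd.MultiIndex):
        proportions = pd.concat(
            {cl: proportions for cl in clusters}, axis=1
        )
    vals = proportions.to_numpy(float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("planted proportions must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    genes = list(proportions.index)
    n_genes = len(genes)

    rows_parts, obs_lib, obs_cluster = [], [], []
    cell_offset = 0
    data_rows: list[sparse.csr_matrix] = []
    for cl in clusters:
        for lib in libraries:
            n = n_cells if isinstance(n_cells, int) else n_cells.get((cl, lib), 0)
            if n == 0:
                continue
            p = proportions[(cl, lib)].to_numpy(float)
            expressed = rng.random((n, n_genes)) < p[None, :]
            if mean_counts is not None:
                mu = np.clip(mean_counts[lib].reindex(genes).to_numpy(float), 1.0, None)
            else:
                mu = np.full(n_genes, 2.0)
            counts = np.zeros((n, n_genes), dtype=np.int64)
            lam = np.broadcast_to(mu - 1.0, (n, n_genes))
            counts[expressed] = 1 + rng.poisson(lam[expressed])
            data_rows.append(sparse.csr_matrix(counts))
            obs_lib.extend([lib] * n)
            obs_cluster.extend([cl] * n)
            cell_offset += n

    X = sparse.vstack(data_rows, format="csr")
    obs = pd.DataFrame(
        {"library": obs_lib, "cluster": obs_cluster},
        index=pd.Index([f"cell{i:06d}" for i in range(X.shape[0])], name="cell_id"),
    )
    obs["library"] = pd.Categorical(obs["library"], categories=list(libraries))
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    return AnnData(X=X, obs=obs, var=var)
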