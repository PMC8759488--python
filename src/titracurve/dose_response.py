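"""Sigmoidal and biphasic concentration-response modeling and classification.

Each gene's transcript counts across a chemical concentration gradient are
summarized as a response curve and fit with

* a four-parameter logistic (4PL) sigmoid
      f(x) = a + (b - a) / (1 + exp(-k (x - th)))
  where ``a`` is the minimum transcript number, ``b`` the maximum, ``th`` the
  inflection concentration (the dose yielding a response halfway between the
  two plateaus) and ``k`` controls the slope; and
* a biphasic model built from two sigmoids, either their sum or their
  (rescaled) product, capturing non-monotonic rise-then-fall or
  fall-then-rise responses.

Classification uses a dimensionless *scaled error*: the sum of squared
residuals of the response curve after normalizing it by its range
(max - min of the fitted responses).  Curves whose sigmoid fit has scaled
error below a threshold (default 0.4) are called sigmoidal; curves that fail
the sigmoid criterion but fit the biphasic model below the threshold are
called biphasic; the remainder are unclassified.  Near-constant curves are
short-circuited to "flat" before any fitting.

A :class:`CriticalWindow` (default 0.05-0.5 uM) marks the concentration
interval separating regenerative success from failure; a classified gene is
flagged ``in_window`` when any of its inflection points falls inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SigmoidParams",
    "BiphasicParams",
    "FitResult",
    "GeneClassification",
    "CriticalWindow",
    "ConcentrationSeries",
    "eval_sigmoid",
    "eval_biphasic",
    "fit_sigmoid",
    "fit_biphasic",
    "classify_gene",
    "classify_panel",
    "summarize_classifications",
]

_EXP_CLAMP = 700.0  # exp overflow guard

ErrorKind = Literal["normalized_sse", "rmse"]
AxisMode = Literal["linear", "log"]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SigmoidParams:
    """4PL parameters: plateaus ``a`` (left) and ``b`` (right), slope ``k``
    (per uM), inflection ``th`` (uM).  The direction of response is the sign
    of ``k * (b - a)``."""

    a: float
    b: float
    k: float
    th: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.k, self.th], dtype=float)


@dataclass(frozen=True)
class BiphasicParams:
    """Two sigmoid components combined by ``mode``.

    ``mode="sum"``     : f(x) = s1(x) + s2(x)
    ``mode="product"`` : f(x) = s1(x) * s2(x) / scale

    The product of two count-scale sigmoids has squared-count units; the
    positive ``scale`` constant (fitted alongside the component parameters)
    returns it to the count scale.
    """

    first: SigmoidParams
    second: SigmoidParams
    mode: Literal["sum", "product"] = "sum"
    scale: float = 1.0


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit to a response curve."""

    params: SigmoidParams | BiphasicParams
    lse: float  # sum of squared residuals on the fitted points (counts^2)
    scaled_error: float  # dimensionless; NaN when the response range is ~0
    converged: bool
    n_points: int

    @property
    def inflection_points(self) -> list[float]:
        p = self.params
        if isinstance(p, SigmoidParams):
            return [p.th]
        return sorted([p.first.th, p.second.th])


@dataclass(frozen=True)
class CriticalWindow:
    """Concentration interval (uM) separating regenerative success (below)
    from failure (above).  Inclusive at both ends."""

    low: float = 0.05
    high: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"require 0 < low < high, got ({self.low}, {self.high})")

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


@dataclass
class GeneClassification:
    gene_id: str
    label: Literal["sigmoidal", "biphasic", "unclassified", "flat"]
    best_fit: FitResult | None
    direction: Literal["increasing", "decreasing", "non-monotonic", "flat"]
    inflection_points: list[float] = field(default_factory=list)
    in_window: bool = False
    timepoint: float | None = None


@dataclass
class ConcentrationSeries:
    """One gene's transcript counts over the concentration gradient.

    ``concentration`` and ``counts`` are parallel arrays, one entry per
    observation (replicates appear as repeated concentrations).
    """

    gene_id: str
    concentration: np.ndarray
    counts: np.ndarray
    replicate: np.ndarray | None = None
    timepoint: float | None = None

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.concentration.shape != self.counts.shape:
            raise ValueError("concentration and counts must be the same length")

    def concentration_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-concentration mean response, sorted by concentration."""
        grid = np.unique(self.concentration)
        means = np.array(
            [self.counts[self.concentration == c].mean() for c in grid]
        )
        return grid, means


# ---------------------------------------------------------------------------
# model evaluation


def eval_sigmoid(p: SigmoidParams, x: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the 4PL sigmoid at concentration(s) ``x``."""
    return _sigmoid(p.as_array(), np.asarray(x, dtype=float))


def _sigmoid(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b, k, th = theta
    z = np.clip(k * (x - th), -_EXP_CLAMP, _EXP_CLAMP)
    return a + (b - a) / (1.0 + np.exp(-z))


def eval_biphasic(p: BiphasicParams, x: float | np.ndarray) -> float | np.ndarray:
    x = np.asarray(x, dtype=float)
    s1 = eval_sigmoid(p.first, x)
    s2 = eval_sigmoid(p.second, x)
    if p.mode == "sum":
        return s1 + s2
    if p.mode == "product":
        return s1 * s2 / p.scale
    raise ValueError(f"unknown biphasic mode: {p.mode!r}")


def _biphasic_sum(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    return _sigmoid(theta[:4], x) + _sigmoid(theta[4:8], x)


def _biphasic_product(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    return _sigmoid(theta[:4], x) * _sigmoid(theta[4:8], x) / theta[8]


def _sigmoid_jac(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the 4PL sigmoid wrt (a, b, k, th)."""
    a, b, k, th = theta
    z = np.clip(k * (x - th), -_EXP_CLAMP, _EXP_CLAMP)
    s = 1.0 / (1.0 + np.exp(-z))
    sp = s * (1.0 - s)
    return np.column_stack(
        [1.0 - s, s, (b - a) * sp * (x - th), -(b - a) * sp * k]
    )


def _biphasic_sum_jac(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.hstack([_sigmoid_jac(theta[:4], x), _sigmoid_jac(theta[4:8], x)])


def _biphasic_product_jac(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    s1 = _sigmoid(theta[:4], x)
    s2 = _sigmoid(theta[4:8], x)
    c = theta[8]
    j1 = _sigmoid_jac(theta[:4], x) * (s2 / c)[:, None]
    j2 = _sigmoid_jac(theta[4:8], x) * (s1 / c)[:, None]
    jc = (-s1 * s2 / c**2)[:, None]
    return np.hstack([j1, j2, jc])


# ---------------------------------------------------------------------------
# error scaling and axis handling


def compute_scaled_error(
    sse: float, n_points: int, response_range: float, kind: ErrorKind = "normalized_sse"
) -> float:
    """Dimensionless fitting error used by the 0.4 classification cutoff.

    ``normalized_sse`` (default): SSE of the range-normalized curve,
    SSE / range^2 — invariant to rescaling the counts.
    ``rmse``: root-mean-square residual divided by the range.

    Returns NaN when the range is not positive (flat curves).
    """
    if not np.isfinite(response_range) or response_range <= 0:
        return float("nan")
    if kind == "normalized_sse":
        return float(sse / response_range**2)
    if kind == "rmse":
        return float(np.sqrt(sse / n_points) / response_range)
    raise ValueError(f"unknown error kind: {kind!r}")


def transform_axis(conc: np.ndarray, mode: AxisMode = "linear") -> np.ndarray:
    """Concentration axis used for fitting.

    ``linear`` returns the concentrations unchanged.  ``log`` returns
    log10(uM) with a zero concentration mapped one half dilution step below
    the lowest nonzero concentration (the dilution step is the ratio of the
    two lowest nonzero concentrations).
    """
    conc = np.asarray(conc, dtype=float)
    if mode == "linear":
        return conc
    if mode != "log":
        raise ValueError(f"unknown axis mode: {mode!r}")
    nz = np.unique(conc[conc > 0])
    if nz.size == 0:
        raise ValueError("log axis requires at least one nonzero concentration")
    step = nz[1] / nz[0] if nz.size > 1 else 10.0
    zero_sub = nz[0] / np.sqrt(step)
    out = np.where(conc > 0, conc, zero_sub)
    return np.log10(out)


# ---------------------------------------------------------------------------
# fitting

_K_STARTS = (1.0, 5.0, 20.0, 100.0, -1.0, -5.0, -20.0, -100.0)


def _prepare_fit_data(
    series: ConcentrationSeries,
    fit_target: Literal["means", "points"],
    axis: AxisMode,
) -> tuple[np.ndarray, np.ndarray]:
    if fit_target == "means":
        x, y = series.concentration_means()
    else:
        order = np.argsort(series.concentration, kind="stable")
        x, y = series.concentration[order], series.counts[order]
    n_distinct = np.unique(x).size
    if n_distinct < 5:
        raise ValueError(
            f"need >=5 distinct concentrations to fit 4 parameters, got {n_distinct}"
        )
    return transform_axis(x, axis), y


def _run_starts(
    residual,
    starts: Sequence[np.ndarray],
    lower: np.ndarray,
    upper: np.ndarray,
    n_optimize: int = 10,
    jac=None,
) -> tuple[np.ndarray, float, bool]:
    """Deterministic multi-start bounded least squares; best solution by SSE.

    All starts are screened by their initial SSE and only the ``n_optimize``
    most promising are refined with the trust-region optimizer.
    """
    clipped = [np.clip(t, lower, upper) for t in starts]
    sse0 = np.array([float(np.sum(residual(t) ** 2)) for t in clipped])
    order = np.argsort(sse0, kind="stable")[:n_optimize]
    best_theta, best_sse, best_ok = clipped[order[0]], sse0[order[0]], False
    for idx in order:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                sol = least_squares(
                    residual,
                    clipped[idx],
                    jac=jac if jac is not None else "2-point",
                    bounds=(lower, upper),
                    max_nfev=200,
                    ftol=1e-10,
                    xtol=1e-10,
                )
            except Exception:  # singular starts etc.
                continue
        sse = float(2.0 * sol.cost)
        if sse < best_sse:
            best_theta, best_sse, best_ok = sol.x, sse, bool(sol.success)
    return best_theta, best_sse, best_ok


def fit_sigmoid(
    series: ConcentrationSeries,
    *,
    fit_target: Literal["means", "points"] = "means",
    axis: AxisMode = "linear",
    error_kind: ErrorKind = "normalized_sse",
) -> FitResult:
    """Multi-start bounded nonlinear least squares for the 4PL sigmoid.

    By default the fit targets the per-concentration mean responses (the
    response curve); ``fit_target="points"`` fits replicate-level data.
    Starts span a deterministic grid of slope signs/magnitudes and interior
    inflection candidates; bounds are a, b in [0, 2*max(response)], th within
    the (possibly transformed) concentration range, |k| <= 1e4.
    """
    x, y = _prepare_fit_data(series, fit_target, axis)
    rng_y = float(y.max() - y.min())
    ymax = float(max(y.max(), 1e-12))

    lower = np.array([0.0, 0.0, -1e4, x.min()])
    upper = np.array([2 * ymax, 2 * ymax, 1e4, x.max()])

    interior = np.unique(x)[1:-1]
    starts = [
        np.array([y.min(), y.max(), k0, th0])
        for k0 in _K_STARTS
        for th0 in interior
    ]

    def residual(theta: np.ndarray) -> np.ndarray:
        return _sigmoid(theta, x) - y

    theta, sse, ok = _run_starts(
        residual, starts, lower, upper, jac=lambda t: _sigmoid_jac(t, x)
    )
    params = SigmoidParams(*[float(v) for v in theta])
    scaled = compute_scaled_error(sse, y.size, rng_y, error_kind)
    return FitResult(params, sse, scaled, ok, int(y.size))


def _biphasic_starts(
    x: np.ndarray, y: np.ndarray, mode: str, sigmoid_seed: SigmoidParams | None
) -> list[np.ndarray]:
    lo, hi = float(y.min()), float(y.max())
    amp = max(hi - lo, 1e-9)
    interior = np.unique(x)[1:-1]
    pairs = [
        (t1, t2) for i, t1 in enumerate(interior) for t2 in interior[i + 1:]
    ]
    starts: list[np.ndarray] = []
    for t1, t2 in pairs:
        k1 = 3.0 / max(abs(t1), 1e-3)
        k2 = 3.0 / max(abs(t2), 1e-3)
        if mode == "sum":
            # rise-then-fall, fall-then-rise, double rise, double fall
            shapes = [
                (0.0, amp, hi, lo),
                (amp, 0.0, lo, hi),
                (lo, lo + amp / 2, lo, lo + amp / 2),
                (lo + amp / 2, lo, lo + amp / 2, lo),
            ]
            for a1, b1, a2, b2 in shapes:
                starts.append(np.array([a1, b1, k1, t1, a2, b2, k2, t2]))
        else:
            shapes = [
                (lo, hi, hi, lo),  # bump: up then down
                (hi, lo, lo, hi),  # valley: down then up
                (lo, hi, lo, hi),
                (hi, lo, hi, lo),
            ]
            for a1, b1, a2, b2 in shapes:
                starts.append(
                    np.array([a1, b1, k1, t1, a2, b2, k2, t2, max(hi, 1e-6)])
                )
    if sigmoid_seed is not None and mode == "sum":
        # one flat second component reproduces the plain sigmoid (nesting)
        starts.append(
            np.array(
                [
                    sigmoid_seed.a,
                    sigmoid_seed.b,
                    sigmoid_seed.k,
                    sigmoid_seed.th,
                    0.0,
                    0.0,
                    1.0,
                    float(np.median(x)),
                ]
            )
        )
    return starts


def fit_biphasic(
    series: ConcentrationSeries,
    *,
    fit_target: Literal["means", "points"] = "means",
    axis: AxisMode = "linear",
    error_kind: ErrorKind = "normalized_sse",
    sigmoid_seed: SigmoidParams | None = None,
) -> FitResult:
    """Fit sum- and product-of-two-sigmoids models; return the better mode.

    ``sigmoid_seed`` (typically the solution of :func:`fit_sigmoid` on the
    same series) adds a start with one flat component, guaranteeing the
    biphasic fit never does worse than the nested plain sigmoid.
    """
    x, y = _prepare_fit_data(series, fit_target, axis)
    rng_y = float(y.max() - y.min())
    ymax = float(max(y.max(), 1e-12))

    best: FitResult | None = None
    for mode in ("sum", "product"):
        n_extra = 1 if mode == "product" else 0
        lower = np.array([0.0, 0.0, -1e4, x.min()] * 2 + [1e-9] * n_extra)
        upper = np.array(
            [2 * ymax, 2 * ymax, 1e4, x.max()] * 2 + [4 * ymax**2] * n_extra
        )
        model = _biphasic_product if mode == "product" else _biphasic_sum
        model_jac = _biphasic_product_jac if mode == "product" else _biphasic_sum_jac

        def residual(theta: np.ndarray) -> np.ndarray:
            return model(theta, x) - y

        starts = _biphasic_starts(x, y, mode, sigmoid_seed)
        theta, sse, ok = _run_starts(
            residual, starts, lower, upper, jac=lambda t: model_jac(t, x)
        )
        params = BiphasicParams(
            first=SigmoidParams(*[float(v) for v in theta[:4]]),
            second=SigmoidParams(*[float(v) for v in theta[4:8]]),
            mode=mode,  # type: ignore[arg-type]
            scale=float(theta[8]) if mode == "product" else 1.0,
        )
        scaled = compute_scaled_error(sse, y.size, rng_y, error_kind)
        result = FitResult(params, sse, scaled, ok, int(y.size))
        if best is None or _better(result, best):
            best = result
    assert best is not None
    return best


def _better(candidate: FitResult, incumbent: FitResult) -> bool:
    c, i = candidate.scaled_error, incumbent.scaled_error
    if np.isnan(c):
        return False
    if np.isnan(i):
        return True
    return c < i


# ---------------------------------------------------------------------------
# classification


def _direction_of_sigmoid(p: SigmoidParams) -> str:
    s = p.k * (p.b - p.a)
    if s > 0:
        return "increasing"
    if s < 0:
        return "decreasing"
    return "flat"


def _has_interior_extremum(
    params: BiphasicParams, x_lo: float, x_hi: float, n: int = 512
) -> bool:
    xs = np.linspace(x_lo, x_hi, n)
    ys = np.asarray(eval_biphasic(params, xs))
    d = np.diff(ys)
    tol = 1e-9 * max(np.abs(ys).max(), 1.0)
    signs = np.sign(np.where(np.abs(d) < tol, 0.0, d))
    signs = signs[signs != 0]
    return bool(signs.size and np.any(signs[:-1] != signs[1:]))


def _untransform_th(th: float, axis: AxisMode) -> float:
    return float(10.0**th) if axis == "log" else float(th)


def classify_gene(
    series: ConcentrationSeries,
    threshold: float = 0.4,
    window: CriticalWindow = CriticalWindow(),
    *,
    eps_flat_frac: float = 0.01,
    fit_target: Literal["means", "points"] = "means",
    axis: AxisMode = "linear",
    error_kind: ErrorKind = "normalized_sse",
) -> GeneClassification:
    """Classify one gene's response curve as sigmoidal, biphasic, flat or
    unclassified.

    Order of tests: (0) response range below ``eps_flat_frac`` of the mean
    level -> flat (no fitting; avoids dividing by a ~0 range); (1) sigmoid
    scaled error strictly below ``threshold`` -> sigmoidal; (2) biphasic
    scaled error strictly below ``threshold`` -> biphasic; (3) unclassified.
    ``in_window`` is true when any inflection point lies inside ``window``
    (inclusive).
    """
    grid, means = series.concentration_means()
    rng_means = float(means.max() - means.min())
    level = float(np.abs(means).mean())
    if rng_means < eps_flat_frac * max(level, 1e-300) or rng_means == 0.0:
        return GeneClassification(
            gene_id=series.gene_id,
            label="flat",
            best_fit=None,
            direction="flat",
            inflection_points=[],
            in_window=False,
            timepoint=series.timepoint,
        )

    sig_fit = fit_sigmoid(
        series, fit_target=fit_target, axis=axis, error_kind=error_kind
    )
    if sig_fit.scaled_error < threshold:
        p = sig_fit.params
        assert isinstance(p, SigmoidParams)
        th_um = _untransform_th(p.th, axis)
        return GeneClassification(
            gene_id=series.gene_id,
            label="sigmoidal",
            best_fit=sig_fit,
            direction=_direction_of_sigmoid(p),  # type: ignore[arg-type]
            inflection_points=[th_um],
            in_window=window.contains(th_um),
            timepoint=series.timepoint,
        )

    assert isinstance(sig_fit.params, SigmoidParams)
    bi_fit = fit_biphasic(
        series,
        fit_target=fit_target,
        axis=axis,
        error_kind=error_kind,
        sigmoid_seed=sig_fit.params,
    )
    if bi_fit.scaled_error < threshold:
        p = bi_fit.params
        assert isinstance(p, BiphasicParams)
        x_fit = transform_axis(grid, axis)
        if _has_interior_extremum(p, float(x_fit.min()), float(x_fit.max())):
            direction = "non-monotonic"
        else:
            ys = np.asarray(eval_biphasic(p, x_fit))
            direction = "increasing" if ys[-1] >= ys[0] else "decreasing"
        ths = [_untransform_th(t, axis) for t in bi_fit.inflection_points]
        return GeneClassification(
            gene_id=series.gene_id,
            label="biphasic",
            best_fit=bi_fit,
            direction=direction,  # type: ignore[arg-type]
            inflection_points=sorted(ths),
            in_window=any(window.contains(t) for t in ths),
            timepoint=series.timepoint,
        )

    best = sig_fit if _better(sig_fit, bi_fit) else bi_fit
    return GeneClassification(
        gene_id=series.gene_id,
        label="unclassified",
        best_fit=best,
        direction="flat",
        inflection_points=[],
        in_window=False,
        timepoint=series.timepoint,
    )


# ---------------------------------------------------------------------------
# panel-level classification


def _series_from_panel(
    counts: pd.DataFrame, meta: pd.DataFrame, gene: str, timepoint: float
) -> ConcentrationSeries:
    sel = meta[meta["timepoint_hpa"] == timepoint]
    return ConcentrationSeries(
        gene_id=gene,
        concentration=sel["concentration_uM"].to_numpy(float),
        counts=counts.loc[gene, sel.index].to_numpy(float),
        replicate=sel["replicate"].to_numpy(),
        timepoint=float(timepoint),
    )


def _check_panel(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    missing = [c for c in counts.columns if c not in meta.index]
    orphans = [s for s in meta.index if s not in counts.columns]
    if missing or orphans:
        raise ValueError(
            "sample/metadata mismatch; "
            f"samples without metadata: {missing}; metadata without samples: {orphans}"
        )
    required = {"concentration_uM", "replicate", "timepoint_hpa"}
    absent = required - set(meta.columns)
    if absent:
        raise ValueError(f"metadata missing required columns: {sorted(absent)}")


def classify_panel(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    threshold: float = 0.4,
    window: CriticalWindow = CriticalWindow(),
    **kwargs,
) -> pd.DataFrame:
    """Classify every gene at every timepoint of a count panel.

    ``counts``: genes x samples; ``meta``: indexed by sample id with columns
    ``concentration_uM``, ``replicate``, ``timepoint_hpa``.  Returns one row
    per (gene, timepoint) with the fitted parameters, errors, label,
    direction and window flag.
    """
    _check_panel(counts, meta)
    rows = []
    for tp in sorted(meta["timepoint_hpa"].unique()):
        for gene in counts.index:
            series = _series_from_panel(counts, meta, gene, tp)
            cls = classify_gene(series, threshold=threshold, window=window, **kwargs)
            rows.append(_classification_row(cls))
    return pd.DataFrame(rows)


def _classification_row(cls: GeneClassification) -> dict:
    row = {
        "gene": cls.gene_id,
        "timepoint_hpa": cls.timepoint,
        "label": cls.label,
        "direction": cls.direction,
        "in_window": cls.in_window,
        "inflection_points": ";".join(f"{t:.6g}" for t in cls.inflection_points),
        "mode": "",
        "a": np.nan,
        "b": np.nan,
        "k": np.nan,
        "th": np.nan,
        "lse": np.nan,
        "scaled_error": np.nan,
    }
    fit = cls.best_fit
    if fit is None:
        return row
    row["lse"] = fit.lse
    row["scaled_error"] = fit.scaled_error
    p = fit.params
    if isinstance(p, SigmoidParams):
        row.update(a=p.a, b=p.b, k=p.k, th=p.th, mode="sigmoid")
    else:
        row.update(a=p.first.a, b=p.first.b, k=p.first.k, th=p.first.th, mode=p.mode)
    return row


def summarize_classifications(table: pd.DataFrame) -> dict:
    """Panel-level tallies: per-timepoint label counts, plus genes classified
    (sigmoidal or biphasic) or in-window at *any* timepoint, each gene counted
    once."""
    summary: dict = {"n_genes": int(table["gene"].nunique()), "per_timepoint": {}}
    for tp, sub in table.groupby("timepoint_hpa"):
        summary["per_timepoint"][str(tp)] = {
            "sigmoidal": int((sub["label"] == "sigmoidal").sum()),
            "biphasic": int((sub["label"] == "biphasic").sum()),
            "flat": int((sub["label"] == "flat").sum()),
            "unclassified": int((sub["label"] == "unclassified").sum()),
            "in_window": int(sub["in_window"].sum()),
        }
    classified = table[table["label"].isin(["sigmoidal", "biphasic"])]
    summary["classified_either_timepoint"] = int(classified["gene"].nunique())
    summary["in_window_either_timepoint"] = int(
        table.loc[table["in_window"], "gene"].nunique()
    )
    return summary
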