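"""Per-concentration differential expression against the 0 uM control.

Each treated concentration is compared to the vehicle control within the same
timepoint using a two-sample t-test on log2(count + 1) — pooled variance by
default, which is exactly calibrated at the 4-replicate design (Welch's
unequal-variance variant is available but runs conservative at such small
group sizes); fold changes are differences of mean log2 counts.  Benjamini-Hochberg correction is
applied within each (concentration, timepoint) stratum, and two significance
regimes are flagged: BH-adjusted q < 0.1 and raw p < 0.01.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["de_test", "bh_adjust", "de_table"]


def _log2p1(x: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def de_test(
    treated: np.ndarray, control: np.ndarray, equal_var: bool = True
) -> tuple[float, float, float]:
    """t-test of one gene's treated vs control replicates on log2 counts.

    Returns ``(t_stat, p, log2fc)`` where ``log2fc`` is the difference of
    mean log2(count + 1).  ``equal_var=False`` selects Welch's variant.
    Two groups with zero variance and equal means give ``(0, 1, 0)``.
    Requires at least two replicates per group.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise ValueError("need >=2 replicates per group")
    lt, lc = _log2p1(treated), _log2p1(control)
    log2fc = float(lt.mean() - lc.mean())
    if lt.var() == 0 and lc.var() == 0:
        if log2fc == 0:
            return 0.0, 1.0, 0.0
        return float(np.inf) * np.sign(log2fc), 0.0, log2fc
    t, p = stats.ttest_ind(lt, lc, equal_var=equal_var)
    return float(t), float(p), log2fc


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    alpha_q: float = 0.1,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Differential expression of every gene at every nonzero concentration.

    For each timepoint, each concentration > 0 is tested against the 0 uM
    control of the same timepoint; BH correction is applied within each
    (concentration, timepoint) stratum.  Returns one row per (gene,
    concentration, timepoint) with ``significant_q`` (q < ``alpha_q``) and
    ``significant_p01`` (raw p < 0.01) flags.
    """
    frames = []
    for tp in sorted(meta["timepoint_hpa"].unique()):
        sel = meta[meta["timepoint_hpa"] == tp]
        control_samples = sel.index[sel["concentration_uM"] == 0]
        if control_samples.empty:
            raise ValueError(f"no 0 uM control samples at timepoint {tp}")
        ctrl = _log2p1(counts[control_samples].to_numpy())
        for conc in sorted(sel["concentration_uM"].unique()):
            if conc == 0:
                continue
            trt_samples = sel.index[sel["concentration_uM"] == conc]
            if len(trt_samples) < 2 or len(control_samples) < 2:
                raise ValueError(
                    f"need >=2 replicates; concentration {conc} at {tp} HPA"
                )
            trt = _log2p1(counts[trt_samples].to_numpy())
            t, p = stats.ttest_ind(trt, ctrl, equal_var=equal_var, axis=1)
            log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
            # zero-variance ties produce NaN; equal means are a clean null
            bad = ~np.isfinite(p)
            if bad.any():
                equal = bad & (np.abs(log2fc) < 1e-12)
                p = np.where(equal, 1.0, p)
                t = np.where(equal, 0.0, t)
                p = np.where(bad & ~equal, 0.0, p)
                t = np.where(bad & ~equal, np.sign(log2fc) * np.inf, t)
            frames.append(
                pd.DataFrame(
                    {
                        "gene": counts.index,
                        "concentration_uM": conc,
                        "timepoint_hpa": tp,
                        "log2fc": log2fc,
                        "t_stat": t,
                        "p": p,
                        "q": bh_adjust(p),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    table["significant_q"] = table["q"] < alpha_q
    table["significant_p01"] = table["p"] < 0.01
    return table
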