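"""Welch differential expression and Benjamini-Hochberg correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titracurve import bh_adjust, de_table, de_test
from titracurve.synthetic import (
    PlantedGeneSpec,
    SigmoidParams,
    SyntheticPanel,
    generate_counts,
)


def bh_bruteforce(p):
    """Step-up by definition: q_i = min over ranks j >= rank(i) of p_(j)*n/j."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * n / (j + 1) for j in range(pos, n)
        ]
        q[idx] = min(min(candidates), 1.0)
    return q


class TestDeTest:
    def test_identical_groups_are_null(self):
        x = np.array([100.0, 110.0, 95.0, 105.0])
        t, p, lfc = de_test(x, x)
        assert lfc == 0.0
        assert p == pytest.approx(1.0)

    def test_exact_doubling_gives_log2fc_near_one(self):
        ctrl = np.array([400.0, 500.0, 450.0, 480.0])
        t, p, lfc = de_test(2 * ctrl, ctrl)
        assert lfc == pytest.approx(1.0, abs=0.01)  # counts >> 1 pseudocount
        assert t > 0

    def test_zero_variance_equal_means(self):
        t, p, lfc = de_test(np.array([5.0, 5.0]), np.array([5.0, 5.0]))
        assert (t, p, lfc) == (0.0, 1.0, 0.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            de_test(np.array([1.0]), np.array([1.0, 2.0]))

    def test_type_i_error_calibrated(self):
        """Under a planted lognormal null the default (pooled-variance) test
        on log2 counts rejects at very nearly the nominal rate; Welch's
        variant runs conservative at 4 replicates per group."""
        rng = np.random.default_rng(12)
        n_genes = 5000
        level = 500.0
        sigma = np.sqrt(np.log1p(0.1**2))
        draw = lambda: level * rng.lognormal(-sigma**2 / 2, sigma, (n_genes, 4))
        t_counts, c_counts = draw(), draw()
        p_pooled = np.array(
            [de_test(t_counts[i], c_counts[i])[1] for i in range(n_genes)]
        )
        assert np.mean(p_pooled < 0.05) == pytest.approx(0.05, abs=0.01)
        p_welch = np.array(
            [de_test(t_counts[i], c_counts[i], equal_var=False)[1]
             for i in range(n_genes)]
        )
        assert np.mean(p_welch < 0.05) <= np.mean(p_pooled < 0.05) + 0.002


class TestBH:
    def test_textbook_example(self):
        # ranks 1..4 of n=4: min-from-top of (0.04, 0.04, 0.04, 0.04)
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([np.nan, 0.2])

    def test_q_at_least_p_and_in_unit_interval(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all((q >= 0) & (q <= 1))

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    def test_matches_bruteforce_step_up(self, p):
        assert np.allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


def _shifted_panel(seed=21, n_shifted=20, n_null=80, fold=3.0):
    """Null genes are flat; shifted genes step up 3-fold at >=0.5 uM."""
    genes = []
    for i in range(n_shifted):
        genes.append(
            PlantedGeneSpec(
                f"hit{i}",
                "sigmoidal",
                SigmoidParams(a=300.0, b=300.0 * fold, k=50.0, th=0.3),
                noise_cv=0.1,
            )
        )
    for i in range(n_null):
        genes.append(PlantedGeneSpec(f"null{i}", "flat", 300.0, noise_cv=0.1))
    return SyntheticPanel(genes=genes, seed=seed)


class TestDeTable:
    def test_planted_shifts_detected_with_fdr_control(self):
        counts, meta, _ = generate_counts(_shifted_panel())
        table = de_table(counts, meta, alpha_q=0.1)
        top = table[table["concentration_uM"] == 10.0]
        hits = top[top["significant_q"]]
        true_hits = hits["gene"].str.startswith("hit").sum()
        false_hits = hits["gene"].str.startswith("null").sum()
        assert true_hits >= 18
        assert false_hits <= 8

    def test_all_null_panel_controls_false_discovery(self):
        genes = [PlantedGeneSpec(f"n{i}", "flat", 300.0, 0.1) for i in range(100)]
        fdp = []
        for seed in range(25):
            counts, meta, _ = generate_counts(SyntheticPanel(genes=genes, seed=seed))
            table = de_table(counts, meta, alpha_q=0.1)
            for _, sub in table.groupby("concentration_uM"):
                n_disc = int(sub["significant_q"].sum())
                fdp.append(1.0 if n_disc else 0.0)
        # under the global null FDP is 0/1, E[FDP]=P(any rejection)<=alpha;
        # allow one-sided 99% sampling slack around the 0.1 guarantee
        n = len(fdp)
        assert np.mean(fdp) <= 0.1 + 2.33 * np.sqrt(0.1 * 0.9 / n)

    def test_row_count_one_concentration(self):
        genes = [PlantedGeneSpec(f"n{i}", "flat", 300.0, 0.05) for i in range(5)]
        panel = SyntheticPanel(genes=genes, grid=(0.0, 10.0), seed=0)
        counts, meta, _ = generate_counts(panel)
        table = de_table(counts, meta)
        assert len(table) == 5  # genes x 1 nonzero concentration x 1 timepoint

    def test_missing_control_stratum_rejected(self):
        counts, meta, _ = generate_counts(_shifted_panel())
        keep = meta["concentration_uM"] > 0
        with pytest.raises(ValueError, match="control"):
            de_table(counts[meta.index[keep]], meta[keep])

    def test_gene_order_equivariance(self):
        counts, meta, _ = generate_counts(_shifted_panel())
        shuffled = counts.sample(frac=1.0, random_state=4)
        key = ["gene", "concentration_uM", "timepoint_hpa"]
        t1 = de_table(counts, meta).sort_values(key).reset_index(drop=True)
        t2 = de_table(shuffled, meta).sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, t2)
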