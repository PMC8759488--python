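"""Expressing-cell proportions, the >5% filter, and rank ordering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

from titracurve import (
    apply_gene_filter,
    ordering_summary,
    proportion_expressing,
    rank_order_classify,
)
from titracurve.cell_proportions import ProportionTable
from titracurve.synthetic import LIBRARIES, generate_cell_matrix


def make_table(values_by_gene, libraries=LIBRARIES, cluster=1):
    """ProportionTable with explicit per-library proportions, one cluster."""
    props = pd.DataFrame(
        {
            (cluster, lib): [v[i] for v in values_by_gene.values()]
            for i, lib in enumerate(libraries)
        },
        index=pd.Index(list(values_by_gene), name="gene"),
    )
    props.columns = pd.MultiIndex.from_tuples(props.columns, names=["cluster", "library"])
    n_cells = pd.DataFrame(
        {lib: [100] for lib in libraries}, index=pd.Index([cluster], name="cluster")
    )
    return ProportionTable(props, n_cells)


def uniform_props(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.DataFrame(
        {lib: values for lib in LIBRARIES}, index=pd.Index(genes, name="gene")
    )


class TestProportions:
    def test_absent_gene_proportion_zero_everywhere(self):
        adata = generate_cell_matrix(uniform_props([0.0, 0.4]), 100, seed=0)
        table = proportion_expressing(adata)
        assert (table.proportions.loc["g0"] == 0).all()

    def test_unit_proportion_exact(self):
        adata = generate_cell_matrix(uniform_props([1.0]), 50, seed=0)
        table = proportion_expressing(adata)
        assert (table.proportions.loc["g0"] == 1.0).all()

    def test_large_stratum_close_to_planted(self):
        adata = generate_cell_matrix(
            uniform_props([0.3]), {(1, "0HPA"): 10_000}, seed=1
        )
        table = proportion_expressing(adata)
        assert table.proportions.loc["g0", (1, "0HPA")] == pytest.approx(0.3, abs=0.02)

    def test_empty_stratum_reported_missing(self):
        adata = generate_cell_matrix(
            uniform_props([0.5]), {(1, "0HPA"): 50, (1, "Cont6HPA"): 50}, seed=0
        )
        table = proportion_expressing(adata)
        assert np.isnan(table.proportions.loc["g0", (1, "Rom6HPA")])
        assert table.n_cells.loc[1, "Rom6HPA"] == 0

    def test_invariant_to_cell_duplication(self):
        adata = generate_cell_matrix(uniform_props([0.25, 0.7]), 80, seed=2)
        doubled = AnnData(
            X=sparse.vstack([adata.X, adata.X], format="csr"),
            obs=pd.concat([adata.obs, adata.obs]).reset_index(drop=True),
            var=adata.var.copy(),
        )
        t1 = proportion_expressing(adata)
        t2 = proportion_expressing(doubled)
        pd.testing.assert_frame_equal(t1.proportions, t2.proportions)

    def test_expression_floor(self):
        X = sparse.csr_matrix(np.array([[0, 1], [0, 2], [0, 5]]))
        obs = pd.DataFrame({"library": ["0HPA"] * 3, "cluster": [1, 1, 1]})
        adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=["a", "b"]))
        t = proportion_expressing(adata, expression_floor=1)
        assert t.proportions.loc["a", (1, "0HPA")] == 0.0
        assert t.proportions.loc["b", (1, "0HPA")] == pytest.approx(2 / 3)


class TestFilter:
    def test_strict_inequality_at_floor(self):
        table = make_table(
            {"below": (0.04, 0.01, 0.02), "at": (0.05, 0.05, 0.05), "above": (0.051, 0.0, 0.0)}
        )
        assert apply_gene_filter(table, 0.05) == ["above"]

    def test_seven_of_twentynine_planted_below_floor(self):
        """Planting 7 of 29 genes below the 5% floor retains exactly 22."""
        rng = np.random.default_rng(8)
        values = {}
        for i in range(22):
            values[f"keep{i}"] = tuple(rng.uniform(0.08, 0.6, 3))
        for i in range(7):
            values[f"drop{i}"] = tuple(rng.uniform(0.0, 0.04, 3))
        table = make_table(values)
        retained = apply_gene_filter(table, 0.05)
        assert len(retained) == 22
        assert all(g.startswith("keep") for g in retained)


class TestRankOrder:
    def test_descending_order_matches_proportions(self):
        table = make_table({"g": (0.1, 0.2, 0.4)})  # 0HPA, Cont, Rom
        res = rank_order_classify(table, "g", 1)
        assert res.ordering == "Rom6HPA>Cont6HPA>0HPA"
        assert res.classifiable

    def test_full_tie_annotated(self):
        table = make_table({"g": (0.2, 0.2, 0.2)})
        res = rank_order_classify(table, "g", 1, tie_tol=0.0)
        assert res.ordering.count("=") == 2
        assert ">" not in res.ordering

    def test_tie_tolerance_groups_near_values(self):
        table = make_table({"g": (0.30, 0.31, 0.10)})
        res = rank_order_classify(table, "g", 1, tie_tol=0.02)
        assert res.ordering == "Cont6HPA=0HPA>Rom6HPA"

    def test_missing_stratum_unclassifiable(self):
        table = make_table({"g": (0.2, np.nan, 0.4)})
        res = rank_order_classify(table, "g", 1)
        assert not res.classifiable

    def test_all_six_orderings_recovered(self):
        """Exhaustive permutation fixtures realize each strict ordering once,
        agreeing with a brute-force sort."""
        levels = {"0HPA": 0, "Cont6HPA": 1, "Rom6HPA": 2}
        values = {}
        expected = {}
        for i, perm in enumerate(itertools.permutations(LIBRARIES)):
            by_lib = {lib: 0.6 - 0.2 * rank for rank, lib in enumerate(perm)}
            values[f"g{i}"] = tuple(by_lib[lib] for lib in LIBRARIES)
            expected[f"g{i}"] = ">".join(perm)
        table = make_table(values)
        seen = []
        for g, want in expected.items():
            res = rank_order_classify(table, g, 1)
            assert res.ordering == want
            seen.append(res.ordering)
        assert len(set(seen)) == 6


class TestOrderingSummary:
    def test_single_pair_unit_entry(self):
        table = make_table({"g": (0.1, 0.2, 0.4)})
        res = [rank_order_classify(table, "g", 1)]
        summary = ordering_summary(res)
        assert summary.loc["g"].sum() == 1

    def test_category_totals_match_direct_tally(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(10)]
        clusters = list(range(1, 6))
        results = []
        for g in genes:
            for cl in clusters:
                vals = tuple(np.round(rng.uniform(0.05, 0.9, 3), 3))
                table = make_table({g: vals}, cluster=cl)
                results.append(rank_order_classify(table, g, cl))
        summary = ordering_summary(results)
        assert summary.to_numpy().sum() == len(genes) * len(clusters)
        # independent tally
        from collections import Counter

        tally = Counter((r.gene, r.ordering) for r in results)
        for (g, ordering), n in tally.items():
            assert summary.loc[g, ordering] == n
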