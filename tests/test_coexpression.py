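"""Co-expression modules: correlations, detection, sign partition, comparisons."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haeseq.coexpression import (
    CoexpressionModule,
    CorrelationMatrix,
    compare_module_correlations,
    detect_modules,
    module_summaries,
    pairwise_correlations,
    partition_signs,
)


def corr_from(df_or_array, genes=None):
    m = pd.DataFrame(df_or_array)
    if genes is not None:
        m.index = m.columns = genes
    return m


def _block_corr(genes, rng, r_in=0.0, split=None, r_named=None):
    """Build an exchangeable-ish correlation matrix via latent draws."""
    n = len(genes)
    m = np.full((n, n), r_in)
    np.fill_diagonal(m, 1.0)
    return corr_from(m, genes)


class TestPairwiseCorrelations:
    def test_duplicate_and_negated_genes(self, rng):
        x = pd.DataFrame(
            rng.normal(size=(3, 6)), index=["a", "b", "c"],
            columns=[f"i{j}" for j in range(6)],
        )
        x.loc["b"] = x.loc["a"]
        x.loc["c"] = -x.loc["a"]
        cm = pairwise_correlations(x, x.columns, "control")
        assert cm.matrix.loc["a", "b"] == pytest.approx(1.0)
        assert cm.matrix.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = pd.DataFrame(
            rng.normal(size=(10, 8)), index=[f"g{i}" for i in range(10)],
            columns=[f"i{j}" for j in range(8)],
        )
        cm = pairwise_correlations(x, x.columns, "control").matrix
        for a, b in combinations(x.index[:5], 2):
            u, v = x.loc[a].to_numpy(), x.loc[b].to_numpy()
            du, dv = u - u.mean(), v - v.mean()
            expected = np.sum(du * dv) / np.sqrt(np.sum(du**2) * np.sum(dv**2))
            assert cm.loc[a, b] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_gene_absent_and_min_n(self, rng):
        x = pd.DataFrame(
            rng.normal(size=(2, 5)), index=["a", "b"], columns=[f"i{j}" for j in range(5)]
        )
        x.loc["b"] = 3.0
        cm = pairwise_correlations(x, x.columns, "c").matrix
        assert np.isnan(cm.loc["a", "b"])
        with pytest.raises(ValueError):
            pairwise_correlations(x, x.columns[:3], "c")


def _cm(matrix, subgroup):
    return CorrelationMatrix(matrix=matrix, subgroup=subgroup, n_individuals=20)


def _null_corr(genes, rng, n=20):
    x = rng.normal(size=(len(genes), n))
    return corr_from(np.corrcoef(x), genes)


class TestDetectModules:
    def test_planted_block_found_in_unique_subgroup(self, rng):
        genes = [f"g{i}" for i in range(12)]
        block = genes[:6]
        strong = _null_corr(genes, rng)
        strong.loc[block, block] = 0.9
        np.fill_diagonal(strong.values, 1.0)
        corr = {
            "control": _cm(_null_corr(genes, rng), "control"),
            "CC4-M": _cm(_null_corr(genes, rng), "CC4-M"),
            "CC4-S": _cm(strong, "CC4-S"),
        }
        mods = detect_modules(corr)
        assert len(mods) == 1
        assert mods[0].source_subgroup == "CC4-S"
        assert mods[0].genes == frozenset(block)

    def test_block_in_every_subgroup_rejected(self, rng):
        genes = [f"g{i}" for i in range(10)]
        m = _null_corr(genes, rng)
        m.loc[genes[:6], genes[:6]] = 0.9
        np.fill_diagonal(m.values, 1.0)
        corr = {s: _cm(m.copy(), s) for s in ("control", "CC4-M", "CC4-S")}
        assert detect_modules(corr) == []

    def test_four_gene_block_below_min_size(self, rng):
        genes = [f"g{i}" for i in range(8)]
        m = _null_corr(genes, rng)
        m.loc[genes[:4], genes[:4]] = 0.95
        np.fill_diagonal(m.values, 1.0)
        corr = {
            "control": _cm(m, "control"),
            "CC4-M": _cm(_null_corr(genes, rng), "CC4-M"),
            "CC4-S": _cm(_null_corr(genes, rng), "CC4-S"),
        }
        assert detect_modules(corr) == []

    def test_gene_order_permutation_invariance(self, rng):
        genes = [f"g{i}" for i in range(9)]
        strong = _null_corr(genes, rng)
        strong.loc[genes[:5], genes[:5]] = 0.85
        np.fill_diagonal(strong.values, 1.0)
        null_m, null_s = _null_corr(genes, rng), _null_corr(genes, rng)
        perm = list(rng.permutation(genes))
        corr1 = {
            "control": _cm(null_m, "control"),
            "CC4-M": _cm(null_s, "CC4-M"),
            "CC4-S": _cm(strong, "CC4-S"),
        }
        corr2 = {
            "control": _cm(null_m.loc[perm, perm], "control"),
            "CC4-M": _cm(null_s.loc[perm, perm], "CC4-M"),
            "CC4-S": _cm(strong.loc[perm, perm], "CC4-S"),
        }
        m1, m2 = detect_modules(corr1), detect_modules(corr2)
        assert [m.genes for m in m1] == [m.genes for m in m2]


def exhaustive_best_partition(genes, corr):
    """Oracle: enumerate all two-colorings, maximize sign-consistent |r|."""
    genes = sorted(genes)
    n = len(genes)
    best, best_sides = -np.inf, None
    for code in range(1 << (n - 1)):
        sides = [False] + [(code >> k) & 1 == 1 for k in range(n - 1)]
        agree = 0.0
        for i, j in combinations(range(n), 2):
            r = corr.loc[genes[i], genes[j]]
            if not np.isfinite(r):
                continue
            consistent = (sides[i] == sides[j]) == (r > 0)
            agree += abs(r) if consistent else 0.0
        if agree > best + 1e-12:
            best, best_sides = agree, sides
    a = frozenset(g for g, s in zip(genes, best_sides) if not s)
    b = frozenset(g for g, s in zip(genes, best_sides) if s)
    return {a, b}, best


class TestPartitionSigns:
    def test_all_positive_single_side(self):
        genes = list("abcde")
        m = corr_from(np.full((5, 5), 0.6), genes)
        np.fill_diagonal(m.values, 1.0)
        a, b, fr = partition_signs(genes, m)
        assert a == frozenset(genes) and b == frozenset() and fr == 0.0

    def test_two_block_exact_recovery(self):
        genes = [f"g{i}" for i in range(8)]
        m = np.full((8, 8), -0.8)
        m[:4, :4] = 0.8
        m[4:, 4:] = 0.8
        np.fill_diagonal(m, 1.0)
        cm = corr_from(m, genes)
        a, b, fr = partition_signs(genes, cm)
        assert {a, b} == {frozenset(genes[:4]), frozenset(genes[4:])}
        assert fr == pytest.approx(0.0)

    def test_star_negative_gene_singleton_side(self):
        genes = list("abcd")
        m = np.full((4, 4), 0.7)
        m[3, :] = m[:, 3] = -0.7
        np.fill_diagonal(m, 1.0)
        a, b, _ = partition_signs(genes, corr_from(m, genes))
        assert b == frozenset({"d"})

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            genes = [f"g{i}" for i in range(n)]
            x = rng.normal(size=(n, 7))
            m = corr_from(np.corrcoef(x), genes)
            a, b, fr = partition_signs(genes, m)
            oracle_sides, oracle_agree = exhaustive_best_partition(genes, m)
            assert {a, b} == oracle_sides or fr == pytest.approx(
                1.0 - oracle_agree / sum(
                    abs(m.iloc[i, j]) for i, j in combinations(range(n), 2)
                )
            )

    def test_frustrated_triangle_reports_score(self):
        genes = list("abc")
        m = np.array([[1.0, -0.5, -0.5], [-0.5, 1.0, -0.5], [-0.5, -0.5, 1.0]])
        a, b, fr = partition_signs(genes, corr_from(m, genes))
        assert fr > 0.0


class TestSummariesAndComparison:
    def _module(self, genes, side_a, side_b):
        return CoexpressionModule(
            module_id="m", cell_type="monocyte", source_subgroup="CC4-S",
            genes=frozenset(genes), side_a=frozenset(side_a), side_b=frozenset(side_b),
        )

    def test_constant_within_a_median(self):
        genes = list("abcd")
        m = corr_from(np.full((4, 4), 0.6), genes)
        np.fill_diagonal(m.values, 1.0)
        mod = self._module(genes, genes, [])
        out = module_summaries(mod, {"control": _cm(m, "control")})
        assert out.loc["control", "median_within_a"] == pytest.approx(0.6)
        assert np.isnan(out.loc["control", "median_within_b"])

    def test_matches_enumerated_pair_medians(self, rng):
        genes = [f"g{i}" for i in range(7)]
        m = _null_corr(genes, rng)
        mod = self._module(genes, genes[:4], genes[4:])
        out = module_summaries(mod, {"x": _cm(m, "x")})
        wa = np.median([m.loc[a, b] for a, b in combinations(sorted(genes[:4]), 2)])
        ab = np.median([m.loc[a, b] for a, b in product(sorted(genes[:4]), sorted(genes[4:]))])
        assert out.loc["x", "median_within_a"] == pytest.approx(wa)
        assert out.loc["x", "median_a_b"] == pytest.approx(ab)

    def test_relabel_sides_swaps_medians(self, rng):
        genes = [f"g{i}" for i in range(6)]
        m = _null_corr(genes, rng)
        m1 = self._module(genes, genes[:3], genes[3:])
        m2 = self._module(genes, genes[3:], genes[:3])
        o1 = module_summaries(m1, {"x": _cm(m, "x")})
        o2 = module_summaries(m2, {"x": _cm(m, "x")})
        assert o1.loc["x", "median_within_a"] == o2.loc["x", "median_within_b"]
        assert o1.loc["x", "median_a_b"] == pytest.approx(o2.loc["x", "median_a_b"])

    def test_identical_matrices_p_one(self, rng):
        genes = [f"g{i}" for i in range(6)]
        m = _null_corr(genes, rng)
        mod = self._module(genes, genes, [])
        assert compare_module_correlations(mod, _cm(m, "x"), _cm(m.copy(), "y")) == 1.0

    def test_matches_exact_signed_rank_enumeration(self, rng):
        """Oracle: full enumeration of sign assignments for <= 10 pairs."""
        genes = [f"g{i}" for i in range(5)]  # 10 within pairs
        mx, my = _null_corr(genes, rng), _null_corr(genes, rng)
        mod = self._module(genes, genes, [])
        p = compare_module_correlations(mod, _cm(mx, "x"), _cm(my, "y"))
        d = np.array(
            [mx.loc[a, b] - my.loc[a, b] for a, b in combinations(genes, 2)]
        )
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        n = len(d)
        ws = []
        for code in range(1 << n):
            signs = [(code >> k) & 1 for k in range(n)]
            ws.append(sum(r for r, s in zip(ranks, signs) if s))
        ws = np.array(ws)
        mean_w = n * (n + 1) / 4
        p_exact = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
        assert p == pytest.approx(p_exact, rel=1e-9)
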