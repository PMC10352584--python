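"""Variant filtering, association against cohort expectation, segregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from haeseq.variants import (
    VariantRecord,
    associate,
    chisq_vs_expected,
    cohort_frequency,
    filter_deleterious,
    min_achievable_p,
    segregation_check,
)
from haeseq.variants import testable_set as restricted_testable_set


def variant(**kw):
    base = dict(
        chrom="1", pos=100, ref="A", alt="G", gene="FXII",
        consequence="missense", cadd=25.0,
        polyphen_hvar="deleterious", polyphen_hdiv="deleterious", sift="benign",
        population_frequency=0.01,
    )
    base.update(kw)
    return VariantRecord(**base)


class TestFilter:
    @pytest.mark.parametrize(
        "kw,kept",
        [
            (dict(cadd=19.0, population_frequency=0.01), True),
            (dict(cadd=18.0, sift="deleterious"), False),  # strict "> 18"
            (dict(consequence="nonsense", cadd=0.0, population_frequency=0.06), False),
            (dict(consequence="frameshift", cadd=0.0, population_frequency=0.0), True),
            (dict(polyphen_hvar="benign", polyphen_hdiv="benign"), False),  # <2 predictors
            (dict(consequence="synonymous"), False),
        ],
    )
    def test_rule(self, kw, kept):
        assert (filter_deleterious([variant(**kw)]) != []) is kept

    def test_missing_frequency_treated_as_novel_and_flagged(self):
        v = variant(population_frequency=None)
        assert filter_deleterious([v]) == [v]
        assert v.frequency_missing

    @given(
        cadd=st.floats(0, 50, allow_nan=False),
        bump=st.floats(0, 20, allow_nan=False),
        freq=st.floats(0, 0.2, allow_nan=False),
        drop=st.floats(0, 0.2, allow_nan=False),
    )
    def test_monotone_in_cadd_and_frequency(self, cadd, bump, freq, drop):
        v1 = variant(cadd=cadd, population_frequency=freq)
        v2 = variant(cadd=cadd + bump, population_frequency=max(freq - drop, 0.0))
        if filter_deleterious([v1]):
            assert filter_deleterious([v2])


class TestFrequencies:
    def test_examples(self):
        ids = [f"i{k}" for k in range(10)]
        v = variant(genotypes={i: 0 for i in ids})
        assert cohort_frequency(v, ids) == 0.0
        v = variant(genotypes={"a": 0, "b": 1, "c": 1, "d": 2})
        assert cohort_frequency(v, ["a", "b", "c", "d"]) == 0.5

    def test_matches_counting_oracle(self, rng):
        ids = [f"i{k}" for k in range(50)]
        g = {i: int(rng.integers(0, 3)) for i in ids}
        g[ids[0]] = None
        v = variant(genotypes=g)
        typed = [i for i in ids if g[i] is not None]
        assert cohort_frequency(v, ids) == sum(g[i] for i in typed) / (2 * len(typed))

    def test_all_missing_raises(self):
        v = variant(genotypes={"a": None})
        with pytest.raises(ValueError):
            cohort_frequency(v, ["a"])


class TestChiSquare:
    def test_expectation_met_gives_zero(self):
        ids = [f"i{k}" for k in range(25)]
        # 10 alt among 50 alleles at f = 0.2 sits exactly at expectation
        genotypes = {i: (1 if k < 10 else 0) for k, i in enumerate(ids)}
        res = chisq_vs_expected(variant(genotypes=genotypes), ids, 0.2)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        ids = [f"i{k}" for k in range(25)]
        genotypes = {i: (1 if k < 20 else 0) for k, i in enumerate(ids)}
        res = chisq_vs_expected(variant(genotypes=genotypes), ids, 0.2)
        # (20-10)^2/10 + (30-40)^2/40 = 12.5
        assert res.chi_square == pytest.approx(12.5)
        assert res.p_value == pytest.approx(stats.chi2.sf(12.5, 1))

    def test_degenerate_frequency_untestable(self):
        ids = ["a", "b"]
        res = chisq_vs_expected(variant(genotypes={"a": 0, "b": 0}), ids, 0.0)
        assert not res.testable and np.isnan(res.p_value)


class TestTestableSet:
    def test_single_variant_threshold(self):
        # n=20 alleles at f=0.25: extreme chi2 clears 0.05 easily
        v = variant(genotypes={f"i{k}": (1 if k < 5 else 0) for k in range(10)})
        kept, alpha = restricted_testable_set([v], 10, [f"i{k}" for k in range(10)])
        assert kept == [v] and alpha == 0.05

    def test_tiny_subgroup_untestable(self):
        # one individual (2 alleles) at f=0.5: extreme chi2 = 2, p ~ 0.157
        assert min_achievable_p(2, 0.5) == pytest.approx(stats.chi2.sf(2.0, 1))
        v = variant(genotypes={"a": 1, "b": 1})
        kept, _ = restricted_testable_set([v], 1, ["a", "b"])
        assert kept == []

    def test_prefix_rule_matches_brute_force(self, rng):
        ids = [f"i{k}" for k in range(40)]
        vs = []
        for k in range(20):
            f = float(rng.uniform(0.01, 0.5))
            vs.append(
                variant(pos=100 + k, genotypes={i: int(rng.binomial(2, f)) for i in ids})
            )
        n_sub = 12
        kept, alpha = restricted_testable_set(vs, n_sub, ids)
        # oracle: try every k, check the sorted prefix condition directly
        ps = sorted(
            min_achievable_p(2 * n_sub, cohort_frequency(v, ids)) for v in vs
        )
        best_k = 0
        for k in range(len(ps), 0, -1):
            if all(p < 0.05 / k for p in ps[:k]):
                best_k = k
                break
        assert len(kept) == best_k
        if best_k:
            assert alpha == pytest.approx(0.05 / best_k)
            # fixed point: every member achievable below alpha, no larger prefix
            for v in kept:
                assert min_achievable_p(2 * n_sub, cohort_frequency(v, ids)) < alpha
            if best_k < len(ps):
                assert not all(p < 0.05 / (best_k + 1) for p in ps[: best_k + 1])


class TestAssociation:
    def test_null_cohort_rarely_significant(self, rng):
        ids = [f"i{k}" for k in range(60)]
        sub = {"severe": ids[:20], "mild": ids[20:40]}
        hits = 0
        for s in range(40):
            r = np.random.default_rng(s)
            vs = [
                variant(pos=100 + k, genotypes={i: int(r.binomial(2, f)) for i in ids})
                for k, f in enumerate(r.uniform(0.05, 0.5, size=10))
            ]
            out = associate(vs, sub, ids)
            hits += out.groupby("variant")["significant"].any().any()
        assert hits / 40 <= 0.12  # family-wise ~0.05 plus Monte-Carlo slack

    def test_planted_shift_detected(self, rng):
        ids_ctrl = [f"c{k}" for k in range(50)]
        ids_sev = [f"s{k}" for k in range(50)]
        ids_mild = [f"m{k}" for k in range(50)]
        genotypes = {}
        for i in ids_ctrl + ids_mild:
            genotypes[i] = int(rng.binomial(2, 0.1))
        for i in ids_sev:
            genotypes[i] = int(rng.binomial(2, 0.5))
        v = variant(genotypes=genotypes)
        out = associate([v], {"severe": ids_sev, "mild": ids_mild},
                        ids_ctrl + ids_sev + ids_mild)
        assert out.set_index("subgroup").loc["severe", "significant"]

    def test_genotype_unit_runs(self, rng):
        ids = [f"i{k}" for k in range(30)]
        v = variant(genotypes={i: int(rng.binomial(2, 0.3)) for i in ids})
        out = associate([v], {"severe": ids[:15]}, ids, unit="genotype")
        assert (out["n_alleles"] == 15).all()


class TestSegregation:
    def test_examples(self):
        labels = {"s1": "severe", "s2": "severe", "m1": "mild", "m2": "mild"}
        assert segregation_check({"s1": 1, "s2": 2, "m1": 0, "m2": 0}, labels) == "consistent_severe"
        assert segregation_check({"s1": 0, "s2": 0, "m1": 1, "m2": 1}, labels) == "consistent_mild"
        assert segregation_check({"s1": 1, "s2": 2, "m1": 1, "m2": 0}, labels) == "inconsistent"
        assert segregation_check({"s1": 1, "s2": None, "m1": 0, "m2": 0}, labels) == "inconsistent"
        with pytest.raises(ValueError):
            segregation_check({"s1": 1, "m1": 0, "m2": 0}, {"s1": "severe", "m1": "mild", "m2": "mild"})

    def test_random_families_match_enumeration_oracle(self, rng):
        labels = {"s1": "severe", "s2": "severe", "s3": "severe", "m1": "mild", "m2": "mild"}
        for _ in range(100):
            genos = {m: int(rng.integers(0, 3)) for m in labels}
            call = segregation_check(genos, labels)
            carriers = {m for m, g in genos.items() if g >= 1}
            severe = {m for m, s in labels.items() if s == "severe"}
            mild = set(labels) - severe
            if carriers == severe:
                assert call == "consistent_severe"
            elif carriers == mild:
                assert call == "consistent_mild"
            else:
                assert call == "inconsistent"


def test_vcf_round_trip(tmp_path, rng):
    from haeseq.io import read_variants, write_variant_annotations, write_variants_vcf

    ids = [f"i{k}" for k in range(8)]
    vs = [
        variant(pos=101, genotypes={i: int(rng.integers(0, 3)) for i in ids}),
        variant(pos=202, ref="T", alt="C", gene="KNG1", consequence="nonsense",
                population_frequency=None,
                genotypes={**{i: 0 for i in ids}, ids[0]: None}),
    ]
    write_variants_vcf(vs, tmp_path / "v.vcf", ids)
    write_variant_annotations(vs, tmp_path / "v.tsv")
    back = read_variants(tmp_path / "v.vcf", tmp_path / "v.tsv")
    by_key = {v.key: v for v in back}
    for v in vs:
        w = by_key[v.key]
        assert w.genotypes == v.genotypes
        assert w.gene == v.gene and w.consequence == v.consequence
        assert w.population_frequency == v.population_frequency
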