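"""Synthetic cohort generator: determinism, marginals, copula calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haeseq.normalize import collapse_replicates
from haeseq.simulate import (
    ClinicalModel,
    DEEffect,
    ModuleSpec,
    SimulationConfig,
    VariantSpec,
    count_scale_corr,
    loading_for_target_corr,
    simulate_clinical,
    simulate_cohort,
    simulate_counts,
    simulate_variants,
)

MU = 300.0


def _mono_cfg(**kw):
    base = dict(
        seed=11, n_controls=8, n_mild=8, n_severe=8, n_genes=24,
        cell_types=("monocyte",),
        nb_mean_log_range=(np.log(MU), np.log(MU)),
    )
    base.update(kw)
    return SimulationConfig(**base)


def _module(genes, loading, sides=None):
    sides = sides or {g: "A" for g in genes}
    return ModuleSpec(
        gene_ids=tuple(genes), side_of_gene=sides,
        loading_per_subgroup={"control": loading, "mild": loading, "severe": loading},
    )


class TestClinical:
    def test_determinism_and_strata_sides(self):
        cfg = _mono_cfg()
        r1 = simulate_clinical(cfg)
        r2 = simulate_clinical(cfg)
        assert r1 == r2
        for p in r1:
            if p.patient_id.startswith("PS"):
                assert p.attacks_last_year >= 5
            elif p.patient_id.startswith("PM"):
                assert p.attacks_last_year < 5
            else:
                assert p.attacks_last_year is None

    def test_no_severe_stratum(self):
        cfg = _mono_cfg(n_severe=0)
        recs = simulate_clinical(cfg)
        assert all(
            (r.attacks_last_year or 0) < 5 for r in recs if r.role == "patient"
        )

    def test_onset_distribution_right_skewed(self):
        cfg = _mono_cfg(n_controls=0, n_mild=10_000, n_severe=0)
        ages = np.array(
            [r.onset_age_years for r in simulate_clinical(cfg)], dtype=float
        )
        assert stats.skew(ages) > 0

    def test_negative_group_size_rejected(self):
        with pytest.raises(ValueError):
            _mono_cfg(n_mild=-1)


class TestCounts:
    def test_nb_marginal_calibration(self):
        # loading-free genes must match the configured NB mean/dispersion
        cfg = _mono_cfg(seed=2, n_controls=3334, n_mild=0, n_severe=0, n_genes=3,
                        replicates_per_cell_type=1, nb_dispersion=0.1)
        counts = simulate_counts(simulate_clinical(cfg), cfg)["monocyte"].counts
        x = counts.to_numpy(float)
        mean = x.mean(axis=1)
        var = x.var(axis=1)
        assert np.allclose(mean, MU, rtol=0.05)
        assert np.allclose(var, MU + 0.1 * MU**2, rtol=0.15)

    def test_independence_limit(self):
        cfg = _mono_cfg(seed=3, n_controls=500, n_mild=0, n_severe=0, n_genes=12,
                        module_specs=(_module([f"G{i:03d}" for i in range(2, 10)], 0.0),))
        cm = collapse_replicates(simulate_counts(simulate_clinical(cfg), cfg)["monocyte"])
        r = np.corrcoef(cm.counts.to_numpy(float))
        iu = np.triu_indices(len(r), 1)
        assert np.median(np.abs(r[iu])) < 0.05

    def test_copula_hits_target_correlation(self):
        load = loading_for_target_corr(0.8, MU, 0.1, 3)
        genes = [f"G{i:03d}" for i in range(2, 10)]
        cfg = _mono_cfg(seed=4, n_controls=500, n_mild=0, n_severe=0, n_genes=16,
                        module_specs=(_module(genes, load),))
        cm = collapse_replicates(simulate_counts(simulate_clinical(cfg), cfg)["monocyte"])
        r = np.corrcoef(cm.counts.loc[genes].to_numpy(float))
        iu = np.triu_indices(len(genes), 1)
        assert 0.75 <= np.median(r[iu]) <= 0.85

    def test_ab_pairs_negative(self):
        genes = [f"G{i:03d}" for i in range(2, 7)]
        sides = {g: ("A" if i < 3 else "B") for i, g in enumerate(genes)}
        cfg = _mono_cfg(seed=5, n_controls=500, n_mild=0, n_severe=0, n_genes=10,
                        module_specs=(_module(genes, 0.8, sides),))
        cm = collapse_replicates(simulate_counts(simulate_clinical(cfg), cfg)["monocyte"])
        sub = cm.counts.loc[genes].to_numpy(float)
        r = np.corrcoef(sub)
        cross = [r[i, j] for i in range(3) for j in range(3, 5)]
        assert np.median(cross) < 0

    def test_planted_de_and_nmd_shift_means(self):
        cfg = _mono_cfg(seed=6, n_controls=40, n_mild=0, n_severe=40,
                        de_effects=(DEEffect("G010", "severe", 2.0),),
                        nmd_factor=0.5,
                        clinical=ClinicalModel(nmd_prob=1.0))
        patients = simulate_clinical(cfg)
        cm = collapse_replicates(simulate_counts(patients, cfg)["monocyte"])
        grp = cm.samples["group"]
        sev = grp.index[grp == "CC4-S"]
        ctl = grp.index[grp == "control"]
        ratio = cm.counts.loc["G010", sev].mean() / cm.counts.loc["G010", ctl].mean()
        assert ratio == pytest.approx(4.0, rel=0.25)
        nmd_ratio = (
            cm.counts.loc["SERPING1", sev].mean() / cm.counts.loc["SERPING1", ctl].mean()
        )
        assert nmd_ratio == pytest.approx(0.5, rel=0.25)

    def test_module_gene_outside_panel_rejected(self):
        with pytest.raises(ValueError, match="not in panel"):
            _mono_cfg(module_specs=(_module(["NOPE1", "NOPE2"], 0.5),))

    def test_replicates_share_individual_latent(self):
        # replicate-to-replicate correlation within an individual exceeds the
        # across-individual correlation for a dispersed gene
        cfg = _mono_cfg(seed=7, n_controls=200, n_mild=0, n_severe=0, n_genes=4,
                        nb_dispersion=0.3)
        cm = simulate_counts(simulate_clinical(cfg), cfg)["monocyte"]
        wide = cm.counts.iloc[1].to_numpy(float).reshape(200, 3)
        within = np.corrcoef(wide[:, 0], wide[:, 1])[0, 1]
        across = np.corrcoef(wide[:-1, 0], wide[1:, 0])[0, 1]
        assert within > 0.5 > abs(across)


class TestVariants:
    def test_frequency_extremes(self):
        cfg = _mono_cfg(variant_specs=(VariantSpec("FXII", 0.0), VariantSpec("KNG1", 1.0)))
        patients = simulate_clinical(cfg)
        v0, v1 = simulate_variants(patients, cfg)
        assert set(v0.genotypes.values()) == {0}
        assert set(v1.genotypes.values()) == {2}

    def test_binomial_expectation(self):
        cfg = _mono_cfg(seed=8, n_controls=10_000, n_mild=0, n_severe=0,
                        variant_specs=(VariantSpec("FXII", 0.3),))
        patients = simulate_clinical(cfg)
        (v,) = simulate_variants(patients, cfg)
        f = np.mean(list(v.genotypes.values())) / 2
        assert 0.29 <= f <= 0.31

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            VariantSpec("FXII", 1.5)


class TestBundle:
    def test_bundle_consistency_and_determinism(self):
        cfg = _mono_cfg(seed=9, variant_specs=(VariantSpec("FXII", 0.2),),
                        module_specs=(_module([f"G{i:03d}" for i in range(2, 8)], 0.6),),
                        de_effects=(DEEffect("G010", "severe", 1.0),))
        b1 = simulate_cohort(cfg)
        b2 = simulate_cohort(cfg)
        ids = {p.patient_id for p in b1.patients}
        for cm in b1.counts.values():
            assert set(cm.samples["individual_id"]) == ids
        assert b1.truth["de_effects"] == [
            {"gene": "G010", "contrast": "severe", "log2fc": 1.0}
        ]
        assert b1.truth == b2.truth
        for cell in b1.counts:
            pd.testing.assert_frame_equal(b1.counts[cell].counts, b2.counts[cell].counts)
        assert [v.genotypes for v in b1.variants] == [v.genotypes for v in b2.variants]

    def test_closed_form_corr_monotone(self):
        vals = [count_scale_corr(r, MU, 0.1, 3) for r in (0.1, 0.4, 0.7, 0.95)]
        assert all(np.diff(vals) > 0)
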