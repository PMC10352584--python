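"""Calibration and recovery experiments at the study's design scale.

Each function runs one self-contained simulation experiment through the
package's public machinery — generate a seeded synthetic cohort with (or
without) a planted effect, run the corresponding analysis stage, and measure
how well the truth is recovered.  They power both the acceptance test suite
and ``scripts/acceptance.py``.

The experiments use the study's transcriptomic design: 20 individuals per
subgroup, cultured triplicates, NB counts with dispersion 0.1; module
experiments pin the gene mean at 300 (mid-range for a targeted myeloid
panel) because the copula loading that yields a stated Pearson target is
mean-dependent.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from haeseq import de as de_mod
from haeseq.clinical import PatientRecord
from haeseq.coexpression import (
    compare_module_correlations,
    detect_modules,
    pairwise_correlations,
)
from haeseq.dysregulation import dysregulation_counts
from haeseq.normalize import collapse_replicates, size_factors, vst_transform
from haeseq.simulate import (
    ClinicalModel,
    DEEffect,
    ModuleSpec,
    SimulationConfig,
    loading_for_target_corr,
    simulate_clinical,
    simulate_counts,
)

MU = 300.0
DISPERSION = 0.1
REPS = 3
N_PER_GROUP = 20


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _fixed_mean_config(seed: int, **kw) -> SimulationConfig:
    base = dict(
        seed=seed,
        n_controls=N_PER_GROUP,
        n_mild=N_PER_GROUP,
        n_severe=N_PER_GROUP,
        cell_types=("monocyte",),
        replicates_per_cell_type=REPS,
        nb_mean_log_range=(float(np.log(MU)), float(np.log(MU))),
        nb_dispersion=DISPERSION,
    )
    base.update(kw)
    return SimulationConfig(**base)


# --------------------------------------------------------------- DE (crit. 3)


def de_null_calibration(seed: int, n_genes: int = 500, n_reps: int = 4) -> dict:
    """Type-I error of the NB Wald test on null cohorts (20 vs 20)."""
    n = N_PER_GROUP
    p_all = []
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        lam = rng.gamma(1 / DISPERSION, DISPERSION, size=(n_genes, 2 * n)) * 100.0
        counts = pd.DataFrame(
            rng.poisson(lam),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(2 * n)],
        )
        cols = list(counts.columns)
        res = de_mod.nb_wald_test(counts, cols[:n], cols[n:])
        p_all.extend(r.p_value for r in res)
    p = np.asarray(p_all, dtype=float)
    p = p[np.isfinite(p)]
    return {
        "n_tests": int(p.size),
        "type1_at_05": float(np.mean(p < 0.05)),
        "calls_at_bonferroni_per_500": float(np.sum(p < 3.65e-4) / n_reps),
    }


def de_lfc_recovery(seed: int, n_genes: int = 50, log2fc: float = 2.0) -> dict:
    """Median estimated log2 fold change for genes planted at ``log2fc``."""
    n = N_PER_GROUP
    rng = np.random.default_rng(_child_seeds(seed, 1)[0])
    lam_a = rng.gamma(1 / DISPERSION, DISPERSION, size=(n_genes, n)) * 100.0
    lam_b = rng.gamma(1 / DISPERSION, DISPERSION, size=(n_genes, n)) * 100.0 * 2.0**log2fc
    counts = pd.DataFrame(
        np.concatenate([rng.poisson(lam_a), rng.poisson(lam_b)], axis=1),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(2 * n)],
    )
    cols = list(counts.columns)
    res = de_mod.nb_wald_test(
        counts, cols[:n], cols[n:], pd.Series(1.0, index=counts.columns)
    )
    return {"median_lfc": float(np.median([r.log2_fold_change for r in res]))}


# ---------------------------------------------------------- modules (crit. 4)


def _module_cohort(seed, genes, loadings, n_genes=70, sides=None):
    sides = sides or {g: "A" for g in genes}
    ms = ModuleSpec(
        gene_ids=tuple(genes), side_of_gene=sides, loading_per_subgroup=loadings
    )
    cfg = _fixed_mean_config(seed, n_genes=n_genes, module_specs=(ms,))
    patients = simulate_clinical(cfg)
    cm = collapse_replicates(simulate_counts(patients, cfg)["monocyte"])
    factors = size_factors(cm.counts)
    vst = vst_transform(cm.counts, factors)
    groups = cm.samples["group"]
    corr = {
        g: pairwise_correlations(vst, list(groups.index[groups == g]), g)
        for g in ("control", "CC4-M", "CC4-S")
    }
    return corr


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def module_recovery(seed: int, n_seeds: int = 50, target_r: float = 0.8) -> dict:
    """Recovery of an 8-gene module planted in CC4-S only (|r| = target)."""
    load = loading_for_target_corr(target_r, MU, DISPERSION, REPS)
    genes = [f"G{i:03d}" for i in range(10, 18)]
    truth = frozenset(genes)
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        corr = _module_cohort(
            s, genes, {"control": 0.0, "mild": 0.0, "severe": load}
        )
        mods = detect_modules(corr)
        best = max((_jaccard(m.genes, truth) for m in mods), default=0.0)
        hits += best >= 0.8
    return {"n_seeds": n_seeds, "recovery_rate": hits / n_seeds}


def module_specificity(seed: int, n_seeds: int = 50, target_r: float = 0.8) -> dict:
    """Rejection of the same module planted identically in all subgroups."""
    load = loading_for_target_corr(target_r, MU, DISPERSION, REPS)
    genes = [f"G{i:03d}" for i in range(10, 18)]
    truth = frozenset(genes)
    rejected = 0
    for s in _child_seeds(seed, n_seeds):
        corr = _module_cohort(
            s, genes, {"control": load, "mild": load, "severe": load}
        )
        mods = detect_modules(corr)
        rejected += not any(_jaccard(m.genes, truth) >= 0.5 for m in mods)
    return {"n_seeds": n_seeds, "rejection_rate": rejected / n_seeds}


# --------------------------------------- differential correlation (crit. 5)


def diffcorr_power(
    seed: int, n_seeds: int = 100, r_high: float = 0.7, r_low: float = 0.2
) -> dict:
    """Power of the paired Wilcoxon to see r~0.7 vs r~0.2 on a 10-gene module."""
    from haeseq.coexpression import CoexpressionModule

    load_hi = loading_for_target_corr(r_high, MU, DISPERSION, REPS)
    load_lo = loading_for_target_corr(r_low, MU, DISPERSION, REPS)
    genes = [f"G{i:03d}" for i in range(10, 20)]
    module = CoexpressionModule(
        module_id="m", cell_type="monocyte", source_subgroup="CC4-S",
        genes=frozenset(genes), side_a=frozenset(genes), side_b=frozenset(),
    )
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        corr = _module_cohort(
            s, genes, {"control": load_lo, "mild": 0.0, "severe": load_hi},
            n_genes=25,
        )
        p = compare_module_correlations(module, corr["CC4-S"], corr["control"])
        hits += p < 0.01
    return {"n_seeds": n_seeds, "power_at_01": hits / n_seeds}


# ------------------------------------------------- dysregulation (crit. 7)


def dysregulation_null(seed: int, n_reps: int = 30, n_genes: int = 200,
                       n_controls: int = 40, alpha: float = 0.05) -> dict:
    """Leave-one-out control counts on Gaussian null data vs G*alpha."""
    counts = []
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        cols = [f"c{i}" for i in range(n_controls)]
        x = pd.DataFrame(
            rng.normal(8.0, 0.5, size=(n_genes, n_controls)),
            index=[f"g{i}" for i in range(n_genes)], columns=cols,
        )
        prof = dysregulation_counts(x, cols, alpha=alpha)
        counts.extend(prof.per_individual.values)
    return {
        "expected": n_genes * alpha,
        "mean_count": float(np.mean(counts)),
        "ratio": float(np.mean(counts) / (n_genes * alpha)),
    }


def dysregulation_ordering(seed: int, n_seeds: int = 100) -> dict:
    """Planted dysregulation reproduces severe > mild > control counts."""
    effects = tuple(
        [DEEffect(f"G{i:03d}", "patient", 2.0) for i in range(20, 26)]
        + [DEEffect(f"G{i:03d}", "severe", 2.0) for i in range(30, 36)]
    )
    per_group: dict[str, list] = {"control": [], "CC4-M": [], "CC4-S": []}
    for s in _child_seeds(seed, n_seeds):
        cfg = _fixed_mean_config(s, n_genes=60, de_effects=effects)
        patients = simulate_clinical(cfg)
        cm = collapse_replicates(simulate_counts(patients, cfg)["monocyte"])
        factors = size_factors(cm.counts)
        vst = vst_transform(cm.counts, factors)
        groups = cm.samples["group"]
        ctrl = list(groups.index[groups == "control"])
        prof = dysregulation_counts(
            vst, ctrl, alpha=3.65e-4, min_mean=30.0,
            normalized_counts=cm.counts / factors,
        )
        for g in per_group:
            per_group[g].extend(prof.per_individual[groups == g].values)
    return {g: float(np.median(v)) for g, v in per_group.items()} | {
        "mean_control": float(np.mean(per_group["control"])),
        "mean_mild": float(np.mean(per_group["CC4-M"])),
        "mean_severe": float(np.mean(per_group["CC4-S"])),
    }


# ------------------------------------------------------- SERPING1 (crit. 8)


def nmd_direction(seed: int, n_seeds: int = 100, n_per_class: int = 10) -> dict:
    """Fraction of cohorts where NMD carriers show lower SERPING1 medians."""
    correct = 0
    for s in _child_seeds(seed, n_seeds):
        patients = [
            PatientRecord(
                patient_id=f"P{i:02d}", role="patient", onset_age_years=10,
                attacks_avg_5y=1.0, attacks_max_year=2.0, attacks_last_year=0.0,
                serping1_class="nmd" if i < n_per_class else "non_nmd",
            )
            for i in range(2 * n_per_class)
        ]
        cfg = _fixed_mean_config(
            s, n_controls=0, n_mild=0, n_severe=0, n_genes=20,
            nmd_factor=0.5, serping1_log_mean=float(np.log(MU)),
        )
        cm = collapse_replicates(simulate_counts(patients, cfg)["monocyte"])
        factors = size_factors(cm.counts)
        vst = vst_transform(cm.counts, factors)
        groups = pd.Series("CC4-M", index=vst.columns)
        classes = pd.Series(
            {c: ("nmd" if i < n_per_class else "non_nmd")
             for i, c in enumerate(vst.columns)}
        )
        out = de_mod.serping1_nmd_contrast(vst, groups, classes)
        correct += out["median_patient_nmd"] < out["median_patient_non_nmd"]
    return {"n_seeds": n_seeds, "direction_rate": correct / n_seeds}
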