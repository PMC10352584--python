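"""Two-group negative-binomial Wald differential expression with filters.

Each gene is modelled as NB2: ``y_j ~ NB(mu_j, alpha)`` with
``Var = mu + alpha * mu^2``, ``mu_j = s_j * exp(b0 + b1 * x_j)`` where
``s_j`` is the sample's size factor and ``x_j`` the group indicator.  The
per-gene dispersion ``alpha`` is estimated by profile maximum likelihood
(floored at 1e-8, i.e. effectively Poisson); ``b1`` is the natural-log fold
change, tested with a Wald statistic ``b1 / se(b1)`` against the standard
normal.  No empirical-Bayes shrinkage is applied: at ~20 individuals per
group the per-gene MLE is adequate and keeps every step testable in
isolation.

Significance additionally requires a minimal normalized mean (default 30) in
*both* groups — small counts otherwise produce unstable, biased-low p-values
— and, when MAD-based outlier flagging removes samples, the post-removal
p-value is the one that must pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from haeseq.normalize import CountMatrix, size_factors as _size_factors, vst_transform

DEFAULT_ALPHA = 3.65e-4  # Bonferroni-corrected 0.05 for a ~136-gene panel
DEFAULT_MIN_MEAN = 30.0
DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 50.0


@dataclass
class DEResult:
    """Per-gene outcome of the two-group NB Wald test."""

    gene_id: str
    base_mean_a: float
    base_mean_b: float
    log2_fold_change: float
    wald_statistic: float
    p_value: float
    dispersion: float
    passes_min_mean: bool = False
    outlier_samples_removed: list[str] = field(default_factory=list)
    p_value_pre_removal: Optional[float] = None
    significant: bool = False


def _nb_nll(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Negative NB2 log-likelihood (constant terms in y included)."""
    if alpha < 1e-10:
        # Poisson limit, numerically stable
        return float(np.sum(mu - y * np.log(np.maximum(mu, 1e-300)) + special.gammaln(y + 1)))
    inv = 1.0 / alpha
    amu = alpha * mu
    ll = (
        special.gammaln(y + inv)
        - special.gammaln(inv)
        - special.gammaln(y + 1)
        + y * np.log(amu / (1.0 + amu))
        - inv * np.log1p(amu)
    )
    return float(-np.sum(ll))


def _fit_group_mean(y: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """MLE of the group mean m (mu_j = s_j * m) for fixed dispersion.

    Solves the score equation sum (y - mu) / (1 + alpha*mu) = 0 in log m by
    safeguarded Newton iteration; for alpha -> 0 the solution is the
    offset-weighted mean sum(y)/sum(s).
    """
    ty = y.sum()
    if ty == 0:
        return 0.0
    logm = np.log(ty / s.sum())
    for _ in range(50):
        mu = s * np.exp(logm)
        denom = 1.0 + alpha * mu
        score = np.sum((y - mu) / denom)
        # derivative of score wrt log m
        dscore = -np.sum(mu * (1.0 + alpha * y) / denom**2)
        if dscore == 0:
            break
        step = score / dscore
        step = np.clip(step, -2.0, 2.0)
        logm -= step
        if abs(step) < 1e-10:
            break
    return float(np.exp(logm))


def _profile_nll(log_alpha, y_a, s_a, y_b, s_b):
    """Cox-Reid adjusted profile negative log-likelihood in log-dispersion.

    The CR term 0.5*log det(X'WX) corrects the downward bias of the plain
    profile MLE that comes from estimating the two group means; without it
    the Wald test is noticeably anti-conservative at ~20 samples per group.
    """
    alpha = float(np.exp(log_alpha))
    m_a = _fit_group_mean(y_a, s_a, alpha)
    m_b = _fit_group_mean(y_b, s_b, alpha)
    nll = 0.0
    cr = 0.0
    for y, s, m in ((y_a, s_a, m_a), (y_b, s_b, m_b)):
        if y.size and m > 0:
            mu = s * m
            nll += _nb_nll(y, mu, alpha)
            cr += 0.5 * np.log(np.sum(mu / (1.0 + alpha * mu)))
        elif y.size:
            nll += _nb_nll(y, np.full_like(s, 1e-300), alpha)
    return nll + cr


def _fit_gene(y_a, s_a, y_b, s_b):
    """Profile-ML dispersion, group means and Wald statistic for one gene.

    Returns (m_a, m_b, alpha, log2fc, wald_z, p).  p is NaN when either
    group has zero total counts (the log fold change is unbounded there).
    """
    res = optimize.minimize_scalar(
        _profile_nll,
        bounds=(np.log(DISPERSION_FLOOR), np.log(DISPERSION_CEIL)),
        args=(y_a, s_a, y_b, s_b),
        method="bounded",
        options={"xatol": 1e-3},
    )
    alpha = float(np.exp(res.x))
    m_a = _fit_group_mean(y_a, s_a, alpha)
    m_b = _fit_group_mean(y_b, s_b, alpha)
    if m_a == 0.0 or m_b == 0.0:
        lfc = np.inf if m_b > m_a else (-np.inf if m_a > m_b else 0.0)
        return m_a, m_b, alpha, lfc, np.nan, np.nan
    mu_a, mu_b = s_a * m_a, s_b * m_b
    info_a = np.sum(mu_a / (1.0 + alpha * mu_a))
    info_b = np.sum(mu_b / (1.0 + alpha * mu_b))
    se = np.sqrt(1.0 / info_a + 1.0 / info_b)
    b1 = np.log(m_b) - np.log(m_a)
    z = b1 / se
    p = 2.0 * stats.norm.sf(abs(z))
    return m_a, m_b, alpha, b1 / np.log(2.0), float(z), float(p)


def nb_wald_test(
    counts: pd.DataFrame,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    factors: Optional[pd.Series] = None,
) -> list[DEResult]:
    """NB Wald test of group B versus group A for every gene.

    ``counts`` must be replicate-collapsed (one column per individual);
    each group needs at least two members.  Positive ``log2_fold_change``
    means higher expression in group B.  All-zero genes yield NaN p-values
    and never pass the mean filter.
    """
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs >= 2 individuals")
    if set(a_ids) & set(b_ids):
        raise ValueError("groups overlap")
    if factors is None:
        factors = _size_factors(counts[a_ids + b_ids])
    s_a = factors.loc[a_ids].to_numpy(dtype=float)
    s_b = factors.loc[b_ids].to_numpy(dtype=float)
    ya = counts[a_ids].to_numpy(dtype=float)
    yb = counts[b_ids].to_numpy(dtype=float)
    results = []
    for i, gene in enumerate(counts.index):
        m_a, m_b, alpha, lfc, z, p = _fit_gene(ya[i], s_a, yb[i], s_b)
        base_a = float(np.mean(ya[i] / s_a))
        base_b = float(np.mean(yb[i] / s_b))
        results.append(
            DEResult(
                gene_id=str(gene),
                base_mean_a=base_a,
                base_mean_b=base_b,
                log2_fold_change=lfc,
                wald_statistic=z,
                p_value=p,
                dispersion=alpha,
            )
        )
    return results


def apply_de_filters(
    results: Iterable[DEResult],
    alpha: float = DEFAULT_ALPHA,
    min_mean: float = DEFAULT_MIN_MEAN,
) -> list[DEResult]:
    """Set ``passes_min_mean`` and ``significant`` in place and return results.

    A gene is significant iff its (post-outlier-removal) p-value is below
    ``alpha`` and both group normalized means reach ``min_mean``.
    """
    out = list(results)
    for r in out:
        r.passes_min_mean = (r.base_mean_a >= min_mean) and (r.base_mean_b >= min_mean)
        r.significant = bool(
            r.passes_min_mean and np.isfinite(r.p_value) and r.p_value < alpha
        )
    return out


def flag_outliers(
    vst_values: pd.DataFrame, group_ids: Sequence[str], k: float = 5.0
) -> dict[str, list[str]]:
    """Per-gene outlying samples within one group by the MAD rule.

    A sample is flagged for a gene when its VST value deviates from the
    within-group median by more than ``k`` median absolute deviations.
    A zero MAD (near-constant gene) flags nothing: the rule is undefined
    there and constant groups contain no gross excesses by construction.
    """
    ids = list(group_ids)
    if len(ids) < 4:
        raise ValueError("outlier flagging needs >= 4 samples in the group")
    x = vst_values[ids].to_numpy(dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        flagged = np.abs(x - med) > k * mad
    flagged[np.broadcast_to(mad == 0, flagged.shape)] = False
    out: dict[str, list[str]] = {}
    for i, gene in enumerate(vst_values.index):
        if flagged[i].any():
            out[str(gene)] = [ids[j] for j in np.flatnonzero(flagged[i])]
    return out


def differential_expression(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    alpha: float = DEFAULT_ALPHA,
    min_mean: float = DEFAULT_MIN_MEAN,
    mad_k: float = 5.0,
    remove_outliers: bool = True,
) -> pd.DataFrame:
    """Full DE stage for one contrast on a replicate-collapsed matrix.

    Runs the Wald test on all individuals, flags MAD outliers per gene within
    each group, re-tests affected genes without their outliers, and applies
    the significance filters to the post-removal p-value.  Returns a tidy
    DataFrame (one row per gene).
    """
    groups = matrix.samples["group"]
    a_ids = list(groups.index[groups == group_a])
    b_ids = list(groups.index[groups == group_b])
    factors = _size_factors(matrix.counts[a_ids + b_ids])
    results = nb_wald_test(matrix.counts, a_ids, b_ids, factors)
    results = apply_de_filters(results, alpha=alpha, min_mean=min_mean)

    if remove_outliers and len(a_ids) >= 4 and len(b_ids) >= 4:
        vst = vst_transform(matrix.counts[a_ids + b_ids], factors)
        flags_a = flag_outliers(vst, a_ids, k=mad_k)
        flags_b = flag_outliers(vst, b_ids, k=mad_k)
        by_gene = {r.gene_id: r for r in results}
        for gene in set(flags_a) | set(flags_b):
            r = by_gene[gene]
            drop = set(flags_a.get(gene, [])) | set(flags_b.get(gene, []))
            keep_a = [j for j in a_ids if j not in drop]
            keep_b = [j for j in b_ids if j not in drop]
            if len(keep_a) < 2 or len(keep_b) < 2:
                continue
            row = matrix.counts.loc[[gene]]
            redo = nb_wald_test(row, keep_a, keep_b, factors)[0]
            r.p_value_pre_removal = r.p_value
            r.p_value = redo.p_value
            r.log2_fold_change = redo.log2_fold_change
            r.wald_statistic = redo.wald_statistic
            r.outlier_samples_removed = sorted(drop)
        results = apply_de_filters(results, alpha=alpha, min_mean=min_mean)

    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "base_mean_a": r.base_mean_a,
                "base_mean_b": r.base_mean_b,
                "log2_fold_change": r.log2_fold_change,
                "wald_statistic": r.wald_statistic,
                "p_value": r.p_value,
                "p_value_pre_removal": r.p_value_pre_removal,
                "dispersion": r.dispersion,
                "passes_min_mean": r.passes_min_mean,
                "outliers_removed": ",".join(r.outlier_samples_removed),
                "significant": r.significant,
            }
            for r in results
        ]
    ).set_index("gene")


def serping1_nmd_contrast(
    vst_matrix: pd.DataFrame,
    groups: pd.Series,
    serping1_classes: pd.Series,
    gene: str = "SERPING1",
) -> dict:
    """*SERPING1* expression by variant class.

    Variants introducing premature stop codons trigger nonsense-mediated
    decay (NMD) of the transcript, so carriers of NMD-susceptible variants
    are expected to show lower *SERPING1* mRNA than carriers of other
    variant types, independent of clinical severity.  Reports per-class
    medians of the gene's VST expression and a two-sided rank-sum p-value
    for NMD vs non-NMD carriers (NaN when a class has < 2 members).
    """
    if gene not in vst_matrix.index:
        raise KeyError(f"{gene} not in the panel")
    expr = vst_matrix.loc[gene]
    ctrl = expr[groups.loc[expr.index] == "control"]
    patients = expr[groups.loc[expr.index] != "control"]
    cls = serping1_classes.reindex(patients.index).fillna("none")
    nmd = patients[cls == "nmd"]
    non_nmd = patients[cls == "non_nmd"]

    def _median(s):
        return float(np.median(s)) if len(s) else float("nan")

    p = float("nan")
    if len(nmd) >= 2 and len(non_nmd) >= 2:
        p = float(stats.mannwhitneyu(nmd, non_nmd, alternative="two-sided").pvalue)
    return {
        "median_control": _median(ctrl),
        "median_patient_all": _median(patients),
        "median_patient_nmd": _median(nmd),
        "median_patient_non_nmd": _median(non_nmd),
        "n_nmd": int(len(nmd)),
        "n_non_nmd": int(len(non_nmd)),
        "p_nmd_vs_non_nmd": p,
    }
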