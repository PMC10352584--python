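"""Per-individual dysregulated-gene counting against a control reference.

Every individual's expression of every (sufficiently expressed) gene is
compared with the range defined by the control group on the VST scale; the
number of genes falling outside that range — in either direction — is the
individual's dysregulation count.  Controls themselves are evaluated
leave-one-out against the remaining controls, so their nonzero baseline
counts are estimated without bias.  Group-wise count distributions are
compared with two-sided Mann-Whitney tests.

The single-observation test is a normal prediction-interval z-test:
``z = (x - mean(ref)) / (sd(ref) * sqrt(1 + 1/n))`` with a two-sided normal
tail.  It is the simplest "one value versus a reference group" test on a
variance-stabilized scale; with a finite reference group it is mildly
anti-conservative relative to the exact t form (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from haeseq.de import DEFAULT_ALPHA


@dataclass
class DysregulationProfile:
    """Two marginals of one boolean individual x gene dysregulation matrix."""

    per_individual: pd.Series  # index: individual, value: n dysregulated genes
    per_gene: pd.Series  # index: gene, value: n dysregulated individuals
    flags: pd.DataFrame  # genes x individuals boolean
    p_values: pd.DataFrame  # genes x individuals
    genes_tested: list[str]

    def __post_init__(self) -> None:
        if int(self.per_individual.sum()) != int(self.per_gene.sum()):
            raise AssertionError("marginal totals disagree")


def single_vs_group_test(value: float, control_values: Sequence[float]) -> float:
    """Two-sided prediction-interval p for one observation vs a reference group.

    Degenerate reference (zero spread): p=1 when the value equals the common
    reference value, else p=0 (the observation is outside any interval the
    controls can define).
    """
    ref = np.asarray(control_values, dtype=float)
    if ref.size < 3:
        raise ValueError("need >= 3 control values")
    sd = ref.std(ddof=1)
    if sd == 0:
        return 1.0 if value == ref[0] else 0.0
    z = (value - ref.mean()) / (sd * np.sqrt(1.0 + 1.0 / ref.size))
    return float(2.0 * stats.norm.sf(abs(z)))


def dysregulation_counts(
    vst_matrix: pd.DataFrame,
    control_ids: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    min_mean: float | None = None,
    normalized_counts: pd.DataFrame | None = None,
) -> DysregulationProfile:
    """Count dysregulated genes per individual and individuals per gene.

    ``vst_matrix`` is genes x individuals (replicates collapsed).  Patients
    are tested against all controls; each control against the other
    controls (leave-one-out).  When ``min_mean`` and ``normalized_counts``
    are given, genes whose control normalized mean falls below ``min_mean``
    are excluded from counting, mirroring the DE read-count filter.
    """
    ctrl = list(control_ids)
    if len(ctrl) < 4:
        raise ValueError("need >= 4 controls (leave-one-out keeps >= 3)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    genes = list(vst_matrix.index)
    if min_mean is not None and normalized_counts is not None:
        ctrl_means = normalized_counts[ctrl].mean(axis=1)
        genes = [g for g in genes if ctrl_means.loc[g] >= min_mean]
    x = vst_matrix.loc[genes]
    individuals = list(x.columns)
    ctrl_arr = x[ctrl].to_numpy(dtype=float)
    n = len(ctrl)
    pmat = np.empty((len(genes), len(individuals)))
    mean_all = ctrl_arr.mean(axis=1)
    sd_all = ctrl_arr.std(axis=1, ddof=1)
    for j, ind in enumerate(individuals):
        v = x[ind].to_numpy(dtype=float)
        if ind in ctrl:
            mask = [c for c in ctrl if c != ind]
            ref = x[mask].to_numpy(dtype=float)
            mean = ref.mean(axis=1)
            sd = ref.std(axis=1, ddof=1)
            m = n - 1
        else:
            mean, sd, m = mean_all, sd_all, n
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (v - mean) / (sd * np.sqrt(1.0 + 1.0 / m))
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.where(sd == 0, np.where(v == mean, 1.0, 0.0), p)
        pmat[:, j] = p
    p_values = pd.DataFrame(pmat, index=genes, columns=individuals)
    flags = p_values < alpha
    return DysregulationProfile(
        per_individual=flags.sum(axis=0),
        per_gene=flags.sum(axis=1),
        flags=flags,
        p_values=p_values,
        genes_tested=genes,
    )


def mann_whitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p; exact at small n without ties, else
    normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (no_ties and max(x.size, y.size) <= 8) else "asymptotic"
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        ).pvalue
    )


def compare_count_distributions(
    profile: DysregulationProfile, group_labels: pd.Series
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of per-individual counts by group.

    Compares every unordered pair of group labels present (e.g. control vs
    CC4-M, control vs CC4-S, CC4-M vs CC4-S); a group with fewer than two
    individuals is skipped with ``p = NaN``.
    """
    counts = profile.per_individual
    labels = group_labels.reindex(counts.index)
    rows = []
    groups = sorted(labels.dropna().unique())
    for ga, gb in combinations(groups, 2):
        a = counts[labels == ga]
        b = counts[labels == gb]
        if len(a) < 2 or len(b) < 2:
            p = float("nan")
        else:
            p = mann_whitney_p(a.to_numpy(), b.to_numpy())
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": len(a),
                "n_b": len(b),
                "median_a": float(a.median()) if len(a) else float("nan"),
                "median_b": float(b.median()) if len(b) else float("nan"),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
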