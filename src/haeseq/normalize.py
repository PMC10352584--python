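"""Count containers, median-of-ratios normalization, VST and PCA.

Targeted RNA-seq yields a small gene panel (~140 genes) of UMI-deduplicated
counts per sample.  Library depth is removed with the median-of-ratios size
factors that underlie DESeq-style pipelines; downstream correlation and
outlier procedures work on a monotone variance-stabilizing transform of the
normalized counts, ``log2(count / size_factor + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_SAMPLE_COLUMNS = ("individual_id", "cell_type", "replicate", "group")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample annotations.

    ``counts`` is indexed by gene id with one column per sample id;
    ``samples`` is indexed by sample id and must carry ``individual_id``,
    ``cell_type``, ``replicate`` and ``group`` columns (group in
    {'control', 'CC4-M', 'CC4-S'}).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample annotation lacks column {col!r}")
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids].copy(), self.samples.loc[ids].copy())

    def groups_of(self, sample_ids=None) -> pd.Series:
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return self.samples.loc[ids, "group"]


def size_factors(
    counts: pd.DataFrame, allow_pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factor per sample, rescaled to geometric mean 1.

    Reference genes are those with strictly positive counts in every sample;
    each sample's factor is the median over reference genes of
    ``count / geometric_mean(gene)``.  When no gene is all-positive the
    median-of-ratios reference is undefined; pass
    ``allow_pseudo_reference=True`` to fall back to a positive-count-only
    geometric mean per gene (the "poscounts" style estimator).
    """
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if all_positive.any():
        ref = x[all_positive]
        log_gm = np.mean(np.log(ref), axis=1)
        ratios = np.log(ref) - log_gm[:, None]
    elif allow_pseudo_reference:
        logs = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
        log_gm = np.nanmean(logs, axis=1)
        usable = np.isfinite(log_gm)
        if not usable.any():
            raise ValueError("matrix has no positive counts at all")
        ratios = logs[usable] - log_gm[usable, None]
    else:
        raise ValueError(
            "no gene has positive counts in every sample; rerun with "
            "allow_pseudo_reference=True to use the positive-count fallback"
        )
    log_sf = np.nanmedian(ratios, axis=0)
    log_sf = log_sf - np.mean(log_sf)  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def vst_transform(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Monotone variance-stabilizing transform ``log2(count/factor + 1)``.

    Zero counts map to zero exactly; the transform is strictly increasing in
    the count for a fixed factor.
    """
    f = factors.loc[counts.columns].to_numpy(dtype=float)
    if (f <= 0).any():
        raise ValueError("size factors must be positive")
    return pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float) / f[None, :] + 1.0),
        index=counts.index,
        columns=counts.columns,
    )


def collapse_replicates(matrix: CountMatrix) -> CountMatrix:
    """Sum UMI counts over each individual's replicates, per cell type.

    Technical/culture replicates of one individual are not independent units
    of inference; collapsing by summation makes the individual the
    replication unit while conserving total counts.
    """
    samples = matrix.samples
    for col in ("individual_id", "replicate", "cell_type"):
        if samples[col].isna().any():
            raise ValueError(f"missing {col} annotation")
    key = samples["individual_id"].astype(str) + "|" + samples["cell_type"].astype(str)
    collapsed = matrix.counts.T.groupby(key.loc[matrix.counts.columns]).sum().T
    new_rows = []
    for k in collapsed.columns:
        ind, cell = k.split("|", 1)
        members = samples[key == k]
        new_rows.append(
            {
                "sample_id": k,
                "individual_id": ind,
                "cell_type": cell,
                "replicate": 0,
                "group": members["group"].iloc[0],
            }
        )
    new_samples = pd.DataFrame(new_rows).set_index("sample_id")
    return CountMatrix(collapsed.astype(int), new_samples)


def run_pca(vst_matrix: pd.DataFrame, n_components: int = 2):
    """PCA of samples in gene space (centered covariance eigendecomposition).

    Returns ``(coordinates, variance_explained_pct)`` where coordinates is a
    samples x PC DataFrame and variance explained is in percent.  Component
    signs are fixed so the largest-magnitude gene loading is positive, which
    makes outputs deterministic across runs.
    """
    from sklearn.decomposition import PCA

    if vst_matrix.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    n_components = min(n_components, vst_matrix.shape[1] - 1, vst_matrix.shape[0])
    x = vst_matrix.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    for k in range(n_components):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1
            pca.components_[k] *= -1
    cols = [f"PC{i+1}" for i in range(n_components)]
    coordinates = pd.DataFrame(coords, index=vst_matrix.columns, columns=cols)
    var_pct = pd.Series(
        100.0 * pca.explained_variance_ratio_, index=cols, name="variance_explained_pct"
    )
    return coordinates, var_pct
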