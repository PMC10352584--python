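"""Subgroup-specific co-expression module detection and comparison.

For each cohort subgroup (control, CC4-M, CC4-S) and cell type, pairwise
Pearson correlations are computed over individuals on the VST scale.  A
candidate module is a connected component (>= 5 genes) of the graph that
links genes whose correlation magnitude reaches 0.7.  A candidate is
accepted only if its defining criterion — the candidate's genes contain a
group of >= 5 members in which every gene has a partner with |r| >= 0.7 —
can be met in *exactly one* subgroup; that subgroup is the module's source.  Accepted modules are split into two
subparts A and B such that correlations are positive within a subpart and
negative between subparts, and per-subgroup median correlations are
summarized and compared with paired Wilcoxon signed-rank tests over matched
gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_R_MIN = 0.7
DEFAULT_MIN_SIZE = 5
_EXACT_PARTITION_MAX = 15  # exhaustive two-coloring up to this module size


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix for one subgroup and cell type."""

    matrix: pd.DataFrame  # genes x genes, NaN where undefined
    subgroup: str
    cell_type: str = ""
    n_individuals: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class CoexpressionModule:
    module_id: str
    cell_type: str
    source_subgroup: str
    genes: frozenset
    side_a: frozenset = frozenset()
    side_b: frozenset = frozenset()
    frustration: float = 0.0
    summaries: Optional[pd.DataFrame] = None


def pairwise_correlations(
    vst_matrix: pd.DataFrame,
    subgroup_ids: Sequence[str],
    subgroup: str = "",
    cell_type: str = "",
) -> CorrelationMatrix:
    """Pearson correlations over the subgroup's individuals for all gene pairs.

    Requires >= 4 individuals; genes with zero variance get NaN (absent)
    entries, including on the diagonal.
    """
    ids = list(subgroup_ids)
    if len(ids) < 4:
        raise ValueError("need >= 4 individuals for subgroup correlations")
    r = vst_matrix[ids].T.corr(method="pearson")
    return CorrelationMatrix(
        matrix=r, subgroup=subgroup, cell_type=cell_type, n_individuals=len(ids)
    )


def _criterion_holds(
    genes: Sequence[str], corr: pd.DataFrame, r_min: float, min_size: int
) -> bool:
    """Can this subgroup assemble a qualifying group from the gene set?

    True when the subgraph linking the given genes at |r| >= r_min contains
    a connected component of at least ``min_size`` genes (every member of
    such a component has a strong partner inside it by construction).  This
    set-level formulation is robust to a stray gene hitchhiking onto a
    candidate through one spurious edge, which would otherwise let a module
    shared by all subgroups masquerade as subgroup-specific.
    """
    genes = list(genes)
    sub = corr.loc[genes, genes].to_numpy(dtype=float)
    np.fill_diagonal(sub, np.nan)
    with np.errstate(invalid="ignore"):
        adj = np.abs(sub) >= r_min
    adj &= np.isfinite(sub)
    g = nx.Graph()
    g.add_nodes_from(range(len(genes)))
    for i, j in zip(*np.nonzero(np.triu(adj, k=1))):
        g.add_edge(int(i), int(j))
    return any(len(c) >= min_size for c in nx.connected_components(g))


def detect_modules(
    corr_by_subgroup: Dict[str, CorrelationMatrix],
    r_min: float = DEFAULT_R_MIN,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[CoexpressionModule]:
    """Detect modules specific to exactly one subgroup.

    Candidates are connected components of the |r| >= r_min graph within
    each subgroup; a candidate is accepted only if the within-set criterion
    holds in exactly one of the supplied subgroups (the specificity rule).
    Absent (NaN) correlations never contribute edges.  Output is ordered and
    labelled deterministically, independent of gene order in the input.
    """
    panels = [tuple(sorted(cm.gene_ids)) for cm in corr_by_subgroup.values()]
    if len(set(panels)) != 1:
        raise ValueError("all subgroups must share one gene panel")
    genes_sorted = list(panels[0])

    candidates: dict[frozenset, str] = {}
    for label in sorted(corr_by_subgroup):
        cm = corr_by_subgroup[label]
        r = cm.matrix.loc[genes_sorted, genes_sorted].to_numpy(dtype=float)
        g = nx.Graph()
        g.add_nodes_from(genes_sorted)
        iu = np.triu_indices(len(genes_sorted), k=1)
        with np.errstate(invalid="ignore"):
            strong = np.abs(r[iu]) >= r_min
        strong &= np.isfinite(r[iu])
        for i, j in zip(iu[0][strong], iu[1][strong]):
            g.add_edge(genes_sorted[i], genes_sorted[j])
        for comp in nx.connected_components(g):
            if len(comp) >= min_size:
                candidates.setdefault(frozenset(comp), label)

    modules = []
    for gene_set in sorted(candidates, key=lambda s: sorted(s)):
        holds_in = [
            label
            for label in sorted(corr_by_subgroup)
            if _criterion_holds(
                sorted(gene_set), corr_by_subgroup[label].matrix, r_min, min_size
            )
        ]
        if len(holds_in) == 1:
            src = holds_in[0]
            modules.append(
                CoexpressionModule(
                    module_id="",
                    cell_type=corr_by_subgroup[src].cell_type,
                    source_subgroup=src,
                    genes=gene_set,
                )
            )
    for k, m in enumerate(modules, start=1):
        m.module_id = f"module_{k}"
    return modules


def _partition_objective(sides: np.ndarray, w: np.ndarray, s: np.ndarray) -> float:
    """Agreement weight of a coloring: |r| summed over sign-consistent pairs."""
    same = sides[:, None] == sides[None, :]
    consistent = np.where(s > 0, same, ~same)
    iu = np.triu_indices(len(sides), k=1)
    return float(np.sum(w[iu] * consistent[iu]))


def partition_signs(
    module_genes: Iterable[str], source_corr: pd.DataFrame
) -> tuple[frozenset, frozenset, float]:
    """Split a module into sign-consistent subparts A and B.

    Seeks the two-coloring maximizing summed |r| over sign-consistent pairs
    (positive correlations within a side, negative across).  Small modules
    (<= 15 genes) are solved by exhaustive enumeration; larger ones by the
    greedy construction (seed with the strongest edge, attach each remaining
    gene to the side with the larger signed agreement) followed by
    single-gene flip refinement.  Returns ``(side_a, side_b, frustration)``
    where frustration is the weighted fraction of sign-violated pairs; it is
    0 for a perfectly consistent (balanced) sign pattern.  With no negative
    correlations side B is empty.  Side A is canonically the larger side
    (ties broken by the lexicographically smallest gene).
    """
    genes = sorted(module_genes)
    n = len(genes)
    r = source_corr.loc[genes, genes].to_numpy(dtype=float)
    np.fill_diagonal(r, np.nan)
    w = np.where(np.isfinite(r), np.abs(r), 0.0)
    s = np.where(np.isfinite(r), np.sign(r), 0.0)
    total = float(np.sum(w[np.triu_indices(n, k=1)]))
    if n == 1 or total == 0:
        return frozenset(genes), frozenset(), 0.0
    if not (s < 0).any():
        return frozenset(genes), frozenset(), 0.0

    if n <= _EXACT_PARTITION_MAX:
        # enumerate colorings with gene 0 pinned to side 0
        m = n - 1
        codes = np.arange(1 << m, dtype=np.uint32)
        bits = ((codes[:, None] >> np.arange(m)) & 1).astype(bool)
        sides_all = np.concatenate(
            [np.zeros((len(codes), 1), dtype=bool), bits], axis=1
        )
        iu = np.triu_indices(n, k=1)
        same = sides_all[:, iu[0]] == sides_all[:, iu[1]]
        consistent = np.where(s[iu] > 0, same, ~same)
        agreement = consistent @ w[iu]
        best = int(np.argmin(-agreement))  # first maximizer in enumeration order
        sides = sides_all[best]
        best_agree = float(agreement[best])
    else:
        sides = _greedy_partition(w, s)
        best_agree = _partition_objective(sides, w, s)
        improved = True
        while improved:
            improved = False
            for i in range(n):
                sides[i] = ~sides[i]
                a = _partition_objective(sides, w, s)
                if a > best_agree + 1e-12:
                    best_agree = a
                    improved = True
                else:
                    sides[i] = ~sides[i]

    side0 = frozenset(g for g, b in zip(genes, sides) if not b)
    side1 = frozenset(g for g, b in zip(genes, sides) if b)
    frustration = 1.0 - best_agree / total
    if len(side1) > len(side0) or (
        len(side1) == len(side0) and side1 and min(side1) < min(side0)
    ):
        side0, side1 = side1, side0
    return side0, side1, frustration


def _greedy_partition(w: np.ndarray, s: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    sides = np.zeros(n, dtype=bool)
    assigned = np.zeros(n, dtype=bool)
    iu = np.triu_indices(n, k=1)
    k = int(np.argmax(w[iu]))
    i0, j0 = int(iu[0][k]), int(iu[1][k])
    assigned[[i0, j0]] = True
    sides[j0] = s[i0, j0] < 0
    while not assigned.all():
        attach = (w * assigned[None, :]).sum(axis=1)
        attach[assigned] = -np.inf
        g = int(np.argmax(attach))
        signed = w[g] * s[g]
        score_a = signed[assigned & ~sides].sum() - signed[assigned & sides].sum()
        sides[g] = score_a < 0
        assigned[g] = True
    return sides


def _unique_pairs(genes_a: Sequence[str], genes_b: Optional[Sequence[str]] = None):
    if genes_b is None:
        return list(combinations(sorted(genes_a), 2))
    return [(a, b) for a in sorted(genes_a) for b in sorted(genes_b)]


def _pair_values(corr: pd.DataFrame, pairs) -> np.ndarray:
    return np.array([corr.at[a, b] for a, b in pairs], dtype=float)


def module_summaries(
    module: CoexpressionModule, corr_by_subgroup: Dict[str, CorrelationMatrix]
) -> pd.DataFrame:
    """Per-subgroup medians of unique pair correlations: within-A, A-B, within-B.

    A side with fewer than two genes has no within-side pairs and yields an
    absent (NaN) median.
    """
    a = sorted(module.side_a)
    b = sorted(module.side_b)
    rows = []
    for label in sorted(corr_by_subgroup):
        corr = corr_by_subgroup[label].matrix
        row = {"subgroup": label}
        row["median_within_a"] = (
            float(np.nanmedian(_pair_values(corr, _unique_pairs(a))))
            if len(a) >= 2
            else float("nan")
        )
        row["median_within_b"] = (
            float(np.nanmedian(_pair_values(corr, _unique_pairs(b))))
            if len(b) >= 2
            else float("nan")
        )
        row["median_a_b"] = (
            float(np.nanmedian(_pair_values(corr, _unique_pairs(a, b))))
            if a and b
            else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subgroup")


def compare_module_correlations(
    module: CoexpressionModule,
    corr_x: CorrelationMatrix,
    corr_y: CorrelationMatrix,
    pair_set: str = "within",
) -> float:
    """Paired Wilcoxon signed-rank p over matched gene-pair correlations.

    ``pair_set`` selects which unique pairs enter the test: ``'within'``
    pools within-A and within-B pairs, ``'cross'`` uses A-B pairs, ``'all'``
    every unique pair in the module.  The same pairs are matched between the
    two subgroups.  Identical coefficient vectors give p = 1; small pair
    counts use the exact signed-rank distribution.
    """
    a, b = sorted(module.side_a), sorted(module.side_b)
    if not a and not b:
        a = sorted(module.genes)
    if pair_set == "within":
        pairs = _unique_pairs(a) + (_unique_pairs(b) if len(b) >= 2 else [])
    elif pair_set == "cross":
        pairs = _unique_pairs(a, b)
    elif pair_set == "all":
        pairs = _unique_pairs(sorted(module.genes))
    else:
        raise ValueError(f"unknown pair_set {pair_set!r}")
    if not pairs:
        return float("nan")
    x = _pair_values(corr_x.matrix, pairs)
    y = _pair_values(corr_y.matrix, pairs)
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    if d.size == 0:
        return float("nan")
    if np.all(d == 0):
        return 1.0
    try:
        # 'auto' uses the exact signed-rank distribution at small n
        # (no ties) and the normal approximation otherwise.
        res = stats.wilcoxon(d, zero_method="wilcox", method="auto")
    except ValueError:
        return 1.0
    return float(res.pvalue)
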