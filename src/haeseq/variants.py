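"""Panel-variant filtering, severity association and family segregation.

A targeted DNA panel (~180 genes hypothesized to modulate HAE severity)
yields annotated variants with per-individual genotypes.  Three analyses:

* **Deleteriousness filter** — keep protein-truncating variants (nonsense,
  frameshift) and missense variants predicted damaging (CADD > 18 and at
  least 2 of PolyPhen-HVAR / PolyPhen-HDIV / SIFT deleterious), all at
  population frequency < 0.05.
* **Association** — per severity subgroup, a 1-df goodness-of-fit chi-square
  of the subgroup's alt/ref allele counts against the expectation derived
  from the *cohort-wide* allele frequency (the cohort is its own reference
  population since database frequencies differ systematically).  The
  Bonferroni denominator is restricted to *testable* variants: those whose
  frequency even at the most extreme possible subgroup count could beat the
  corrected threshold.  The restriction is resolved as a sorted-prefix fixed
  point (the testable count determines the threshold that defines
  testability).
* **Segregation** — in families with both severe and mild members, a variant
  segregates consistently only if carriers are exactly the severe (or
  exactly the mild) members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CADD_MIN = 18.0
POPULATION_FREQ_MAX = 0.05
TRUNCATING = ("nonsense", "frameshift")
PREDICTORS = ("polyphen_hvar", "polyphen_hdiv", "sift")


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str  # nonsense | frameshift | missense | synonymous | other
    cadd: float = float("nan")
    polyphen_hvar: str = "absent"  # deleterious | benign | absent
    polyphen_hdiv: str = "absent"
    sift: str = "absent"
    population_frequency: Optional[float] = None
    genotypes: Dict[str, Optional[int]] = field(default_factory=dict)  # id -> 0/1/2|None
    frequency_missing: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        for g in self.genotypes.values():
            if g is not None and g not in (0, 1, 2):
                raise ValueError("genotypes are alt-allele counts in {0,1,2}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class AssociationResult:
    variant_key: str
    subgroup: str
    observed_alt: int
    expected_alt: float
    n_alleles: int
    chi_square: float
    p_value: float
    min_achievable_p: float
    testable: bool = False
    adjusted_alpha: float = float("nan")
    significant: bool = False


def filter_deleterious(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Apply the rare-deleterious filter.

    Keeps a variant iff population frequency < 0.05 AND (truncating, or
    missense with CADD strictly above 18 and >= 2 of 3 predictor calls
    deleterious).  Absent predictor calls count as non-deleterious; a
    missing population frequency is treated as 0 (novel variant) and the
    record is flagged.
    """
    kept = []
    for v in variants:
        freq = v.population_frequency
        if freq is None:
            freq = 0.0
            v.frequency_missing = True
        if freq >= POPULATION_FREQ_MAX:
            continue
        if v.consequence in TRUNCATING:
            kept.append(v)
            continue
        if v.consequence != "missense":
            continue
        if not (np.isfinite(v.cadd) and v.cadd > CADD_MIN):
            continue
        n_del = sum(getattr(v, p) == "deleterious" for p in PREDICTORS)
        if n_del >= 2:
            kept.append(v)
    return kept


def cohort_frequency(variant: VariantRecord, individuals: Sequence[str]) -> float:
    """Alt-allele frequency over all genotyped cohort members.

    Missing genotypes are excluded from numerator and denominator.
    """
    counts = [variant.genotypes.get(i) for i in individuals]
    counts = [c for c in counts if c is not None]
    if not counts:
        raise ValueError(f"{variant.key}: no genotyped individual")
    return float(sum(counts)) / (2 * len(counts))


def _chisq(observed_alt: int, n_alleles: int, freq: float) -> tuple[float, float]:
    exp_alt = n_alleles * freq
    exp_ref = n_alleles * (1.0 - freq)
    chi2 = (observed_alt - exp_alt) ** 2 / exp_alt + (
        (n_alleles - observed_alt) - exp_ref
    ) ** 2 / exp_ref
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def chisq_vs_expected(
    variant: VariantRecord,
    subgroup_ids: Sequence[str],
    cohort_freq: float,
    unit: str = "allele",
) -> AssociationResult:
    """1-df goodness-of-fit of subgroup counts vs cohort expectation.

    ``unit='allele'`` (default) tests alt vs ref allele counts over 2n
    alleles against the cohort allele frequency; ``unit='genotype'`` tests
    carrier vs non-carrier counts over n individuals against the
    Hardy-Weinberg carrier frequency ``1 - (1 - f)**2``.  No continuity
    correction.  A cohort frequency of exactly 0 or 1 makes the test
    degenerate (zero expected count in one cell); such variants are
    untestable by construction.
    """
    ids = [i for i in subgroup_ids if variant.genotypes.get(i) is not None]
    if not ids:
        raise ValueError("empty genotyped subgroup")
    if unit == "allele":
        obs = int(sum(variant.genotypes[i] for i in ids))
        n_alleles = 2 * len(ids)
    elif unit == "genotype":
        obs = int(sum(variant.genotypes[i] >= 1 for i in ids))
        n_alleles = len(ids)
        cohort_freq = 1.0 - (1.0 - cohort_freq) ** 2
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if not 0.0 < cohort_freq < 1.0:
        return AssociationResult(
            variant_key=variant.key,
            subgroup="",
            observed_alt=obs,
            expected_alt=n_alleles * cohort_freq,
            n_alleles=n_alleles,
            chi_square=float("nan"),
            p_value=float("nan"),
            min_achievable_p=1.0,
            testable=False,
        )
    chi2, p = _chisq(obs, n_alleles, cohort_freq)
    return AssociationResult(
        variant_key=variant.key,
        subgroup="",
        observed_alt=obs,
        expected_alt=n_alleles * cohort_freq,
        n_alleles=n_alleles,
        chi_square=chi2,
        p_value=p,
        min_achievable_p=min_achievable_p(n_alleles, cohort_freq),
    )


def min_achievable_p(n_alleles: int, cohort_freq: float) -> float:
    """Smallest p the chi-square test can reach at the most extreme count.

    The extreme subgroup outcomes are 0 or ``n_alleles`` alt alleles; the
    larger of the two chi-square values gives the attainable floor.
    """
    if not 0.0 < cohort_freq < 1.0:
        return 1.0
    chi_low, p_low = _chisq(0, n_alleles, cohort_freq)
    chi_high, p_high = _chisq(n_alleles, n_alleles, cohort_freq)
    return min(p_low, p_high)


def testable_set(
    variants: Sequence[VariantRecord],
    subgroup_sizes: Mapping[str, int] | int,
    all_individuals: Sequence[str],
    family_alpha: float = 0.05,
    unit: str = "allele",
) -> tuple[list[VariantRecord], float]:
    """Restricted-Bonferroni testable set and its adjusted alpha.

    For each variant the minimum achievable p (over the smallest tested
    subgroup, the binding case) is computed from the cohort frequency; after
    sorting ascending, the testable set is the largest prefix of size k in
    which every member satisfies ``min_achievable_p < family_alpha / k``.
    Returns ``([], family_alpha)`` when no variant is testable.
    """
    if isinstance(subgroup_sizes, int):
        n_min = subgroup_sizes
    else:
        if not subgroup_sizes:
            raise ValueError("no subgroup sizes supplied")
        n_min = min(subgroup_sizes.values())
    if n_min < 1:
        raise ValueError("subgroup size must be positive")
    scored = []
    for v in variants:
        f = cohort_frequency(v, all_individuals)
        if unit == "genotype":
            trials, f = n_min, 1.0 - (1.0 - f) ** 2
        else:
            trials = 2 * n_min
        scored.append((min_achievable_p(trials, f), v))
    scored.sort(key=lambda t: (t[0], t[1].key))
    for k in range(len(scored), 0, -1):
        thresh = family_alpha / k
        if all(p < thresh for p, _ in scored[:k]):
            return [v for _, v in scored[:k]], thresh
    return [], family_alpha


def associate(
    variants: Sequence[VariantRecord],
    subgroups: Mapping[str, Sequence[str]],
    all_individuals: Sequence[str],
    family_alpha: float = 0.05,
    unit: str = "allele",
) -> pd.DataFrame:
    """Association of every variant with every severity subgroup.

    Computes cohort frequencies, the testable set with its adjusted alpha,
    and per-(variant, subgroup) chi-square results.  Untestable variants are
    reported with ``testable=False`` and never significant (the chi-square
    is still shown for transparency).
    """
    n_sizes = {name: len(ids) for name, ids in subgroups.items()}
    testable, adj_alpha = testable_set(
        variants, n_sizes, all_individuals, family_alpha, unit=unit
    )
    testable_keys = {v.key for v in testable}
    rows = []
    for v in variants:
        f = cohort_frequency(v, all_individuals)
        for name, ids in subgroups.items():
            res = chisq_vs_expected(v, ids, f, unit=unit)
            res.subgroup = name
            res.testable = v.key in testable_keys
            res.adjusted_alpha = adj_alpha
            res.significant = bool(
                res.testable
                and np.isfinite(res.p_value)
                and res.p_value < adj_alpha
            )
            rows.append(
                {
                    "variant": v.key,
                    "gene": v.gene,
                    "subgroup": name,
                    "cohort_freq": f,
                    "observed_alt": res.observed_alt,
                    "expected_alt": res.expected_alt,
                    "n_alleles": res.n_alleles,
                    "chi_square": res.chi_square,
                    "p_value": res.p_value,
                    "min_achievable_p": res.min_achievable_p,
                    "testable": res.testable,
                    "adjusted_alpha": res.adjusted_alpha,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)


def segregation_check(
    family_genotypes: Mapping[str, Optional[int]],
    severity_labels: Mapping[str, str],
) -> str:
    """Consistency of a variant with severity within one family.

    ``severity_labels`` maps member -> 'severe' | 'mild'.  Requires >= 2
    members on each side.  Returns ``consistent_severe`` when carriers are
    exactly the severe members, ``consistent_mild`` for the mirror case,
    otherwise ``inconsistent``.  A missing genotype in the family makes the
    call ``inconsistent`` (the pattern cannot be established).
    """
    severe = [m for m, s in severity_labels.items() if s == "severe"]
    mild = [m for m, s in severity_labels.items() if s == "mild"]
    if len(severe) < 2 or len(mild) < 2:
        raise ValueError("need >= 2 severe and >= 2 mild family members")
    members = severe + mild
    if any(family_genotypes.get(m) is None for m in members):
        return "inconsistent"
    carrier = {m: family_genotypes[m] >= 1 for m in members}
    if all(carrier[m] for m in severe) and not any(carrier[m] for m in mild):
        return "consistent_severe"
    if all(carrier[m] for m in mild) and not any(carrier[m] for m in severe):
        return "consistent_mild"
    return "inconsistent"
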