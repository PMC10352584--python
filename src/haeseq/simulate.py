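"""Seeded synthetic HAE cohort generator.

Stands in for undepositable patient data: produces clinical records with
right-skewed onset/attack distributions, UMI count matrices for three
myeloid cell types (monocyte, M0 macrophage, IFN-gamma-activated
macrophage) in triplicate, and an annotated variant panel — together with a
record of every planted effect ("truth") for recovery testing.

Counts follow a Gaussian-copula negative-binomial construction: each gene's
marginal is NB(mu, dispersion) exactly (Poisson mixed over a unit-mean
gamma), while dependence is injected on the latent gamma layer through a
per-module, per-individual standard-normal factor.  A gene's latent value is
``z = s * l * F + sqrt(1 - l^2) * eps`` with side sign ``s`` (+1 for subpart
A, -1 for B) and subgroup-specific loading ``l``, so two same-side genes
with loading ``l`` have latent correlation ``l**2`` and A-B pairs
``-l**2``.  Replicates of one individual share the individual's latent gamma
draw and differ only by Poisson sampling noise, mirroring the
biological-vs-technical hierarchy of cultured triplicates.
:func:`loading_for_target_corr` inverts the copula's closed-form count-scale
Pearson correlation so modules can be calibrated to a target r.

One root seed drives everything through named child streams
(`SeedSequence.spawn`); identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from haeseq.clinical import PatientRecord
from haeseq.normalize import CountMatrix

GROUP_OF = {"control": "control", "mild": "CC4-M", "severe": "CC4-S"}
_STREAMS = ("clinical", "gene_means", "latent", "counts", "variants")


@dataclass(frozen=True)
class ClinicalModel:
    """Parameters of the right-skewed clinical draws.

    Onset ages are log-normal (years, floored at 1); attack counts in the
    last year are 5 + NB for the severe stratum and an NB clipped below 5
    for the mild stratum, so strata land on the intended side of the CC4
    threshold by construction.  Five-year averages and all-time maxima are
    derived from the last-year count with multiplicative log-normal noise,
    keeping the long- and short-term criteria correlated as in real
    registries.
    """

    onset_log_mean: float = 2.3  # median ~10 years
    onset_log_sd: float = 0.8
    severe_extra_attacks_mean: float = 7.0  # last-year = 5 + NB(mean, shape)
    severe_extra_attacks_shape: float = 1.2
    mild_attacks_mean: float = 1.0  # clipped at 4
    mild_attacks_shape: float = 0.8
    avg5y_log_sd: float = 0.4
    max_year_factor_range: Tuple[float, float] = (1.2, 2.5)
    ltp_prob: float = 0.33
    nmd_prob: float = 0.5
    asymptomatic_prob: float = 0.0


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    ``side_of_gene`` maps each gene to 'A' or 'B'; B-side genes enter the
    latent factor with a negated sign, so A-B pairs correlate negatively.
    ``loading_per_subgroup`` maps {'control','mild','severe'} to the factor
    loading in [0, 1] used for individuals of that subgroup.
    """

    gene_ids: Tuple[str, ...]
    side_of_gene: Mapping[str, str]
    loading_per_subgroup: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("a module needs >= 2 genes")
        if set(self.side_of_gene) != set(self.gene_ids):
            raise ValueError("side_of_gene must cover exactly the module genes")
        if any(s not in ("A", "B") for s in self.side_of_gene.values()):
            raise ValueError("sides are 'A' or 'B'")
        for k, v in self.loading_per_subgroup.items():
            if k not in ("control", "mild", "severe"):
                raise ValueError(f"unknown subgroup {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError("loadings must be in [0, 1]")


@dataclass(frozen=True)
class DEEffect:
    """Planted expression shift: gene mean multiplied by 2**log2fc in the
    stated stratum ('severe', 'mild' or 'patient' = both)."""

    gene: str
    contrast: str
    log2fc: float

    def applies_to(self, stratum: str) -> bool:
        return self.contrast == "patient" or self.contrast == stratum


@dataclass(frozen=True)
class VariantSpec:
    """A panel variant with annotations and (optionally) a planted
    severity-dependent allele frequency."""

    gene: str
    frequency: float
    consequence: str = "missense"
    cadd: float = 10.0
    polyphen_hvar: str = "benign"
    polyphen_hdiv: str = "benign"
    sift: str = "benign"
    population_frequency: float = 0.1
    chrom: str = "1"
    pos: Optional[int] = None
    ref: str = "A"
    alt: str = "G"
    group_frequencies: Optional[Mapping[str, float]] = None  # stratum -> freq

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")
        if self.group_frequencies:
            for f in self.group_frequencies.values():
                if not 0.0 <= f <= 1.0:
                    raise ValueError("group frequencies must be in [0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_controls: int = 20
    n_mild: int = 20
    n_severe: int = 20
    n_genes: int = 140
    cell_types: Tuple[str, ...] = ("monocyte", "macrophage_m0", "macrophage_ifng")
    replicates_per_cell_type: int = 3
    nb_mean_log_range: Tuple[float, float] = (3.5, 7.5)  # natural-log mean bounds
    nb_dispersion: float = 0.1
    de_effects: Tuple[DEEffect, ...] = ()
    module_specs: Tuple[ModuleSpec, ...] = ()
    variant_specs: Tuple[VariantSpec, ...] = ()
    clinical: ClinicalModel = field(default_factory=ClinicalModel)
    serping1_gene: str = "SERPING1"
    nmd_factor: float = 0.5
    serping1_log_mean: Optional[float] = None  # override the drawn baseline

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_mild", "n_severe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.cell_types) != len(set(self.cell_types)):
            raise ValueError("cell types must be distinct")
        if self.replicates_per_cell_type < 1:
            raise ValueError("replicates_per_cell_type must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.nb_mean_log_range
        if not lo <= hi:
            raise ValueError("nb_mean_log_range must be ordered")
        panel = set(self.gene_panel())
        seen: set = set()
        for ms in self.module_specs:
            gs = set(ms.gene_ids)
            if not gs <= panel:
                raise ValueError(f"module genes not in panel: {sorted(gs - panel)}")
            if gs & seen:
                raise ValueError("module gene sets must be disjoint")
            seen |= gs
        for eff in self.de_effects:
            if eff.gene not in panel:
                raise ValueError(f"DE gene {eff.gene!r} not in panel")
            if eff.contrast not in ("severe", "mild", "patient"):
                raise ValueError(f"unknown DE contrast {eff.contrast!r}")

    def gene_panel(self) -> list[str]:
        names = [f"G{i:03d}" for i in range(1, self.n_genes + 1)]
        names[0] = self.serping1_gene
        return names


@dataclass
class CohortBundle:
    patients: list[PatientRecord]
    counts: Dict[str, CountMatrix]
    variants: list
    truth: dict
    config: SimulationConfig


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _nb_draw(rng, mean: float, shape: float, size: int) -> np.ndarray:
    """NB with given mean and gamma shape (smaller shape = more skew)."""
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=size)


def simulate_clinical(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[PatientRecord]:
    """Draw clinical records for controls, mild and severe strata.

    Severe records have attacks_last_year >= 5 and mild < 5 by construction
    (the CC4 threshold side is part of the stratum definition); controls
    carry no attack data.  Onset ages are right-skewed log-normal integers.
    """
    cm = config.clinical
    if rng is None:
        rng = _streams(config.seed)["clinical"]
    records: list[PatientRecord] = []
    for i in range(config.n_controls):
        records.append(PatientRecord(patient_id=f"C{i+1:03d}", role="control"))

    def _onset() -> Optional[int]:
        if cm.asymptomatic_prob > 0 and rng.random() < cm.asymptomatic_prob:
            return None
        return int(max(1, round(float(rng.lognormal(cm.onset_log_mean, cm.onset_log_sd)))))

    def _derived(last: float) -> tuple[float, float]:
        avg = round(float(last * rng.lognormal(0.0, cm.avg5y_log_sd)), 1)
        lo, hi = cm.max_year_factor_range
        mx = round(float(max(last, avg) * rng.uniform(lo, hi)), 1)
        return avg, max(mx, last)

    for i in range(config.n_mild):
        last = float(
            min(4, _nb_draw(rng, cm.mild_attacks_mean, cm.mild_attacks_shape, 1)[0])
        )
        avg, mx = _derived(last)
        records.append(
            PatientRecord(
                patient_id=f"PM{i+1:03d}",
                role="patient",
                onset_age_years=_onset(),
                attacks_avg_5y=avg,
                attacks_max_year=mx,
                attacks_last_year=last,
                ltp=bool(rng.random() < cm.ltp_prob),
                serping1_class="nmd" if rng.random() < cm.nmd_prob else "non_nmd",
            )
        )
    for i in range(config.n_severe):
        last = float(
            5
            + _nb_draw(
                rng, cm.severe_extra_attacks_mean, cm.severe_extra_attacks_shape, 1
            )[0]
        )
        avg, mx = _derived(last)
        records.append(
            PatientRecord(
                patient_id=f"PS{i+1:03d}",
                role="patient",
                onset_age_years=_onset(),
                attacks_avg_5y=avg,
                attacks_max_year=mx,
                attacks_last_year=last,
                ltp=bool(rng.random() < cm.ltp_prob),
                serping1_class="nmd" if rng.random() < cm.nmd_prob else "non_nmd",
            )
        )
    return records


def _stratum_of(record: PatientRecord, config: SimulationConfig) -> str:
    if record.role == "control":
        return "control"
    last = record.attacks_last_year or 0.0
    return "severe" if last >= 5 else "mild"


def simulate_counts(
    patients: Sequence[PatientRecord],
    config: SimulationConfig,
    rngs: Optional[dict] = None,
) -> Dict[str, CountMatrix]:
    """Gaussian-copula NB count matrices, one per cell type.

    Per cell type and gene a baseline mean is drawn uniformly on the
    configured natural-log range; planted DE effects shift strata means by
    2**log2fc, and NMD-susceptible *SERPING1* carriers get the configured
    multiplicative reduction on the *SERPING1* mean.  See the module
    docstring for the dependence construction.
    """
    if not patients:
        raise ValueError("patients must be nonempty")
    if rngs is None:
        s = _streams(config.seed)
        rngs = {"gene_means": s["gene_means"], "latent": s["latent"], "counts": s["counts"]}
    genes = config.gene_panel()
    g_index = {g: i for i, g in enumerate(genes)}
    alpha = config.nb_dispersion
    strata = [_stratum_of(p, config) for p in patients]
    n_ind = len(patients)
    reps = config.replicates_per_cell_type
    lo, hi = config.nb_mean_log_range

    out: Dict[str, CountMatrix] = {}
    for cell in config.cell_types:
        log_mu = rngs["gene_means"].uniform(lo, hi, size=len(genes))
        if config.serping1_log_mean is not None:
            log_mu[g_index[config.serping1_gene]] = config.serping1_log_mean
        mu_base = np.exp(log_mu)

        # per-individual mean matrix with planted effects
        mu = np.tile(mu_base[:, None], (1, n_ind))
        for eff in config.de_effects:
            gi = g_index[eff.gene]
            for j, st in enumerate(strata):
                if st != "control" and eff.applies_to(st):
                    mu[gi, j] *= 2.0 ** eff.log2fc
        si = g_index[config.serping1_gene]
        for j, p in enumerate(patients):
            if p.serping1_class == "nmd":
                mu[si, j] *= config.nmd_factor

        # latent layer: factor per (module, individual)
        z = rngs["latent"].standard_normal((len(genes), n_ind))
        for ms in config.module_specs:
            factor = rngs["latent"].standard_normal(n_ind)
            for g in ms.gene_ids:
                gi = g_index[g]
                sign = 1.0 if ms.side_of_gene[g] == "A" else -1.0
                load = np.array(
                    [ms.loading_per_subgroup.get(st, 0.0) for st in strata]
                )
                eps = z[gi].copy()
                z[gi] = sign * load * factor + np.sqrt(1.0 - load**2) * eps
        u = stats.norm.cdf(z)
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        rate = stats.gamma.ppf(u, a=1.0 / alpha, scale=alpha)  # unit-mean gamma

        lam = mu * rate  # genes x individuals, shared by replicates
        counts = rngs["counts"].poisson(np.repeat(lam[:, :, None], reps, axis=2))

        sample_ids, rows = [], []
        mat = np.empty((len(genes), n_ind * reps), dtype=np.int64)
        col = 0
        for j, p in enumerate(patients):
            for r in range(reps):
                sid = f"{p.patient_id}_{cell}_r{r+1}"
                sample_ids.append(sid)
                rows.append(
                    {
                        "sample_id": sid,
                        "individual_id": p.patient_id,
                        "cell_type": cell,
                        "replicate": r + 1,
                        "group": GROUP_OF[strata[j]],
                    }
                )
                mat[:, col] = counts[:, j, r]
                col += 1
        out[cell] = CountMatrix(
            pd.DataFrame(mat, index=genes, columns=sample_ids),
            pd.DataFrame(rows).set_index("sample_id"),
        )
    return out


def simulate_variants(
    patients: Sequence[PatientRecord],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Draw per-individual genotypes for the variant panel.

    Genotypes are binomial(2, f) with f the spec's cohort frequency, or the
    stratum-specific frequency for planted-association variants.
    """
    from haeseq.variants import VariantRecord

    if rng is None:
        rng = _streams(config.seed)["variants"]
    records = []
    for k, vs in enumerate(config.variant_specs):
        pos = vs.pos if vs.pos is not None else 1000 + 10 * k
        genotypes = {}
        for p in patients:
            st = _stratum_of(p, config)
            f = vs.frequency
            if vs.group_frequencies:
                f = vs.group_frequencies.get(st, f)
            genotypes[p.patient_id] = int(rng.binomial(2, f))
        records.append(
            VariantRecord(
                chrom=vs.chrom,
                pos=pos,
                ref=vs.ref,
                alt=vs.alt,
                gene=vs.gene,
                consequence=vs.consequence,
                cadd=vs.cadd,
                polyphen_hvar=vs.polyphen_hvar,
                polyphen_hdiv=vs.polyphen_hdiv,
                sift=vs.sift,
                population_frequency=vs.population_frequency,
                genotypes=genotypes,
            )
        )
    return records


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Full seeded bundle: clinical records, counts per cell type, variants,
    and the planted-effect truth record."""
    s = _streams(config.seed)
    patients = simulate_clinical(config, rng=s["clinical"])
    counts = simulate_counts(
        patients,
        config,
        rngs={"gene_means": s["gene_means"], "latent": s["latent"], "counts": s["counts"]},
    )
    variants = simulate_variants(patients, config, rng=s["variants"])
    truth = {
        "seed": config.seed,
        "streams": list(_STREAMS),
        "de_effects": [asdict(e) for e in config.de_effects],
        "modules": [
            {
                "genes": sorted(ms.gene_ids),
                "sides": dict(sorted(ms.side_of_gene.items())),
                "loadings": dict(ms.loading_per_subgroup),
            }
            for ms in config.module_specs
        ],
        "associated_variants": [
            v.gene
            for v, vs in zip(variants, config.variant_specs)
            if vs.group_frequencies
        ],
        "nmd_factor": config.nmd_factor,
    }
    return CohortBundle(
        patients=patients, counts=counts, variants=variants, truth=truth, config=config
    )


# ---------------------------------------------------------------------------
# copula calibration


def count_scale_corr(
    latent_rho: float,
    mu: float,
    dispersion: float,
    n_replicates: int = 3,
    quad_points: int = 40,
) -> float:
    """Closed-form Pearson correlation of collapsed counts for two genes with
    equal mean ``mu`` and latent (normal-scale) correlation ``latent_rho``.

    Uses 2-D Gauss-Hermite quadrature for E[R_a R_b] on the gamma layer:
    Cov(sum_a, sum_b) = (k mu)^2 Cov(R_a, R_b) and
    Var(sum) = k mu + dispersion (k mu)^2 with k replicates.
    """
    if latent_rho == 0.0:
        return 0.0
    a = 1.0 / dispersion
    nodes, weights = np.polynomial.hermite_e.hermegauss(quad_points)
    w = weights / np.sqrt(2.0 * np.pi)
    def _rate(z):
        # extreme-node CDF values saturate in double precision; clip before
        # the quantile (their quadrature weights are ~e^-40, so no bias)
        u = np.clip(stats.norm.cdf(z), 1e-15, 1.0 - 1e-15)
        return stats.gamma.ppf(u, a=a, scale=dispersion)

    r1 = _rate(nodes)
    zb = latent_rho * nodes[:, None] + np.sqrt(1.0 - latent_rho**2) * nodes[None, :]
    rb = _rate(zb)
    e_rab = float(np.einsum("i,j,i,ij->", w, w, r1, rb))
    cov_r = e_rab - 1.0
    k = n_replicates
    var = k * mu + dispersion * (k * mu) ** 2
    return (k * mu) ** 2 * cov_r / var


def loading_for_target_corr(
    target_r: float,
    mu: float,
    dispersion: float,
    n_replicates: int = 3,
) -> float:
    """Factor loading giving a target count-scale Pearson r between two
    same-side module genes of mean ``mu``.

    Inverts :func:`count_scale_corr` (monotone in the latent correlation)
    with Brent's method; the loading is the square root of the latent
    correlation.  Raises if the target is unattainable (copula correlations
    cannot exceed the comonotone bound).
    """
    if not 0.0 < target_r < 1.0:
        raise ValueError("target_r must be in (0, 1)")
    hi = count_scale_corr(0.999999, mu, dispersion, n_replicates)
    if target_r >= hi:
        raise ValueError(f"target r={target_r} exceeds attainable bound {hi:.4f}")
    rho = optimize.brentq(
        lambda r: count_scale_corr(r, mu, dispersion, n_replicates) - target_r,
        1e-9,
        0.999999,
        xtol=1e-10,
    )
    return float(np.sqrt(rho))
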