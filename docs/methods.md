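# Methods

This note documents the models, estimators and numerical choices behind
`haeseq`, what the synthetic cohort generator does and does not emulate, and
the known limitations of each procedure.

## Severity classification

Patients are assigned per criterion by fixed thresholds
(`SeverityThresholds` defaults):

| criterion | attribute | severe | mild |
|---|---|---|---|
| CC1 | onset age (years, integer) | ≤ 11 | > 15 |
| CC2 | mean attacks/year, last 5 y | ≥ 6 | < 3 |
| CC3 | max attacks/year, all time | > 13 | < 6 |
| CC4 | attacks in the last year | ≥ 5 | < 5 |
| CC5 | long-term prophylaxis | Y / N (CC4 cohort only) | |

CC1–CC3 carry an explicit `intermediate` state for values between the
bounds; such patients never enter a severe-vs-mild contrast.  The bounds
originated from a decile-guarded median split of the source cohort's
distributions; they are treated here as fixed configuration, not re-derived
per cohort, because downstream contrasts must be stable under cohort
resampling.  Asymptomatic carriers (no onset age) default to CC1-M and to
attack counts of zero in CC2–CC4, and are flagged in the output; whether
they should enter the mild strata at all is a judgement call the caller can
override (`asymptomatic_is_mild=False`).

Onset ages are integers (years); attack rates are reals (5-year averages
are non-integral by construction).

## Normalization and VST

Size factors are median-of-ratios over reference genes with positive counts
in every sample, computed in log space (the DESeq convention: the factor is
`exp(median(log count − log geometric mean))`, which differs from an
arithmetic median of ratios only when the reference gene count is even),
then rescaled to geometric mean 1.  When no gene is all-positive — possible
on very sparse panels — a flagged fallback uses positive-count-only
geometric means.  Size factors of an already-normalized matrix are 1 to
machine precision.

The variance-stabilizing transform is `log2(count / size_factor + 1)`.
This is a deliberate stand-in for a fitted mean-dispersion VST curve: every
downstream use (PCA, correlations, outlier flagging, prediction-interval
tests) depends only on a monotone, roughly variance-stabilizing scale, not
on the exact curve, and the log form is exactly invertible and
zero-preserving.  At panel-typical means (≥ 30 normalized counts) the two
transforms are affinely close; at very low means the log form compresses
less than a true VST.

Technical/culture replicates are collapsed by summation before any
inference, making the individual the replication unit.  Summation (rather
than averaging) keeps counts integral, conserves totals, and is the correct
sufficient statistic for Poisson-layer noise.

PCA is the centered covariance eigendecomposition of samples in gene space
(scikit-learn, full SVD); component signs are fixed by making the
largest-magnitude gene loading positive so runs are deterministic.

## Differential expression

Per gene, a two-group negative-binomial GLM with log link:

    y_ij ~ NB(mu_ij, alpha_i),   Var = mu + alpha mu^2
    log mu_ij = log s_j + b0_i + b1_i x_j

with size factors as offsets.  For fixed dispersion the two group means
separate, so each is fitted by safeguarded Newton iteration on its 1-D
score equation; the dispersion is profiled on a log grid by bounded scalar
minimization (tolerance 1e-3 in log alpha, bounds [1e-8, 50]) of the
**Cox–Reid adjusted** profile likelihood (penalty `0.5 log det(X'WX)`).
The CR adjustment matters at this design size: the plain profile MLE of
alpha is biased low when two mean parameters are estimated from ~40
observations, which inflates the Wald statistic (measured null type-I
~0.062 at alpha 0.05 versus ~0.057 with CR, with the dispersion estimate
unbiased under CR).  The Wald statistic is `b1 / se(b1)` with the standard
error from expected Fisher information, referred to the standard normal
(two-sided).  No empirical-Bayes shrinkage across genes is applied — at 20
individuals per group the per-gene CR-MLE is adequate, and the estimator
stays testable in isolation.  Genes with zero counts throughout a group get
an undefined p-value (the fold change is unbounded) and can never be
significant.

Significance requires all of: p below the panel-wide Bonferroni constant
(default 3.65e-4 — the printed study constant for a ~136-gene panel; note
0.05/136 = 3.676e-4, the printed value is adopted verbatim and is
configurable), normalized group means ≥ 30 in both groups (low-count
comparisons produce unstable, biased-low p-values), and survival of outlier
handling: samples whose VST value deviates from the within-group median by
more than k = 5 median absolute deviations (raw MAD, no consistency
constant) are removed for the affected gene and the test repeated; the
post-removal p-value is the one that counts, and both are reported.  A zero
MAD flags nothing.  The MAD rule automates what was originally a manual
per-gene inspection; k = 5 on raw MAD corresponds to ≈ 7.4 standard
deviations for normal data, i.e. only gross excesses are touched.

## Per-individual dysregulation

On the VST scale, one individual's value for one gene is compared with the
control group by a normal prediction-interval z-test:

    z = (x − mean(ref)) / (sd(ref) sqrt(1 + 1/m)),   p = 2 Phi(−|z|)

with degenerate references (sd = 0) giving p = 1 if the value matches and
p = 0 otherwise.  This is the simplest "one observation vs a reference
group" test on a stabilized scale.  It is mildly anti-conservative with a
finite reference group: the exact reference distribution is t with m−1
degrees of freedom, so at m = 20 controls and nominal alpha 0.05 the true
rate is ≈ 0.065 (ratio ≈ 1.3 over nominal), shrinking as m grows.  The
calibration suite therefore checks the mean leave-one-out control count
against G·alpha with a factor-of-~1.6 band rather than a tight Monte-Carlo
band; at the study's operating point (alpha = 3.65e-4) the absolute excess
is negligible.  Controls are scored leave-one-out so their nonzero baseline
counts are estimated without testing a value against a reference containing
it.  Genes whose control normalized mean falls below the 30-count floor are
excluded, mirroring the DE filter.  Per-individual and per-gene counts are
the two marginals of one boolean matrix and always agree in total.
Group-wise count distributions are compared with two-sided Mann-Whitney U:
exact when both groups are ≤ 8 without ties, otherwise the tie-corrected
normal approximation without continuity correction.

## Co-expression modules

Pearson correlations are computed per subgroup over individuals
(replicates collapsed, VST scale; ≥ 4 individuals required; zero-variance
genes yield absent entries).  Candidate modules are connected components,
with ≥ 5 genes, of the graph joining genes at |r| ≥ 0.7 — the minimal
construction consistent with "each gene reaches 0.7 inside the group".
Absolute values are used because groups contain anti-correlated subparts.

**Specificity rule.**  A candidate is accepted only if exactly one subgroup
*can assemble a qualifying group from the candidate's genes*, i.e. contains
a connected component of ≥ 5 of those genes at |r| ≥ 0.7.  The stricter
alternative — requiring every candidate gene to have a strong edge, in
exactly one subgroup — is fragile in the presence of sampling noise: one
background gene hitchhiking onto the component via a single spurious edge
makes the all-genes condition fail everywhere else, so a module shared by
all subgroups would pass as "specific".  The set-level form rejects shared
modules at the measured ≥ 98% rate while leaving genuine one-subgroup
modules untouched.  The specificity check runs over
{control, CC4-M, CC4-S}.

**Sign partition.**  Modules are split into subparts A and B maximizing the
summed |r| over sign-consistent pairs (positive within a side, negative
across).  Up to 15 genes this is solved exactly by enumerating all
two-colorings (vectorized, ≤ 16k colorings); larger modules use the greedy
construction — seed with the strongest edge, attach each remaining gene to
the side with the larger signed agreement — plus single-gene flip
refinement.  The weighted fraction of sign-violated pairs is reported as a
frustration score (0 for a balanced sign pattern).  Side A is canonically
the larger side; with no negative correlations side B is empty.

Per-subgroup module summaries are medians over unique gene pairs
(within-A, within-B, and A–B cross pairs separately, since cross pairs are
negative by construction).  Subgroup differences are tested with a paired
Wilcoxon signed-rank over matched gene pairs (the pairing across subgroups
is what distinguishes this from the unpaired Mann-Whitney used for counts);
within-side and cross-side pair sets are tested separately by default and
can be pooled.  Small pair sets use the exact signed-rank distribution;
identical coefficient vectors give p = 1.

## Variant association

Deleteriousness filter: population frequency < 0.05 AND (nonsense or
frameshift, OR missense with CADD strictly > 18 and ≥ 2 of
{PolyPhen-HVAR, PolyPhen-HDIV, SIFT} deleterious).  Absent predictor calls
count as benign; a missing population frequency is treated as 0 (novel)
and flagged.  The filter is monotone in CADD and frequency.

Association: per severity subgroup, a 1-df goodness-of-fit chi-square of
observed alt vs ref allele counts against expectations `2nf` / `2n(1−f)`
from the cohort-wide allele frequency (the cohort is its own reference
population), no continuity correction.  Allele counting (2n) is the
default — "variant frequency" under random mating — with a genotype
(carrier, Hardy–Weinberg expectation `1−(1−f)^2`) unit available.  Missing
genotypes are excluded from both observed and expected counts.

The Bonferroni denominator is restricted to *testable* variants: for each
variant the minimum achievable p is computed at the most extreme possible
subgroup count (0 or all alt alleles, evaluated at the smallest tested
subgroup, the binding case); variants sorted by that floor ascending form
the testable set as the largest prefix of size k in which every member has
`min_achievable_p < 0.05 / k`.  This sorted-prefix fixed point resolves the
circularity (the testable count determines the threshold defining
testability) in the standard step-down manner.  S and M subgroups are
tested separately and both reported.

Family segregation: in families with ≥ 2 severe and ≥ 2 mild classified
members, a variant is `consistent_severe` iff carriers are exactly the
severe members (mirror for mild); any missing genotype renders the family
`inconsistent` for that variant.

## Synthetic cohort generator

The generator emulates the study's data *structure*: ~60 individuals
(20 controls + 20 mild + 20 severe by default), three cell types
(monocyte, M0 macrophage, IFN-γ macrophage) in triplicate, a targeted
panel of ~140 genes including *SERPING1*, right-skewed clinical
distributions, and an annotated variant panel.

*Clinical.*  Onset ages are log-normal (meanlog 2.3, sdlog 0.8 — median
≈ 10 y, strongly right-skewed) floored at 1 and rounded to integer years.
Last-year attack counts are `5 + NB(mean 7, shape 1.2)` for the severe
stratum and `min(NB(mean 1, shape 0.8), 4)` for the mild stratum, so strata
sit on the intended side of the CC4 threshold by construction and the
severe distribution spans roughly the published 5–72 range.  Five-year
averages multiply the last-year count by log-normal noise (sd 0.4); yearly
maxima multiply by Uniform(1.2, 2.5).  LTP status is Bernoulli(0.33)
(≈ 13/40 as observed); *SERPING1* variant class is NMD-susceptible with
probability 0.5.  Controls carry no attack data.

*Counts.*  Marginals are exactly NB(mu_g, alpha): each individual draws a
unit-mean gamma rate `R = G^{-1}(Phi(z))` (shape 1/alpha) and each replicate
is Poisson(mu_g R).  Replicates share the individual's R — only Poisson
noise differs — mirroring the biological-vs-technical hierarchy.
Dependence enters on the latent normal layer: per module and individual a
standard-normal factor F, with gene values
`z_g = s_g l F + sqrt(1 − l^2) eps_g`, side sign s (+1 A, −1 B) and
subgroup-specific loading l, giving latent correlations `± l_a l_b`.
Baseline log-means are uniform on [3.5, 7.5] (≈ 33–1800 counts,
panel-typical); the default dispersion 0.1 is a free parameter (the source
panel's dispersions are unpublished) at the low-biological-variability end
typical of sorted myeloid populations.  Planted effects multiply stratum
means by `2^log2fc`; NMD-class individuals get a ×0.5 multiplier (direction
from the source observations; magnitude a configurable default) on
*SERPING1*.

`loading_for_target_corr` inverts the copula's closed-form count-scale
Pearson correlation — `Cov(R_a, R_b)` by 2-D Gauss–Hermite quadrature
(40 nodes, CDF values clipped at 1e-15 before the gamma quantile; the
clipped nodes carry ~e^-40 weight), count variance `k mu + alpha (k mu)^2`
for k collapsed replicates — via Brent's method, so a module can be planted
at a stated empirical r.  Monte-Carlo checks at 500 individuals agree
within 0.01.  Calibration experiments pin the gene mean at 300 because the
Poisson attenuation of the latent correlation is mean-dependent
(≈ 1.5% at mean 300, ≈ 10% at mean 33); correlations measured on the VST
scale differ from count scale by < 2% at these settings.

*Variants.*  Genotypes are Binomial(2, f) per individual, with
stratum-specific f for planted associations.  Output is a minimal VCF v4.2
(GT only) plus an annotation TSV keyed `chrom:pos:ref:alt`, read back via
pysam.

*Randomness.*  One root seed; named child streams
(clinical, gene_means, latent, counts, variants) via `SeedSequence.spawn`,
recorded in the truth JSON.  Identical configs give byte-identical outputs.

*What it does not emulate* — and therefore what green tests do not show
about real data: no read- or UMI-level noise (counts are post-deduplication
molecules), no batch/run effects or GC/length biases, no cell-type-specific
dispersion trends or mean-dispersion coupling, clinical attributes
independent of expression (no confounding between severity and counts
beyond planted effects), Hardy–Weinberg genotypes without relatedness or
linkage, and no missing data unless planted.  Recovery rates measured here
are therefore upper bounds for data with unmodelled structure.

## Experiment sizes

The calibration/recovery experiments (`haeseq.evaluation`, used by the test
suite and `scripts/acceptance.py`) run at the study's design scale: 20
individuals per subgroup, triplicates, dispersion 0.1; 4×500 null genes for
DE calibration; 50 cohorts for module recovery/specificity; 100 cohorts for
differential-correlation power, dysregulation ordering and the NMD
direction; 30 replicates of 200 genes × 40 controls for dysregulation null
calibration.  Exhaustive oracles (module detection/partition, testable-set
prefix, rank-test permutation distributions) run on panels of ≤ 12 genes,
15 variants, and ≤ 10 pairs respectively, where full enumeration is exact
and fast.

## Known limitations

* The NB Wald p-value uses the normal reference; at n ≈ 20/group it is
  mildly anti-conservative (type-I ≈ 0.057 at nominal 0.05), as is the
  dysregulation z-test (see above).  Both are the field's standard forms.
* The log2 VST stand-in under-stabilizes very low counts; procedures
  gated by the 30-count floor are unaffected.
* Module detection at |r| ≥ 0.7 with < 15 individuals per subgroup is
  noise-dominated (the null correlation spread crosses the threshold);
  results at the study's n = 20 are already conservative-margin, and the
  CLI will happily run smaller cohorts without warning beyond statistics.
* The restricted-Bonferroni testable set uses the smallest tested subgroup
  as the binding case for every variant; per-subgroup testable sets would
  be marginally more powerful but no longer a single family.
* The greedy+refinement sign partition above 15 genes is a heuristic for a
  MAX-CUT-equivalent problem; the frustration score makes imperfect
  partitions visible.
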