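# End-to-end demonstration cohort at the study design size (runs in ~15 s).
# 20 controls + 20 mild + 20 severe patients, one gene panel of 80 genes
# across three myeloid cell types in triplicate, with one planted
# expression shift, one severity-specific co-expression module and a
# variant panel including a planted frequency shift.
simulate:
  seed: 42
  n_controls: 20
  n_mild: 20
  n_severe: 20
  n_genes: 80
  nb_dispersion: 0.1
  serping1_log_mean: 5.7        # ~300 normalized counts
  nmd_factor: 0.5
  de_effects:
    - {gene: G010, contrast: severe, log2fc: 1.5}
    - {gene: G011, contrast: patient, log2fc: -1.0}
  module_specs:
    - gene_ids: [G020, G021, G022, G023, G024, G025, G026, G027]
      side_of_gene: {G020: A, G021: A, G022: A, G023: A, G024: A, G025: B, G026: B, G027: B}
      loading_per_subgroup: {control: 0.0, mild: 0.0, severe: 0.9}
  variant_specs:
    - {gene: FXII, frequency: 0.3, population_frequency: 0.25}
    - {gene: THBS1, frequency: 0.02, consequence: nonsense, population_frequency: 0.01}
    - gene: KNG1
      frequency: 0.2
      cadd: 24.0
      polyphen_hvar: deleterious
      polyphen_hdiv: deleterious
      population_frequency: 0.02
      group_frequencies: {severe: 0.45, mild: 0.1, control: 0.2}

thresholds:
  cc4_severe_min: 5.0           # attacks in the last year

de:
  alpha: 3.65e-4                # Bonferroni-corrected 0.05 for the panel
  min_mean: 30.0
  mad_k: 5.0

coexpr:
  r_min: 0.7
  min_size: 5

varassoc:
  criterion: cc4
  family_alpha: 0.05
  unit: allele
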