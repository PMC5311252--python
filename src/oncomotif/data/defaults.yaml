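# Documented defaults for every generator and analysis stage.
# These are the values the acceptance tests and the acceptance script use;
# they can be overridden per stage via --config on the CLI.

seed: 0

screen_sim:
  n_vectors: 450          # library size
  n_replicates: 3         # biological triplicates per condition
  depth: 1.0e6            # expected reads per replicate
  dispersion: 0.05        # NB overdispersion phi (var = mu + phi*mu^2)
  n_enriched: 15          # planted proliferation hits
  n_depleted: 15          # planted drug-sensitization hits
  n_dual: 11              # depleted clones drawn from the enriched set
  log2_effect_enrich: 2.5
  log2_effect_deplete: 2.5
  motif: AAGUGC           # planted seed motif
  abundance_sigma: 0.6    # lognormal sigma of baseline clone abundance

omics_sim:
  n_genes: 12000
  n_targets: 500
  n_replicates: 3
  delta_mrna: -1.0        # mean log2 repression of true targets, mRNA
  delta_protein: -0.8     # same, protein level
  noise_sd: 0.3           # replicate noise, log2 units
  protein_coverage: 0.7   # fraction of genes observed at protein level
  n_algorithms: 9
  pred_p_target: 0.7      # per-algorithm prediction probability, targets
  pred_p_null: 0.1        # same, non-targets

cohort_sim:
  n_tumors: 400
  n_normals: 20
  n_family_mirnas: 8
  n_background_mirnas: 40
  n_cellcycle: 90          # activity-induced (proliferation) genes
  n_repressed: 45          # additional activity-repressed target genes
  n_null: 500
  beta_ts: 0.8            # latent-activity coupling to TS genes (sign: down)
  beta_cc: 0.8            # coupling to cell-cycle genes (up)
  mut_base: -1.2          # logistic intercept, TP53 mutation probability
  mut_slope: 1.0          # logistic slope on activity
  hazard_slope: 0.8       # log relapse hazard per unit activity
  base_hazard: 0.15
  censor_rate: 0.3
  noise_sd: 0.7           # mRNA sample noise, log2 units
  mirna_coupling: 1.0     # log2 family-miRNA expression per unit activity
  mirna_noise_sd: 0.5
  normal_offset: -2.0     # activity shift of normal-tissue samples
  normal_sd: 0.5          # normals are more homogeneous than tumors
  baseline_sd: 0.5        # spread of per-gene baseline log2 expression

screen:
  min_reads: 300          # raw-count filter: >= in every replicate of one condition
  lfc_threshold: 1.5      # volcano cutoff, log2 units
  p_threshold: 0.05
  pseudocount: 0.5        # added to RPM before log2

motif:
  k: 6                    # shared-motif length

targets:
  p_threshold: 0.05
  min_predictions: 5      # ">4 algorithms" consensus rule

signature:
  pct: 5.0                # top/bottom percentile group size
  fdr_threshold: 1.0e-5
  lfc_threshold: 1.0

network:
  threshold: -0.15        # strict inverse-correlation cutoff
  log_scale: true         # correlate against log2(sum + 1)
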