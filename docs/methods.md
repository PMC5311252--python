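# Methods

## Screen statistics

A pooled miR-Vec screen measures relative clone abundance per condition by
deep sequencing of recovered inserts. Counts are scaled per sample to reads
per million (column sum 1e6). The minimum-read filter retains a vector iff
some condition has every replicate's **raw** count at or above the threshold
(default 300): the filter describes sequencing evidence, a property of raw
reads, so it is applied before normalization.

The per-vector test statistic operates on log2(RPM + 0.5). The log scale
treats enrichment and depletion symmetrically, and the pseudocount keeps
values finite for zero counts; the alternative of testing raw normalized
counts or ratios is exposed nowhere because the downstream fold cutoff is
itself a log2 quantity. The test is a two-sided two-sample t-test over
replicates — Welch by default (n = 3 groups routinely have unequal
variances), pooled-variance Student via `equal_var=True`. Rows where both
groups are exactly constant take the analytic limit p = 1 (equal means) or
p = 0 (unequal), and carry a `zero_variance` flag so users can exclude
them. Classification cutoffs follow the volcano convention: inclusive on
the fold (|log2FC| ≥ 1.5), strict on p (< 0.05). No multiple-testing
correction is applied at the screen stage by design; the planted-recovery
tests quantify the resulting error rates directly.

The phenotype helpers are plain arithmetic: proliferation index
(S + G2/M)/G0G1, and relative qPCR quantification where per-replicate
ΔCq = Cq(target) − Cq(reference) and the summary ΔΔCq is the **ratio** of
the mean ΔCq to the control condition's mean ΔCq. The ratio convention
(rather than the textbook subtraction) is deliberate and matched to the
upstream instrument-software output this formula emulates.

## Seed motifs

The seed is defined as mature-sequence positions 1–8 (1-based); the more
common 2–7/2–8 definitions are available through `seed_region` but are not
the default, because position-1 matches are part of the family definition
used throughout. FASTA input in the DNA alphabet is coerced T→U, since
public catalogues are distributed in RNA but user files often are not.
Shared-motif discovery enumerates all k-mers (default k = 6) at offsets
0..8−k within hit seeds and counts carriers among hits and the whole
library; ties in the ranking break lexicographically. The hypergeometric
enrichment p-value is a quantification layer added on top of the
qualitative shared-seed observation: P(X ≥ x) for x motif carriers among n
hits drawn from a catalogue of N seeds containing K carriers.

## Target integration

Differential tables use the same Welch machinery as the screen, on
log2-scale replicate matrices (inputs must already be log2; no conversion
is guessed). Prediction consensus (0–9 algorithms) is consumed as an
integer annotation — running the prediction algorithms is out of scope.
Strata are "0", "1-2", "3-4", ">4" (ASCII hyphens for file/terminal
safety). The putative-target rule is
(mRNA down AND p < 0.05) OR (protein observed AND down AND p < 0.05),
AND prediction count ≥ 5; genes missing from the protein tier are evaluable
through the mRNA branch only, and the `evidence` column records which
branch fired. Missing protein values are never imputed. The ECDF shift per
stratum against the no-prediction reference is quantified with the
asymptotic two-sample Kolmogorov–Smirnov test — a quantification of what is
classically a visual comparison.

## Cohort signature and survival

Family expression is summed on the native RPM scale; wherever a symmetric
scale is needed (correlation, covariates) log2(sum + 1) is used, with the
raw scale available by flag. Percentile groups take k = ceil(n·pct/100)
samples per tail, ties broken by sample id for determinism. The signature
is the set of genes with BH FDR < 1e-5 and |log2FC| > 1 between the
high and low groups (two-sided t-test per gene, BH step-up over all tested
genes). Sample clustering uses d = 1 − Spearman ρ over signature genes with
complete linkage; the two main clusters are the k = 2 cut of the final
merge, and the cluster with the larger mean signature expression is
labelled `cluster_high` (natural for a signature dominated by induced
genes). Genes are clustered with the same metric for heat-map ordering.
Expression is not standardized before clustering — the rank-based distance
makes per-sample monotone transforms irrelevant — though constant sample
profiles are rejected by name. Genotype association is the two-sided
Wilcoxon rank-sum test, exact by enumeration for combined n ≤ 20 and
normal-approximated with tie correction otherwise. Survival uses the
Kaplan–Meier product-limit estimator, the two-group log-rank test, and Cox
proportional-hazards regression with Efron tie handling (the only tie
method exposed: the backing fitter implements Efron, and tie handling only
matters with tied event times). Categorical covariates (cluster, mutation,
copy-number status) are expanded to indicators. Significance is assessed at
the 5% level throughout the survival tier.

## Correlation networks

Per-gene Pearson r against log2(sum + 1); genes with zero variance get an
undefined (NaN) r with a flag rather than a fabricated zero.
Inverse-correlated targets are candidates with r strictly below −0.15.
Cancer types are ranked by the arithmetic mean r over the curated TS panel,
ascending (most negative first), ties on the label. Network edges are
copied from a shipped curation file (`data/network_curation.tsv`) encoding
the known regulatory relations between the TS panel, the E2F/MYC
transcription factors, the miRNA host genes and cell-cycle markers; the
module never infers edges — it is a correlation profiler, not a structure
learner. Color bins default to symmetric edges at ±0.15 and ±0.4.

## Synthetic data

The generators emulate the statistical structure the analyses assume, with
planted truth for recovery testing. All defaults live in
`data/defaults.yaml`; each generator is a pure function of its config
(identical seeds give byte-identical output).

**Screen.** Counts are negative-binomial with variance μ + φμ², sampled as
a gamma–Poisson mixture; φ defaults to 0.05, a choice made for testability
(the real screen's dispersion is unknown). Baseline clone abundances are
lognormal (σ = 0.6), renormalized per condition so each replicate's
expected total equals the depth (1e6). Planted enriched vectors multiply
their second-condition abundance by 2^2.5; planted depleted vectors lose
2^2.5 in the third condition; 11 of the 15 depleted clones are drawn from
the 15 enriched ones, emulating clones that both proliferate and sensitize
(so hit intersection has a planted answer). Hit miRNAs carry the planted
motif at a random offset within seed positions 1–8; background seeds are
rejection-sampled to be motif-free, guaranteeing motif specificity.

**Omics.** Gene-level log2 abundances are Gaussian around per-gene
baselines; planted targets shift the mimic-arm mean by −1 (mRNA) and −0.8
(protein); replicate noise sd 0.3; 70% of genes appear in the protein
tier. Prediction counts are Binomial(9, 0.7) for targets and
Binomial(9, 0.1) otherwise, so roughly 90% of true targets clear the
≥5-algorithm rule while non-targets almost never do.

**Cohort.** A single latent activity per sample (standard Normal for
tumors; Normal(−2, 0.5) for normal tissue — normals sit low and are more
homogeneous than tumors, which is what lets them co-cluster with
low-activity tumors) drives every tier: family-miRNA log2 expression rises
1 per unit activity before per-sample RPM rescaling; the 7 TS-panel genes
and 45 additional repressed target genes fall with slope 0.8; 90
cell-cycle genes rise with slope 0.8; 500 null genes are noise.
Gene baselines have sd 0.5 and sample noise sd 0.7: the between-sample
Spearman correlation contrast that separates the two clusters is governed
by the variance of the coupling slopes across signature genes relative to
baseline-plus-noise variance, so a stylized flat baseline produces the
clear two-cluster structure this family of cohorts exhibits, at the cost
of realism in absolute expression levels. TP53 mutation (and, with an
independent draw, MYC gain) is Bernoulli(logistic(−1.2 + activity)), set
to 0 for normals; relapse time is exponential with rate
0.15·exp(0.8·activity), independently censored with probability 0.3 at a
uniform fraction of the event time.

**What the generators do not emulate.** Read-level sequencing artifacts,
isoform structure, batch effects, copy-number segments, compositional
coupling between the mRNA genes, non-proportional hazards, and the heavy
inter-gene correlation of real transcriptomes. Passing recovery tests
therefore demonstrates that the inference chain is correct under its own
model assumptions — not that those assumptions hold in any particular real
cohort.

## Numerical choices and degenerate inputs

- Zero-variance t-test rows: analytic limits (p = 1/0), flagged.
- Zero-total count columns: rejected with the sample named.
- Constant clustering profiles and constant Cox covariates: rejected with
  the offender named.
- No events in survival data: KM curves are flat and the log-rank p is
  reported as NaN rather than fabricated.
- Stage seeds for the umbrella pipeline derive from one master seed via
  `numpy.random.SeedSequence` spawning; all derived seeds are < 2^31.
- Problem sizes in the test-suite recovery checks (e.g. 20 screen seeds,
  10 omics/cohort seeds, 1000-sample Cox simulations) were chosen as the
  smallest replications at which the Monte-Carlo error of each recovery
  rate is clearly below its acceptance margin.

## Known limitations

- The hypergeometric motif enrichment assumes seeds are independent draws;
  paralogous miRNA families violate this, biasing p downward.
- The 5th-percentile grouping rule (ceil) is one of several defensible
  roundings; group sizes differ by at most one sample between conventions.
- Breslow tie handling for Cox regression is not exposed (the backing
  implementation is Efron-only); with continuous simulated times the two
  coincide.
- The ΔΔCq ratio convention is unusual; users wanting the subtractive
  2^−ΔΔCq convention should compute it from the per-replicate ΔCq values
  the function returns.
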