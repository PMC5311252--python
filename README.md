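# oncomotif

Analysis toolkit for the inference chain that links a shared miRNA seed
motif to oncogenic signaling: pooled miRNA-overexpression screen statistics,
seed-family motif discovery, multi-evidence miRNA target integration,
cohort-level expression signatures with survival analysis, and pan-cancer
miRNA–mRNA correlation profiling. Every analysis tier ships with a matching
synthetic-data generator that plants known effects, so the whole chain can
be exercised end-to-end against ground truth.

## The scientific problem

miRNAs repress genes through base pairing between the seed region (5'
nucleotides 1–8 of the mature miRNA) and mRNA 3'UTRs. A family of human
miRNAs sharing the hexamer **AAGUGC** in their seed (including miR-372-3p,
miR-373-3p, miR-519c-3p and miR-520c-3p, and in total 28 human miRNAs from
seven loci) behaves as a functional unit: overexpression increases cancer
cell proliferation and sensitizes cells to EGFR tyrosine-kinase inhibitors,
apparently by repressing a common panel of tumor suppressors (TGFBR2,
CDKN1A, LATS2, RBL2, ZBTB7A, PTEN, RB1) that guard the G1/S transition.
This package implements the statistics needed to find and characterize such
a "seed-family oncomotif" from data:

1. **Screen** (`oncomotif.screen`). miR-Vec read counts per condition
   (baseline `Ctrl0`, 30-day untreated `Ctrl30`, 30-day drug `Gef30`) are
   normalized to reads per million, filtered to vectors sequenced ≥300
   times in every replicate of at least one condition, and tested per
   contrast with a two-sided t-test on log2(RPM + 0.5); volcano cutoffs
   |log2FC| ≥ 1.5, p < 0.05 classify enriched/depleted clones.
2. **Motif** (`oncomotif.motif`). k-mers shared between hit seeds are
   enumerated against the library background; over-representation is
   quantified with a one-sided hypergeometric test
   p = P(X ≥ x), X ~ Hypergeom(N, K, n); the seed family of a motif is all
   catalogue miRNAs whose seed contains it.
3. **Targets** (`oncomotif.targets`). For mimic-vs-control mRNA and protein
   replicate matrices, per-gene Welch t-tests give log2FC and p; genes are
   stratified by the number of prediction algorithms (of 9) nominating
   them; fold-change ECDFs per stratum are compared by two-sample
   Kolmogorov–Smirnov; a putative target is downregulated (log2FC < 0,
   p < 0.05) at mRNA and/or protein level AND predicted by ≥ 5 algorithms.
4. **Cohort** (`oncomotif.cohort`). Family expression is summed per sample;
   the top/bottom 5th-percentile groups define a differential signature
   (t-test, Benjamini–Hochberg FDR < 1e-5, |log2FC| > 1); samples are
   clustered on signature genes (1 − Spearman ρ, complete linkage, k = 2
   cut); genotype association uses the Wilcoxon rank-sum test and survival
   uses Kaplan–Meier/log-rank plus Cox proportional hazards (Efron ties).
5. **Network** (`oncomotif.network`). Per-gene Pearson correlation with
   log2(summed family expression + 1); candidates with r < −0.15 (strict)
   are called inverse-correlated targets; cancer types are ranked by mean
   TS-panel correlation; a curated node/edge file is decorated with
   correlation color bins for graph export.

## Worked example

```python
from importlib import resources
import oncomotif as om

# the four validated screen-hit miRNAs ship with the package
cat = om.read_fasta(resources.files("oncomotif") / "data" / "oncomotif_mirnas.fasta")
for r in cat.records:
    print(r.mirna_id, om.extract_seed(r.sequence))

# simulate a default screen (450 vectors, triplicates, 15+15 planted hits
# sharing AAGUGC, 11 of them dual) and analyze it
table, catalogue, truth = om.generate_screen(om.ScreenSimConfig(seed=1))
res = om.analyze_screen(table)
enriched = res.index[res["class_Ctrl30_vs_Ctrl0"] == "enriched"]
depleted = res.index[res["class_Gef30_vs_Ctrl30"] == "depleted"]
hits = sorted(set(enriched) | set(depleted))
print(om.find_shared_motifs(hits, catalogue, k=6).head(3))
print(om.motif_enrichment("AAGUGC", hits, catalogue))
```

prints

```
hsa-miR-372-3p AAAGUGCU
hsa-miR-373-3p GAAGUGCU
hsa-miR-519c-3p AAAGUGCA
hsa-miR-520c-3p AAAGUGCU
 motif  hit_count  background_count
AAGUGC         19                19
AGUGCA          7                 7
AGUGCC          4                 4
6.94e-34
```

All four packaged miRNAs carry AAGUGC within their 8-nt seed. In the
simulated screen, the analysis recovers 15 enriched and 15 depleted vectors
(11 dual), and all 19 distinct hits share AAGUGC — found in no background
seed — giving an overwhelming hypergeometric enrichment. The same pattern
at cohort level (summed family expression anti-correlated with the TS
panel, co-varying with proliferation genes, TP53 mutation and relapse) is
produced by `oncomotif.generate_cohort` and the `cohort`/`network` modules;
`oncomotif run --seed 1 --out out/` executes the whole chain and writes
per-stage tables.

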