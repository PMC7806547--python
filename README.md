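# guildscan

Guild-based analysis of gut-microbiome ASV tables: detect **co-abundance
groups (CAGs)** — sets of amplicon sequence variants whose abundances
co-vary across samples and therefore plausibly act as one ecological
unit — and link them to host metabolic phenotypes.

The package is written for microbiome researchers analysing 16S rRNA
amplicon studies (e.g. diet-intervention experiments in mice) who have a
denoised ASV count table, per-sample metadata (group, timepoint, cage)
and terminal phenotype measurements (hepatic triglyceride, serum
cholesterol, cecal short-chain fatty acids), and who want a
strain-level, taxonomy-independent view of which parts of the community
respond to a treatment.

## Method

Taxon-based summaries blur ecology: ASVs assigned to the same genus can
respond to a treatment in opposite directions, while unrelated ASVs that
share a resource move together. The guild approach clusters ASVs by
their co-abundance instead of their taxonomy:

1. **Preprocess.** Rarefy every sample to a common depth (default
   16,500 reads; shallower samples are dropped and reported) and keep
   ASVs present in at least 20% of samples. The filter report states the
   fraction of each sample's reads the retained ASVs carry.
2. **SparCC correlations.** Sequencing counts are compositional, so
   correlations of fractions are biased. SparCC estimates *basis*
   correlations ρᵢⱼ of the latent absolute abundances from the log-ratio
   variances tᵢⱼ = Var[log(xᵢ/xⱼ)] under the sparsity approximation

   tᵢⱼ ≈ ωᵢ + ωⱼ − 2 ρᵢⱼ √(ωᵢ ωⱼ),  Σⱼ ρᵢⱼ ≈ 0,

   solving a linear system for the basis variances ωᵢ, iteratively
   excluding the strongest correlated pair (|ρ| > 0.1), resampling
   fractions from a Dirichlet posterior and taking the element-wise
   median over draws. Pseudo p-values come from a permutation null
   (each ASV's counts shuffled independently across samples; default
   100 replicates).
3. **Ward clustering.** The SparCC distance d = 1 − ρ is clustered with
   Ward's criterion (Lance–Williams on squared dissimilarities).
4. **PERMANOVA tree cut.** From the root down, each node's two child
   clusters are compared by PERMANOVA,

   pseudo-F = [(SS_total − SS_within)/(a−1)] / [SS_within/(N−a)],

   with 999 permutations; a node whose children do not separate
   (p > 0.001) becomes a single CAG and descent stops. By default the
   permutation null draws the two pseudo-clusters from *all* tree
   leaves, which keeps the test calibrated even though Ward already
   chose the most separated split (see `docs/methods.md`).
5. **Community statistics.** Shannon (bits) and observed-ASV alpha
   diversity with per-timepoint Kruskal–Wallis + Benjamini–Hochberg;
   Bray–Curtis beta diversity, PCoA, and pairwise PERMANOVA (9,999
   permutations) per timepoint.
6. **Association.** CAG relative abundances vs phenotypes by Spearman
   correlation with BH FDR over the full CAG × variable family;
   differential CAG abundance between groups by Mann–Whitney with BH per
   group pair; Z-scores of group means for heatmaps. A co-abundance
   network (edges with |ρ| ≥ 0.6) is exported as GraphML/SIF for
   Cytoscape.

A synthetic-data generator plants known guild structure (a log-normal
factor model with a configurable within-guild correlation, multinomial
sequencing noise at negative-binomial depth ≈ 32,000 reads) and coupled
phenotypes, so every stage of the pipeline can be validated against a
machine-readable ground truth.

## Worked example

```python
from guildscan.simulate import default_config, generate, evaluate_recovery
from guildscan.pipeline import run_analysis, PipelineParams

data = generate(default_config(seed=1))   # 3 groups x 10 mice x 5 timepoints
res = run_analysis(data.table, data.metadata, data.phenotypes,
                   PipelineParams(seed=1))

prev = res["prevalence_report"]
print(f"ASVs: {data.table.shape[1]} -> {res['filtered'].shape[1]} after the 20% prevalence filter")
print(f"reads retained: {prev.mean_retained_pct:.2f} +/- {prev.sd_retained_pct:.2f} %")
print(f"CAGs: {res['assignment'].n_cags}")
truth = {a: g for a, g in data.truth_guilds.items() if a in res["filtered"].asv_ids}
print(f"adjusted Rand index vs planted guilds: {evaluate_recovery(res['assignment'], truth):.3f}")
print(res["associations"].sort_values("fdr").head(3)[["cag", "variable", "rho", "fdr"]].to_string(index=False))
```

prints

```
ASVs: 150 -> 126 after the 20% prevalence filter
reads retained: 99.97 +/- 0.03 %
CAGs: 17
adjusted Rand index vs planted guilds: 0.772
 cag   variable      rho      fdr
CAG1   butyrate 0.793993 0.000017
CAG1 propionate 0.717019 0.000422
CAG1    acetate 0.703226 0.000498
```

The 150 simulated ASVs carry 10 planted guilds; the rare tail is removed
by the prevalence filter while the retained ASVs still cover >99.9% of
reads. The tree cut returns 17 CAGs that largely track the planted
guilds (ARI 0.77 — guilds survive, some split by sampling noise), and
the planted SCFA-producer guild (recovered as CAG1) shows the expected
strong positive Spearman correlations with cecal butyrate, propionate
and acetate at low FDR.

The same pipeline runs from the shell:

```bash
guildscan simulate --seed 1 --out-dir sim/
guildscan run --config pipeline.yaml      # paths + parameters in YAML
# or stage by stage:
guildscan sparcc --input sim/table.tsv --bootstrap 100 --seed 1 --out corr.tsv pvals.tsv
guildscan guilds --corr corr.tsv --table sim/table.tsv --alpha 0.001 --permutations 999 --seed 1 --out-dir guilds/
guildscan diversity --table sim/table.tsv --metadata sim/meta.tsv --depth 16500 --out-dir div/
guildscan assoc --guilds guilds/cag_abundance.tsv --phenotypes sim/phen.tsv --metadata sim/meta.tsv --timepoint d105 --out-dir assoc/
```

Every run writes a `manifest.json` (versions, seed, config echo,
per-stage record counts) sufficient to reproduce it exactly.

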