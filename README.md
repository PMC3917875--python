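# coexmod

Discovery and scoring of **bimodal gene co-expression modules** across
compendia of expression datasets, with the downstream clinical statistics
used in breast-cancer transcriptomics: many tumor phenotypes (estrogen
signaling, proliferation, immune infiltration, stromal content) manifest as
groups of genes that switch between "on" and "off" states together across
tumors. `coexmod` finds those groups per dataset, keeps the patterns that
recur across datasets, condenses them into consensus modules, and scores any
new sample for module activity — so that module scores can stand in for
whole expression profiles in subtype prediction, survival and
treatment-response models.

## Method at a glance

1. **Normalize per dataset**: z-score each gene; compute the per-array
   quality score avg.z (mean gene-wise z per array); replace each gene by its
   OLS residual on avg.z; re-z-score.
2. **Bimodality**: fit each gene with a two-component equal-variance
   Gaussian mixture (EM) and compute the Bimodality Index
   `BI = sqrt(π(1−π))·|μ₂−μ₁|/σ`; compare against an empirical null of
   10,000 standard-normal samples of the same size; call genes with
   Benjamini–Hochberg FDR < 0.05.
3. **Cluster** bimodal genes per dataset by model-based clustering
   (diagonal/spherical Gaussian mixture families, BIC model selection).
4. **Metagenes**: summarize each cluster by its unit-norm PC1 loading vector
   and score every sample in the compendium by inner-product projection.
5. **Consensus modules**: keep clusters whose scores correlate at r > 0.7
   with enough other clusters; hierarchically cluster the correlation rows
   (Euclidean, complete linkage); cut by silhouette (or fixed k); distill
   each module to genes present in >1/3 of its member clusters; weights are
   the PC1 of the pooled contributing datasets.
6. **Validate** module distinctness pairwise with SigClust (cluster index
   CI = within-cluster SS / total SS against a Gaussian null with hard- or
   soft-thresholded covariance eigenvalues).
7. **Associate** module scores with phenotypes: coherence in tumors vs cell
   lines (tumor-intrinsic vs microenvironment-extrinsic modules), subtype
   AUC with Youden thresholds, published-signature correlation, Cox
   proportional-hazards survival, logistic pCR and metastatic-site models,
   BH-adjusted.

A synthetic-compendium generator with planted modules, quality confounders,
tumor/cell-line contexts and module-driven clinical outcomes makes the whole
pipeline testable without any external data. See `docs/methods.md` for the
models, defaults, and known limitations.

## Worked example

Generate a compendium with five planted 40-gene modules across six tumor
datasets, run the pipeline, and check recovery:

```python
import coexmod as cm

comp, truth = cm.generate_compendium(cm.default_config(seed=7))
cfg = cm.PipelineConfig(seed=7, min_neighbors=5)   # 6 datasets: max 5 partners
result = cm.run_pipeline(comp.datasets, cfg, run_sigclust=False)

print(len(result.modules))
for m in result.modules:
    best = max(truth.module_names,
               key=lambda t: len(set(m.gene_ids) & set(truth.module_genes(t))))
    a, b = set(m.gene_ids), set(truth.module_genes(best))
    print(m.module_id, len(m.gene_ids), best, round(len(a & b) / len(a | b), 2))
```

Output:

```
5
mod1 23 M5 0.57
mod2 21 M2 0.53
mod3 17 M3 0.42
mod4 16 M1 0.4
mod5 21 M4 0.53
```

All five planted modules are recovered as distinct consensus modules (one
per planted latent), each distilled to its higher-loading core genes: at the
default effect size (Δ = 3 noise-sd, 30% activation) per-gene bimodality
detection operates near the Bimodality Index's intrinsic boundary, so the
distilled sets hold roughly the strongest half of each planted module's
genes — the expected behavior at this signal strength, not a failure of the
aggregation (see `docs/methods.md`). Module scores separate latent-on from
latent-off samples with AUC ≈ 1.0.

The same stages are available from the shell:

```sh
coexmod simulate --out sim/ --seed 7
coexmod run --manifest sim/manifest.tsv --out results/ --seed 7
coexmod score --weights results/module_weights.tsv --data sim/D1.tsv --out scores.tsv
```

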