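# sagesig

A tested, reusable pipeline for tag-based (SAGE-style) comparative
transcriptomics: ditag extraction and tag counting from concatemer reads,
library normalization to a fixed tag total, virtual reference libraries
by per-tag averaging, pairwise two-proportion z-test differential
expression, "multifunctional" signature set algebra, resampling-based
enrichment testing, hierarchical correlation clustering of libraries, and
efficiency-corrected (Pfaffl) relative qPCR quantification. A synthetic
data module generates every input the pipeline consumes, with a
ground-truth ledger, for end-to-end verification.

## Modules

| module | role |
| --- | --- |
| `sagesig.sagetags` | concatemer parsing, ditag extraction (CATG anchoring site), tag counting, tag-to-gene aggregation |
| `sagesig.libnorm` | normalization to 100,000 tags; virtual reference library by per-key averaging |
| `sagesig.diffexpr` | pooled two-proportion z-test, pairwise and consistent differential expression, cluster-size bias summaries |
| `sagesig.signatures` | expressed/common cores, the >=2-category multifunctional grid, signature reports with unique/shared partitions and the differential ("biased") subset |
| `sagesig.enrichment` | Monte-Carlo resampling baseline + exact one-sample binomial enrichment test |
| `sagesig.clustering` | 1 − Pearson distances, agglomerative clustering, Newick output, farthest-pair queries |
| `sagesig.qpcr` | standard-curve efficiency fitting and Pfaffl relative expression ratios |
| `sagesig.synthetic` | reproducible generators (transcriptomes, planted fold-changes, libraries, categories, qPCR tables) and the study-shaped scenario |
| `sagesig.pipeline` / `sagesig.cli` | YAML-configured end-to-end orchestration and the `sagesig` command |

## CLI

```bash
# generate the study-shaped synthetic dataset (7 libraries, planted truth)
sagesig synth --scenario paper --seed 7 --out data/

# individual stages
sagesig tags reads.fa --out tags.tsv
sagesig normalize data/Met1.genes.tsv --out met1.norm.tsv
sagesig de --ref data/Met1.genes.tsv --other data/Met2.genes.tsv --out de.tsv
sagesig enrich --subset list.tsv --universe universe.tsv --de-list de_genes.tsv \
    --iterations 100000 --seed 17 --out enrichment.json
sagesig cluster data/Met*.genes.tsv --out tree.nwk
sagesig qpcr --ct data/qpcr_ct.tsv --dilutions data/qpcr_dilutions.tsv --out qpcr/

# full pipeline from a config file
sagesig run --config config.yaml --out results/
```

A minimal `config.yaml`:

```yaml
inputs:
  met_libraries: [data/Met1.genes.tsv, data/Met2.genes.tsv, data/Met3.genes.tsv,
                  data/Met4.genes.tsv, data/Met5.genes.tsv]
  nm_libraries: [data/NM1.genes.tsv, data/NM2.genes.tsv]
  categories: data/categories.tsv
  metastasis_list: data/metastasis_list.tsv
  qpcr_ct: data/qpcr_ct.tsv
  qpcr_dilutions: data/qpcr_dilutions.tsv
params:
  min_count: 2        # "expressed" threshold
  alpha: 0.05         # two-sided z-test level, no multiplicity correction
  ztest_totals: raw   # raw counts + true totals (or: normalized)
  consistency: per_library
  iterations: 100000  # enrichment resampling
  seed: 17
  linkage: average
```

All parameters not fixed by the underlying protocol (thresholds, test
level, linkage, totals mode) are surfaced in the config with documented
defaults.

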