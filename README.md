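# m6akit

Gene-level m6A epitranscriptomic landscape analysis from IP/input count
matrices, built around a shared negative-binomial count-statistics engine:

- **nbtest** — median-of-ratios size factors, method-of-moments dispersion
  with decile-trend shrinkage, two-group NB Wald test (log link,
  log-size-factor offset), Benjamini–Hochberg adjustment. Drives both
  IP-vs-input enrichment and KO-vs-WT expression contrasts.
- **landscape** — per-population relative m6A Z-scores (Z of the Wald
  statistic over all scored genes, divisor-n SD), high-confidence target
  calls (`log2FC > 1` and `p < 0.05`, strict), and multi-population
  landscape assembly with explicit missingness.
- **inheritance** — classifies each population's targets as
  `root_set` / `inherited` / `de_novo` along a rooted developmental
  hierarchy (immediate-parent or any-ancestor mode) and summarizes origin
  fractions per stage.
- **clustering** — K-means co-clustering of mean-centered m6A and log
  expression profiles, per-cluster m6A–mRNA correlation signs, and
  upper-tail hypergeometric gene-set enrichment (GMT input).
- **overlay** — KO-vs-WT DEG calls (`|log2FC| > 0.5`, `p < 0.05`)
  intersected with m6A target status.
- **kinetics** — log-linear decay fits (`ln(C/C0) = -k t`,
  `t1/2 = ln2/k`) from actinomycin-D time courses, and 2^(-ddCt) qPCR
  quantification.
- **simulate** — NB count simulator with planted methylation states
  propagated down the hierarchy, WT/KO contrasts, and noisy decay curves;
  every stage has ground truth for testing.

Inputs are plain text: featureCounts-style TSV count tables, a CSV sample
sheet (`sample_id,population,assay,condition,replicate`), a tree as a
two-column edge list or newick, GMT gene sets, and decay CSVs. All result
tables are TSV with a `#` parameter header, and runs are byte-reproducible
given a seed.

## CLI

```sh
# end-to-end synthetic run from a YAML config
m6akit run --config config.yaml --seed 7 --out-dir results/

# individual stages
m6akit simulate --n-genes 1000 --seed 7 --out-dir sim/
m6akit quantify --counts sim/sim_counts.tsv --samples sim/sim_samples.csv
m6akit landscape --counts ... --samples ... --lfc-thresh 1 --p-thresh 0.05
m6akit inherit --counts ... --samples ... --tree sim/sim_tree.tsv --mode any-ancestor
m6akit cluster --counts ... --samples ... --k 2 --seed 7
m6akit de --counts ko_wt_counts.tsv --samples ko_wt_samples.csv
m6akit decay --input decay.csv
```

A config file lists the stages and their parameters, e.g.

```yaml
stages: [simulate, quantify, landscape, inherit, cluster, de, decay]
simulate: {n_genes: 1000, frac_methylated_root: 0.3, enrichment_lfc: 2.0}
landscape: {lfc_thresh: 1.0, p_thresh: 0.05}
inherit: {mode: any_ancestor}
cluster: {k: 2, genes: targets}
de: {sim: {n_genes: 1000, frac_de: 0.1, lfc_de: 1.0}}
decay: {sim: {t_half: 3.0, n_curves: 20}}
```

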