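# stclust

Benchmarking **highly variable (HV) versus spatially variable (SV) gene sets**
for cell-type clustering in spatial transcriptomics data.

Spatial transcriptomics assays (merFISH, cosMx, Xenium, Visium, ...) measure a
cells × genes count matrix together with the tissue coordinates of every cell
or spot.  Two families of feature selection compete for the downstream
clustering step:

* **HV genes** — genes whose variance across cells exceeds the level expected
  at their mean expression, selected without looking at the coordinates
  (the convention inherited from scRNA-seq);
* **SV genes** — genes whose expression is spatially autocorrelated over the
  tissue, detected by a spatial statistic (SPARK-style p-values, or the
  built-in Moran's-I permutation scorer).

The two sets are often quite distinct, and each one alone can miss cell types
the other resolves.  `stclust` implements the full evaluation study asking
whether the **union (concatenation) of HV and SV genes** improves cell-type
clustering over either set alone: preprocessing and normalization, gene
selection at three stringency levels, PCA → shared-nearest-neighbor → Leiden
(or kmeans) clustering, five evaluation metrics, and paired permutation tests
across datasets.  A synthetic tissue generator with known ground truth makes
the whole pipeline testable without any data downloads.

## The metrics

For ground-truth labels `u` and predicted labels `u*` (matched to the truth
vocabulary via expression-profile correlation and optimal assignment):

* **AMI** — adjusted mutual information, arithmetic-mean normalization.
* **Weighted F1** — per-truth-class F1 weighted by class frequency.
* **Pearson Gamma** — correlation between pairwise cell distances and the
  binary different-cluster indicator (an internal quality index).
* **Spatial Concordance (SC)** — per cell *i*, compute the Shannon entropy
  `e_i` of truth labels in its local spatial neighborhood (self + k nearest
  neighbors), normalize to weights `e*_i = e_i / Σ_j e_j`, and score

  `SC = Σ_i 1[u_i = u*_i] · e*_i`.

  A correct call in a heterogeneous neighborhood (a domain border) counts
  more than one deep inside a homogeneous region.
* **Mean Spatial AMI** — the same entropy weights applied to AMI values
  computed within each cell's neighborhood: `Σ_i e*_i · AMI(u|_{N_i}, u*|_{N_i})`.

## Worked example

Benchmark the four gene sets (hv, sv, union, all) on three synthetic tissues
(500 cells, 4 spatial domains, 4 localized + 3 dispersed cell types, 160
genes) with the default Leiden pipeline:

```python
import pandas as pd
from stclust import run_synthetic_benchmark, summarize_rankings, paired_permutation_test

records, failures = run_synthetic_benchmark(seeds=range(3), moran_n_perm=199)
table = summarize_rankings(records)
print(table[table.metric.isin(["ami", "spatial_concordance"])].to_string(index=False))

df = pd.DataFrame([vars(r) for r in records])
ami = df[df.metric == "ami"].pivot(index="dataset", columns="gene_set", values="value")
result = paired_permutation_test(ami["union"], ami["sv"], metric="ami", pair=("union", "sv"))
print(f"\nunion vs sv on AMI: mean difference = {result.mean_difference:.3f}, "
      f"p = {result.p_value:.4f} ({result.stars})")
```

Output:

```
             metric gene_set  mean_value  rank
                ami    union    0.549642     1
                ami       hv    0.525435     2
                ami      all    0.524435     3
                ami       sv    0.125173     4
spatial_concordance    union    0.569697     1
spatial_concordance       hv    0.567723     2
spatial_concordance      all    0.565205     3
spatial_concordance       sv    0.311184     4

union vs sv on AMI: mean difference = 0.424, p = 0.2500 (ns)
```

The union gene set ranks first on both metrics.  SV genes alone do poorly
here by construction: the synthetic tissues contain *dispersed* cell types
that carry no spatial signal, so only the HV markers can separate them, while
the *localized* types are resolved through the spatial expression patterns —
the regime in which the two selections are complementary.  Note the
permutation p-value: with only three paired datasets the exact sign-flip null
has eight outcomes, so p can never drop below 1/4; at the ten datasets used
by the acceptance run the same comparison reaches p ≈ 0.002.

Every stage is also exposed as a scikit-learn estimator
(`HighlyVariableGenes`, `SpatiallyVariableGenes`, `SNNLeiden`,
`CorrelationKMeans`, `PearsonResiduals`, ...) and as a CLI:

```bash
stclust simulate --config cfg.yaml --out tissue/
stclust preprocess --counts tissue/matrix.mtx --labels tissue/labels.csv --out proc.csv
stclust select --mode hv-resvar --level low --counts proc.csv --out hv.txt
stclust benchmark --config manifest.yaml --out records.csv
stclust report --records records.csv --out report/
```

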