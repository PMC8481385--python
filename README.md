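# clinenrich

Enrichment analysis of **sample sets** over clinical metadata. Given a
table of per-sample clinical attributes ("clinotypes": age group,
gender, treatment status, survival days, ...) and a selected subcohort
of samples — chosen by hand, by density clustering of a 2D embedding,
or by a radius neighborhood around one sample — `clinenrich` reports
which clinical attributes are statistically over-represented in the
subcohort relative to the full population.

The typical user has clustered or embedded biomedical samples from
omics data (a UMAP/t-SNE map of patients, a cluster of tumors, a
neighborhood around an unannotated sample) and wants to know *what the
samples in that region share clinically*. Apportioning a categorical
attribute across a map by eye does not scale; this package makes the
question a battery of exact tests.

## The statistics

Let **S** be the population of N samples, **C** the set of clinical
attributes, and **s** ⊆ **S** a subcohort of n samples.

* **Categorical attributes** (and discretized numerical ones) are tested
  per level with the one-sided hypergeometric over-representation test —
  the sample-set analogue of gene-set enrichment. With K population
  samples carrying the level and k of them in the cohort,

  p = P(X ≥ k), X ~ Hypergeom(N, K, n),

  where N and n shrink to the non-missing counts for that attribute.

* **Numerical attributes** are compared between the cohort and its
  complement S∖s with the two-sided Wilcoxon rank-sum test (exact null
  for small tie-free groups, normal approximation with tie/continuity
  correction otherwise).

* All m tests are **Bonferroni**-adjusted, p_adj = min(1, m·p), and a
  level is flagged enriched when p_adj < α (default 0.05).
  Benjamini–Hochberg is available as an option.

Around the tests sits the supporting machinery: one-hot digitization of
categorical attributes (X ∈ {low, normal, high} valued "high" becomes
the indicator block (0, 0, 1)), population-σ z-scoring of numerical
ones, Euclidean/cosine/Jaccard pairwise distances, UMAP or t-SNE 2D
embedding, discretization of numerical attributes at explicit or
cluster-derived cutpoints (e.g. survival <300 vs ≥300 days), and DBSCAN
clustering with a k-distance-elbow heuristic for ε.

## Worked example

The built-in synthetic generator emulates a glioblastoma-style cohort:
389 samples, 22 categorical + 7 numerical attributes, three embedding
blobs, 10% missingness, and two planted effects in blob 1 — survival
shifted +220 days and radiotherapy at 85% prevalence.

```python
from clinenrich import (demo_spec, generate, select_radius, cfea,
                        DiscretizationRule)

table, emb, truth = generate(demo_spec(seed=7))
cohort = select_radius(emb, "S0200", 3.0)          # disc around a blob-1 sample
res = cfea(table, cohort,
           rules=[DiscretizationRule("survival_days", (300.0,))])
print(res.summary(max_rows=6))
```

```
Clinical Feature Enrichment Analysis
====================================================================
cohort size: 102    population size: 389
tests performed (Bonferroni m): 77    alpha: 0.05
adjustment: bonferroni    selection: radius
enriched attributes (p_adjusted < alpha): 3
--------------------------------------------------------------------
             attribute        level           test  k  n   K   N    statistic      p_value   p_adjusted  enriched_flag
         survival_days                     ranksum 87 87 344 344 18334.000000 4.544205e-19 3.499038e-17           True
Discrete_survival_days        >=300 hypergeometric 84 87 226 344     1.469637 5.880091e-15 4.527670e-13           True
      treatment_status radiotherapy hypergeometric 84 97 215 355     1.429873 1.131639e-10 8.713617e-09           True
                 cat19         lvl2 hypergeometric 45 96 128 352     1.289062 8.931760e-03 6.877455e-01          False
Discrete_survival_days         <300 hypergeometric  3 87 118 344     0.100526 1.000000e+00 1.000000e+00          False
             age_years                     ranksum 91 91 342 342 10648.000000 3.393554e-01 1.000000e+00          False
... 71 more rows
```

The 102-sample radius cohort recovers exactly the planted truth: long
survival (both as a rank-sum on the raw days and as the discretized
"≥300 days" level, with 84 of 87 non-missing cohort samples above the
cutpoint versus 226 of 344 in the population) and radiotherapy status.
Every other attribute stays below the Bonferroni bar. The `statistic`
column is the fold enrichment (k/n)/(K/N) for hypergeometric rows and
the Mann–Whitney U for rank-sum rows.

The same analysis from the shell:

```sh
clinenrich synth --seed 7 --out-dir demo/
echo '{"survival_days": [300]}' > demo/cutpoints.json
clinenrich run --input demo/table.csv --embed file:demo/embedding.csv \
    --select radius:S0200,3.0 --cutpoints demo/cutpoints.json \
    --seed 7 --out-dir demo/out/
```

which writes `report.tsv`, `subcohort.txt`, `embedding.csv` and a
`runlog.json` with the config hash, parameters and library versions;
reruns with the same config and seed are byte-identical.

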