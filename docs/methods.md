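# Methods

## Procedure

The pipeline has five stages, each usable on its own:

1. **Ingest** (`clinotype_io`). A rectangular CSV/TSV table, one row per
   sample, one ID column. Attribute kinds are inferred by parseability
   (a column whose every non-missing cell parses as a finite real is
   numerical; anything else is categorical, with levels the sorted
   distinct labels), overridable per column. The tokens `""`, `NA`,
   `NaN`, `null` (case-insensitive) are missing. Recognition is the
   only missing-data handling anywhere: no imputation is performed, and
   the tests below drop missing values instead.
2. **Digitize** (`preprocess`). Each categorical attribute with L levels
   becomes L binary indicators `is_<attr>_<level>` in level order; a
   missing cell yields an all-zero block (so indicator blocks sum to the
   presence of the cell). Numerical attributes are z-scored with the
   **population** (n-denominator) standard deviation; a constant column
   maps to zeros; a missing cell maps to 0, i.e. mean imputation in
   standardized space — used *only* for the distance/embedding matrix,
   never by the tests.
3. **Embed** (`embedding`). Pairwise distances on the digitized matrix:
   Euclidean (default), cosine (1 − cosine similarity; an all-zero row —
   e.g. a fully missing sample — is at distance 1 from everything but
   itself), or Jaccard (1 − |A∩B|/|A∪B| on indicator columns only; two
   empty sets are at distance 0; z-scored columns present is an error).
   The matrix is embedded in 2D with UMAP (default) or t-SNE from a
   fixed seed; hyperparameters are the library defaults with
   neighborhood sizes capped for small n (`n_neighbors = min(15, n−1)`,
   `perplexity = min(30, (n−1)/3)`) and are recorded on the embedding
   and in the run log. Alternatively a user-supplied embedding file is
   ingested verbatim. From here on, all similarity is the plain 2D
   Euclidean distance between embedded points.
4. **Select** (`cohort_selection`). Manual ID list; DBSCAN on the 2D
   coordinates (one cluster becomes the cohort); or the closed disc of
   radius r around a chosen sample. The disc boundary is *included*
   (d ≤ r), and r is in embedding units. `eps="auto"` takes the elbow
   of the ascending k-distance curve (k = `min_samples`, default 5),
   located at the maximum discrete second difference.
5. **Test** (`enrichment`). Per categorical (raw and discretized)
   attribute level: the one-sided hypergeometric upper tail P(X ≥ k)
   with per-attribute non-missing denominators (N = non-missing
   population samples, K of them at the level; n = non-missing cohort
   samples, k at the level). Per numerical attribute: two-sided
   Wilcoxon rank-sum between cohort and complement, exact when both
   groups ≤ 25 and tie-free, otherwise normal approximation with tie
   and continuity corrections (the mode used is recorded). All p-values
   are Bonferroni-adjusted by the number m of tests actually performed,
   and `enriched_flag = (p_adj < α)`, α default 0.05.

## Model assumptions

The hypergeometric test conditions on the margins (n, K, N): its null is
that the cohort is an exchangeable draw from the population with respect
to the attribute. Because cohorts are usually selected *from the
embedding*, and the embedding was computed *from the attributes*, a
significant enrichment means "this region of the similarity map is
clinically coherent" — not a causal claim. When the embedding comes
from independent data (e.g. expression profiles), the tests are closer
to ordinary two-sample comparisons. The rank-sum uses the complement
S∖s as the second group because the test assumes independent samples; a
cohort equal to the whole population leaves an empty complement and the
attribute is reported as untestable rather than failing.

## Design choices

- **One-sided enrichment.** Depletion is not flagged by default,
  matching the gene-set-enrichment convention; a two-sided (Fisher)
  alternative is available via `alternative="two-sided"`.
- **Bonferroni by default.** Family-wise control is the method's named
  correction; Benjamini–Hochberg (`adjustment="bh"`) is provided for
  users who want FDR control, but off by default.
- **m counts performed tests.** Untestable rank-sum rows appear in the
  report with empty p-values and do not inflate the Bonferroni factor.
- **Discretization bins are upper-closed at the cutpoint**: bins are
  [−∞,c₁), [c₁,c₂), …, [c_last,∞), so survival exactly 300 falls in
  ">=300". Labels are generated as `<c`, `[a,b)`, `>=c` under the
  derived attribute name `Discrete_<attr>`.
- **Cluster-derived cutpoints** are midpoints between adjacent cluster
  means of the attribute (clusters ordered by mean; noise and missing
  dropped; equal adjacent means is a hard error). This is the simplest
  defensible rule for letting a clustering "suggest" a threshold.
- **Level order** is part of the attribute spec. Inference from files
  uses sorted labels (deterministic and row-order independent);
  constructing a table with an explicit `AttributeSpec` preserves any
  stated order, which is what makes the (0,0,1) one-hot example exact.
- **Per-attribute denominators** (rather than listwise deletion across
  attributes) maximize usable data; every report row prints the k, n,
  K, N it actually used.
- **Statistic column**: fold enrichment (k/n)/(K/N) for hypergeometric
  rows, Mann–Whitney U (cohort side) for rank-sum rows.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance threshold on adjusted p |
| `adjustment` | bonferroni | bonferroni or bh |
| `alternative` | greater | hypergeometric tail |
| `metric` | euclidean | pairwise measure before embedding |
| embed `method` | umap | umap or tsne, seeded |
| `min_samples` | 5 | DBSCAN density threshold |
| `eps` | auto | DBSCAN radius (k-distance elbow) |
| radius `r` | — | closed-disc radius, embedding units |

## Synthetic data

`synthetic_data.generate` draws seeded tables with known structure:
samples assigned to 2D Gaussian blobs, categorical values from baseline
level probabilities, numerical values from Gaussians, and *planted*
effects — a level drawn at elevated prevalence inside one blob (other
levels share the remainder proportionally to baseline), or a mean shift
added inside one blob. Missingness is completely at random (MCAR).
Embedding coordinates are generated directly rather than via UMAP so
selection and enrichment tests are deterministic and fast; the embed
path is exercised separately. `demo_spec` mirrors a mid-sized
glioblastoma clinical table: 389 samples, 22 categorical + 7 numerical
attributes, three blobs, survival days centered near 300 with a
+220-day shift and 85% radiotherapy prevalence planted in one blob, and
10% MCAR missingness (a rate a moderate cohort tolerates while every
attribute remains testable).

What the generator does **not** emulate: informative missingness,
correlated attributes, non-Gaussian numericals (real survival is
right-skewed and censored), or embeddings with manifold structure.
Passing tests therefore demonstrate correctness of the machinery and
calibration under exchangeable nulls — not robustness to the
pathologies of real clinical data.

## Numerical choices and verification

- Exact hypergeometric tails come from `scipy.stats.hypergeom.sf`; the
  test suite checks them against exhaustive subset enumeration for every
  valid (k, n, K, N) with N ≤ 12 to 1e-12, plus monotonicity in k and
  the binary-complement identity P(X≥k) + P(X'≥n−k) = 1 + P(X=k).
- Exact rank-sum p-values are checked against full permutation
  enumeration for all group-size pairs ≤ 7.
- Type-I error of the full pipeline is measured on 1000 seeded null
  tables (40 samples, 8 tests each) with random subcohorts: the raw
  p < 0.05 rate must not exceed 0.05 plus 3 Monte-Carlo standard
  errors (the hypergeometric's discreteness makes it conservative).
- Power: with cohort prevalence 0.9 vs baseline 0.5 (n = 50, N = 400,
  30 tests), the planted level must rank first and be flagged in ≥ 95%
  of 200 seeded reps; the margin is pre-validated against the exact
  hypergeometric tail under binomial sampling of the counts, which puts
  the oracle power above 99%.
- DBSCAN labelings are validated against a brute-force
  density-reachability oracle on 100-point instances, comparing core
  components exactly and border points up to their legitimate
  scan-order ambiguity.
- Report rows sort by ascending adjusted p, ties alphabetically by
  attribute then level; untestable rows sort last. Ties and ordering
  are stable (mergesort) so reruns are byte-identical.

The calibration and power checks above run at reduced problem sizes
(tables of 40–400 samples, 200–1000 replicates) chosen so the whole
suite completes in well under a minute while the Monte-Carlo margins
stay meaningful.

## Known limitations

- No survival modelling (no Kaplan–Meier or Cox), no covariate
  adjustment, no permutation-based FDR.
- Bonferroni controls the family-wise error rate, which is stricter
  than false-discovery-rate control; with many attribute levels it is
  conservative.
- Attribute-kind inference cannot distinguish numerically-coded
  categories (e.g. stage coded 1–4) from true numericals; use
  `type_overrides`. A written-then-reread table re-infers kinds, so a
  categorical attribute with purely numeric labels round-trips as
  numerical unless overridden.
- Testing every level of every attribute inflates m; users who care
  about a single hypothesis should subset the table first.
- UMAP/t-SNE reproducibility is per-machine and per-library-version;
  the run log records versions so a drifted rerun is detectable.
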