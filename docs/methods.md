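# Methods

## Model

A sample's DDR phenotype is summarized at the pathway level. Per-gene
expression is standardized across the cohort (z-scores), weighted by a
per-gene essentiality scaling factor (ESF), and averaged within each of
ten DDR pathways:

    raw_WE(P, s) = Σ_{g∈P} esf_g · z(g, s) / n_P

Raw WE scores are standardized per pathway across samples ("scaled WE"),
so pathways are comparable on a common scale. Samples are then points in
pathway-dimensional space; k-means (Euclidean, k-means++ init, best of 25
restarts) partitions them, the cluster count is chosen from the total
within-cluster sum-of-squares (WSS) curve, and clusters are ordered by the
grand mean of their members' scaled WE — DDR Low, Intermediate, High at
k = 3, DDR-1..DDR-k otherwise.

Assumptions: expression is comparable across samples after TPM
normalization; z-scoring removes per-gene abundance scale so that lowly
and highly expressed genes contribute equally; pathway membership is
disjoint (each gene counts in exactly one denominator); DDR phenotype is a
discrete cluster structure rather than a single continuous axis.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| log transform | log2(TPM+1) | — | compresses RNA-seq heavy tails before z-scoring; `log_transform=False` disables |
| SD convention | ddof=1 | — | sample SD, the convention of common statistical environments |
| WE denominator | genes matched in data | count | missing panel genes would otherwise deflate scores; `strict_denominator=True` divides by the full pathway size |
| k_max | 10 | clusters | upper bound of the WSS scan |
| restarts | 25 | runs | best-of-restarts k-means stability |
| elbow rule | chord distance | — | see below |
| n_sim | 2000 | tables | Monte-Carlo chi-square replicates |
| alpha | 0.05 | — | reported significance threshold |

## Numerical choices

* **Elbow selection.** Both axes of the WSS curve are min-max normalized;
  the pick is the k ∈ {2..k_max−1} maximizing vertical distance below the
  chord from (1, wss₁) to (k_max, wss_k_max). Ties break toward smaller k;
  a flat or exactly linear curve returns k = 2 with a warning. k = 1 is
  excluded (one cluster is not a clustering); the endpoint has zero chord
  distance by construction.
* **WSS monotonicity.** For each k the candidate set includes, besides the
  restarts, one Lloyd run initialized from the best (k−1) centroids plus
  the sample farthest from its centroid. Adding a centroid at a data point
  cannot raise the objective and Lloyd never increases it, so the curve is
  non-increasing by construction (asserted within 1e-8).
* **Degenerate rows.** Constant genes z-score to all-zero rows (flagged),
  the neutral element of the weighted sum; constant WE rows scale to zeros
  with a warning rather than erroring, since subsetted or synthetic data
  can contain constants.
* **Empty clusters.** k-means is re-run with a fresh seed up to 10 times;
  persistent failure raises.
* **Chi-square.** Pearson statistic without continuity correction;
  asymptotic p from χ²_(r−1)(c−1). The Monte-Carlo p conditions on both
  margins (Patefield sampling via `scipy.stats.random_table`) and uses the
  add-one estimator (1 + #{χ²_sim ≥ χ²_obs})/(n_sim + 1), which never
  returns 0 and is exact-conservative under exchangeability. Both p-values
  are always reported; residuals are emitted as a plain table.
* **Wilcoxon.** Exact rank-sum null when the pooled sample is ≤ 25 without
  ties, otherwise the normal approximation with average ranks and tie
  correction. Identical constant groups return p = 1; paired comparisons
  with all-zero differences warn and return p = 1. Raw p-values are
  reported (no multiplicity adjustment), matching common practice for
  small numbers of pre-planned cluster contrasts; a Benjamini–Hochberg
  column can be added downstream.
* **Determinism.** Every stochastic step takes an explicit seed; the
  pipeline manifest excludes wall-clock timings so identical configs yield
  byte-identical artifacts.

## The default panel

The packaged panel lists 130 DDR genes across NHEJ (12), TLS (10), NER
(20), MMEJ (3), HR (20), FA (14), Checkpoint (20), MMR (10), BER (18) and
DR (3). It is a synthetic stand-in assembled from standard DDR pathway
curation: the gene-to-pathway assignments are conventional, but **every
ESF is 1.0**, which reduces the WE score to the unweighted per-pathway
mean z-score. Loading it emits a loud warning. Curated essentiality
weights are study-specific data and should be supplied as a user panel
TSV; the entire weighting scheme is data, not code.

Signature scoring (`signature_score`) is a generic weighted mean
Σ w·z / Σ|w| over a user-supplied gene→weight map. It is a documented
stand-in for published replication-stress and neuroendocrine scores; the
original neuroendocrine score is correlation-based against reference
profiles and is *not* reimplemented here.

## The synthetic cohort generator

The generator emulates the data structure the analysis assumes, not real
RNA-seq sampling. Per cohort: cluster memberships are multinomial
(default 3 equiprobable clusters, n = 120); each panel gene's latent
log2-expression is a per-gene baseline ~ Normal(5, 2) plus the cluster's
pathway effect plus Normal(0, noise_sd = 1); 500 background genes carry no
effect; latent values map to TPM via 2^x − 1 floored at 0. Effects are
−δ on all pathways (Low), +δ on the first half of the pathways in panel
order (Intermediate — a hybrid signature), +δ on all (High), with
δ = 1.5. Subtypes are drawn per sample from cluster-conditional
frequencies encoding SCLC-N enrichment in High, SCLC-A in Intermediate,
SCLC-P/I in Low; a covariate rises one unit per cluster rank plus unit
noise.

What it does **not** emulate: count noise (no negative-binomial
library-size model), gene-gene correlation beyond the planted block
structure, batch effects, or outlier samples. Passing tests therefore
demonstrate correctness of the scoring/clustering/statistics machinery
under the planted model, not robustness to the full messiness of real
tumor RNA-seq.

A geometric note: because Intermediate shares its positive half-signature
with High, the dominant WSS drop is Low-versus-rest, and the chord elbow
occasionally (≈10% of default cohorts) prefers k = 2 over the planted
k = 3. This is a property of the planted hybrid geometry, not of the
selection rule.

## Problem sizes

Defaults are sized for seconds-scale runs: 120-sample cohorts, 630 genes,
k-means over k ≤ 10 with 25 restarts, 2000 Monte-Carlo tables per
chi-square. The validation suite uses 50 cohorts for cluster recovery and
1000–2000 replicate experiments for null calibration.

## Known limitations

* ESF weights in the shipped panel are uninformative (all 1.0); results
  with real weighting depend on user-supplied data.
* The elbow rule is one of several defensible selection criteria
  (`elbow="chord"` is the only implemented rule; gap statistic and
  silhouette are out of scope).
* One pathway per gene is enforced; biology is messier.
* Signature scores are weighted means, not the published correlation-based
  variants.
* No survival analysis, differential expression, or immune-infiltration
  scoring; these belong to established tools downstream of the cluster
  labels this package emits.
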