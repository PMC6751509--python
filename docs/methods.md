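# Methods

## Model

`precda` scores the relevance of every circRNA to a target disease by a
random walk with restart on a weighted heterogeneous network with two node
types (circRNAs, diseases) and two edge types:

* **circRNA–circRNA** edges fuse two similarity channels. The *expression*
  channel is the Spearman rank correlation of expression profiles across
  cell types/tissues, computed per source, combined across sources by
  maximum, and sparsified at a threshold τ: values below τ become 0. The
  *functional* channel embeds each circRNA in disease space — coordinate 1
  on each curated disease, otherwise the maximum similarity between that
  disease and any curated one, taken from an externally supplied
  disease–disease similarity matrix — and takes the cosine between
  embeddings. The edge weight is the mean of the two channels when
  expression evidence survives the filter, and the functional value alone
  otherwise.
* **circRNA–disease** edges carry weight 1 exactly for curated
  associations. There are no disease–disease edges; disease similarity
  enters the model only through the functional embedding.

The walk restarts at the target disease with probability 1 − d and
otherwise follows an incident edge with probability proportional to its
weight. The stationary solution of

    PR = (1 − d) r + d Pᵀ PR,    r = e_target

ranks all circRNAs not already curated for the target.

### Assumptions

* Similarity of expression rank profiles and proximity in disease space are
  both evidence of shared function; their average is a reasonable fusion
  when both are on a [0, 1] scale.
* The disease-similarity matrix is symmetric with unit diagonal and entries
  in [0, 1]; how it was produced (ontology-based, semantic, functional) is
  outside the model.
* Associations are binary and curated; no confidence weighting.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ (`tau`) | 0.7 | expression-similarity filter; correlations below τ are discarded. Negative correlations can never pass τ ∈ (0, 1], so no sign rule is needed. |
| d | 0.85 | transfer probability of the walk; higher values weight network structure over the restart. |
| `tol` | 1e-10 | L∞ convergence tolerance of the fixed-point iteration. |
| `max_iter` | 1000 | iteration cap; non-convergence is flagged on the result, not raised. |

Numerical and procedural choices where the definitions leave room:

* **Ties in expression values** (common: repeated zeros) get average ranks,
  so the correlation is the Pearson correlation of the rank vectors. This
  coincides with the classical 1 − 6Σd²/(n(n²−1)) form exactly when no ties
  exist (property-tested at 1e-12).
* **Missing expression values** are handled pairwise-complete with a
  minimum of three shared conditions; pairs below the minimum, or involving
  a constant profile, have *undefined* similarity, which the combined stage
  treats the same as filtered-out (0).
* **Pairs measured in one source only** keep that source's thresholded
  value by default — discarding measured evidence is strictly less
  informative — with a `--both-sources-only` flag for the strict
  both-sources reading.
* **Weighted transition probabilities**: the walk normalises by the sum of
  incident edge weights, which reduces to the uniform 1/out-degree rule on
  unweighted graphs; `--unweighted-walk` restores the literal unweighted
  reading. Rows of isolated nodes are all-zero (the restart replenishes
  the lost mass).
* **Initialisation** PR⁰ = r; deterministic tie-break on equal scores by
  lexicographic circRNA ID; final scores are not renormalised (rankings are
  within a single target).
* **Validation AUC**: one AUC per disease over all of its held-out
  positives jointly, via the rank-sum (Mann–Whitney) estimator with ties
  counted half; the summary is the unweighted (macro) mean over diseases.
  For multi-experiment summaries both the macro-of-macros and the pooled
  per-disease mean are reported, since the two readings can differ.
* **Degenerate inputs**: a circRNA with no curated disease cannot be
  embedded (the max over an empty disease set is undefined) and is an
  error rather than silently scored; zero score vectors are likewise
  rejected defensively although they cannot arise from genuine inputs.

## Synthetic benchmark

The generator plants modules: groups of circRNAs that are co-expressed and
attached to the same cluster of diseases. Expression uses a latent-factor
Gaussian model — member profiles are √ρ·f_module + √(1−ρ)·ε, so any two
same-module profiles have expected correlation ρ; since Spearman similarity
depends only on rank structure this is the simplest model with a tunable
rank correlation. Two pseudo-sources observe overlapping circRNA subsets
(60 % shared by default) with independent measurement noise, exercising the
max-combination and the single-source branch of the filter. Disease
similarity is written directly as a block matrix (within-module value vs
between-module value) because the pipeline consumes only the matrix.
Associations are drawn within modules at `assoc_density`; a
`holdout_fraction` of the module-consistent pairs is moved to the reference
database only, producing valid cross-database test cases with known ground
truth (the holdout never removes a circRNA's or a disease's last network
association). Default conditions: 5 modules × 10 circRNAs and 3 diseases,
20 conditions per source, ρ = 0.9, noise SD 0.3, disease similarity
0.9/0.1, density 0.8, holdout 0.2.

Two named variants define the benchmark's control conditions:

* **Null** (`null_config`): ρ = 0, a flat disease-similarity matrix and
  associations drawn uniformly across modules. The pipeline's held-out
  macro-AUC sits at chance (≈ 0.5), confirming that the recovery measured
  under the default conditions is signal, not artifact.
* **Expression-informative** (`expression_informative_config`): 30 % of
  curated associations are rewired to another module's diseases
  (`assoc_noise`, emulating curation noise and pleiotropy), with modest
  disease-similarity contrast (0.3 within, 0.05 between) and density 0.5.
  This is the regime in which the expression channel carries information
  the curated associations lack. Under the fully module-consistent default
  the two channels are informationally redundant — the functional channel
  alone separates modules nearly perfectly, and because the fusion rule
  *averages* the channels, expression evidence can even slightly lower
  within-module weights whenever FnSim > ExSim — so the full-vs-ablation
  comparison is only meaningful here. With curation noise the full
  pipeline beats the cosine-only ablation by ≈ 6–9 AUC points on average
  (computed by `scripts/acceptance.py` and the test suite at run time).

What the generator does **not** emulate: read-count noise and library-size
effects (profiles are Gaussian, not counts), ontology DAG structure behind
the disease-similarity matrix, circRNA biogenesis, inter-database
identifier conflicts, and the heavy-tailed degree distributions of real
curated databases. Passing the synthetic benchmarks therefore shows the
pipeline recovers planted co-expression/co-disease structure through the
whole stack — not that any particular real-data AUC will be attained, which
depends on database snapshots and the external disease-similarity method.

## Problem sizes

The shipped benchmarks use 50 circRNAs, 15 diseases and 20 conditions per
source, with 10 bundles for the recovery and null measurements and 20
paired bundles for the ablation comparison — small enough that the whole
suite and the acceptance script each complete in seconds, while every stage
(two-source combination, thresholding, embedding, walk, cross-database
extraction) is exercised end to end.

## Known limitations

* The fusion rule's averaging penalises expression-supported pairs whenever
  the functional value exceeds the expression value; see the
  expression-informative discussion above.
* Cosine similarity of nonnegative score vectors is inflated when the
  disease-similarity baseline is high (all embeddings share a large common
  component), compressing the functional channel's contrast.
* Disease-name harmonisation is exact case-insensitive matching against
  names and synonyms; no fuzzy matching, and conflicting synonym claims
  across terms are surfaced as errors rather than resolved by precedence.
* The per-target walk is solved independently per disease (dense iteration);
  fine at curated-database scale (hundreds of nodes), not tuned for
  genome-scale networks.
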