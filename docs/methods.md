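# Methods

`shapcell` ranks cell types in a labeled single-cell expression matrix by how
much exact Shapley-attribution mass their cells carry, and extracts per-type
key genes. This note documents the models, the choices behind them, and what
the bundled synthetic data can and cannot show.

## Pipeline overview

1. **Input.** A cells × genes matrix with one type label per cell, either
   loaded from MTX + TSV or produced by the bundled generator. Classifiers
   consume the log1p counts-per-million view by default; raw counts are
   retained (both views are exposed because real pipelines differ here).
2. **Balance ladder.** For K types, K + 1 resampling schemes: RAW plus one
   scheme per type that equalizes every class to that type's count —
   under-sampling without replacement above the target, SMOTE interpolation
   below it. One forest is tuned per scheme; the working model is the
   balanced scheme with the best cross-validation score (BVS). RAW is
   evaluated and reported but excluded from selection: the balanced models
   are the ones whose rare-type recall the ladder exists to improve, and on
   imbalanced data a RAW model can post a high plain accuracy while never
   predicting the rarest class at all.
3. **Attribution.** Exact interventional Shapley values of every gene for
   every test cell and class, against a seeded stratified background of
   training cells.
4. **Gene selection.** Per-type top-N gene lists from correctly classified
   test cells; partition into co-expressed (all lists), specific (exactly
   one list), their union, and the distinct union.
5. **Attribution matrix.** For correctly classified test cells, the selected
   genes' attributions to the cell's own class, audited against the
   additivity identity. Cell-type importance is the per-cell mean of summed
   positive entries; per-type key genes are ranked by mean positive entry;
   a classifier retrained on the matrix itself quantifies how much label
   information the selected attributions retain.
6. **Screens and atlases.** Pearson gene–gene correlation with a
   high-correlation threshold, point-biserial gene–type correlation, and
   seeded 2-D UMAP embeddings of either expression or the attribution
   matrix.

## Classifier and hyperparameter search

The classifier is a random forest tuned by randomized search: n_estimators
100–500, max_features ∈ {all, sqrt, log2}, max_depth 10–50,
min_samples_split 2–10, min_samples_leaf 1–4, bootstrap ∈ {true, false};
20 sampled settings, 5-fold stratified cross-validation, split ratio 0.7,
seed 42. These are the package defaults (`SearchSpec()`,
`PipelineConfig()`). Cross-validation is stratified so rare classes appear
in every fold; a class smaller than the fold count is rejected with advice
to balance first. Plain (unweighted) accuracy is the search metric.
Undefined precision/recall (empty prediction or support) is reported as 0
with a warning, never NaN.

On the bundled fixtures the tests and the acceptance script use a
scaled-down search — 60–150 trees, sqrt/log2 feature rules, depth 8–20,
3–5 sampled settings — because the synthetic classes are cleanly separable
and scores saturate long before the full budget; the full search adds cost,
not information, at these problem sizes.

## Interventional tree Shapley values

For forest f, background set Z and cell x, the attribution of gene j to
class c is the Shapley value of j in the game

    v(S) = E_{z∈Z}[ f_c(x_S, z_{S̄}) ],

genes outside the coalition being imputed from a background cell. The game
is linear over trees and background cells, so it decomposes into one tiny
AND-game per (tree, background cell, leaf): along the path to a leaf each
gene must come from x (a-set), must come from z (b-set), is free, or makes
the leaf unreachable. The Shapley value of that game is closed-form in the
set sizes (±(a−1)!·b!/(a+b)! times the leaf value), summed by a
divergence-path traversal (numba-compiled) that visits only the leaves
reachable by some x/z hybrid. No sampling is involved anywhere, which is
why the implementation can be checked to 1e-8 against brute-force coalition
enumeration (≤ 12 genes), and why local accuracy
(base + Σ phi = predicted probability), the dummy axiom (unused gene ⇒
exactly 0) and symmetry hold to float rounding rather than approximately.

The interventional (background-conditioned) formulation was chosen over
path-dependent conditioning precisely because it admits that exhaustive
oracle. The background is up to 128 training cells (64 in the bundled
runs), sampled per type proportionally with at least one cell per type,
seeded. Attribution is computed on the test split only. Per-class values
are kept separate; the global gene ranking aggregates classes by the sum of
per-class mean |phi|.

## Balancing details

SMOTE interpolation draws a class member x uniformly, one of its k = 5
nearest same-class neighbours x_nn (k capped at n−1), and returns
x + u·(x_nn − x), u ~ U(0,1); a singleton class falls back to duplication.
Balancing happens after the train/test split and touches only the training
half, so synthetic cells cannot leak into evaluation; the opposite order
(balance, then split) is available as `run_ladder_balance_first` /
`balance_order: balance_first` for comparison and is documented as
optimistic.

## Gene-set partition

"Co-expressed" = present in every per-type list; "specific" = present in
exactly one; the working union is their disjoint union; genes in 2..K−1
lists belong only to the distinct union. This is the only reading under
which co + specific < distinct with both parts non-empty, matching the
upset-style membership table the partition emits. Per-type gene scores use
the mean (not sum) attribution so rare types are scored on the same footing
as abundant ones; ties break by gene id everywhere a ranking is produced.

The default list length N = 500 is meant for transcriptome-scale inputs.
On the 200-gene bundled fixture the scaled runs use N = 100: long enough to
hold every planted informative gene (~70), short enough that the partition
is non-degenerate. At this scale the union set has a known artifact: a rare
type's markers also appear in a handful of other types' lists (as
absence-of-marker signals), putting them in the 2..K−1 membership band that
the union excludes. Recovery checks therefore run on the distinct union;
the retraining fidelity check keeps the union set.

## Importance ranking and key genes

score(c) = (1/n_c) Σ_{cells of c} Σ_g max(phi, 0). The per-cell mean makes
the score invariant to duplicating a type's rows (tested to 1e-12), which
is what lets a rare type with a strong signature outrank a type a hundred
times more numerous — the outcome shape the method is designed to expose.
Types with fewer than `min_cells` = 5 correctly classified test cells are
excluded as low-quality: with a handful of rows neither the mean score nor
a key-gene list is meaningful. Both the filter and the normalization are
config-exposed.

## Synthetic data

The generator plants K types with exact per-type cell counts, disjoint
marker sets, negative-binomial counts (Gamma–Poisson, dispersion r, default
2) and independent Bernoulli dropout (default 0.3). Markers have mean
`nb_mean` outside their own type and `nb_mean × fold` (default 8) inside
it — exactly, so null and monotonicity checks have closed expectations.
Background genes draw per-gene baseline means from Gamma(shape 0.3, mean
`nb_mean`): real expression mass is heavily concentrated (the top decile of
genes carries roughly half of a type's total expression), and a flat
background cannot reproduce that; shape 0.3 puts the top-decile share
around 0.5.

The default atlas-shaped fixture has 6 types with counts
[4000, 1500, 800, 400, 120, 44] — one dominant progenitor-like population
and a rare neutrophil-like class — scaled proportionally for tests
(`scale=0.25` → 1,716 cells for the acceptance run; `scale=0.12` → 826
cells for the fast checks; minimum 8 cells per type). The dominant type
(default: the third most abundant) carries the same marker quota at twice
the fold change, so importance-by-signal and importance-by-abundance
disagree on purpose. A doubled marker *count* was considered and rejected:
it makes per-type recovery metrics structurally incomparable (a 2m-marker
type must fit ≥ 80% of them into the same fixed-length key-gene list that
m-marker types face), while a doubled fold change distinguishes the type
without changing the metric's arithmetic; the multipliers remain
config-exposed.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, trajectories, mean-dependent dropout, gene–gene correlation beyond
type structure, or UMI-level noise. Passing tests therefore show that the
machinery is correct and recovers planted structure under realistic
imbalance, skew and dropout — not that any biological conclusion about real
tissue follows.

## Numerical and degenerate-input conventions

- Additivity audits at 1e-6 (observed gaps are ~1e-15).
- Oracle equivalence at 1e-8; set-algebra and resampling checks exact.
- Decile bins: contiguous, remainder genes assigned to the earliest bins;
  the size-weighted bin means reconstruct the overall mean to 1e-9. The
  pipeline computes the summary on raw counts — expression-mass shares are
  a statement about counts, and a log transform flattens them.
- Correlation: signed r > threshold (default 0.8), strictly; constant genes
  are excluded (gene–gene) or reported missing (gene–type) with a warning.
- UMAP: 15 neighbours (capped at n−1), min_dist 0.1, fixed seed; random
  init below 10 cells where spectral init is undefined.
- Ties: by gene id in every gene ranking; by type name in the importance
  ranking; scheme selection breaks BVS ties toward the smaller resampled
  training set.

## Known limitations

- Attribution cost grows with background size × trees × leaves; transcriptome-
  scale forests call for reducing the background (the exactness per
  background cell is unaffected) or batching cells.
- The union-set artifact above: on few-gene inputs, mid-membership genes
  (2..K−1 lists) are excluded from the working union by construction.
- SMOTE interpolates in the normalized expression space; synthetic cells
  are convex combinations and ignore count discreteness.
- The retrained-on-attributions classifier shares the test cells with the
  attribution step by design (it quantifies information retention, not
  generalization to new cells).
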