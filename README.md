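# shapcell

Cell-type importance ranking and key-gene extraction from labeled
single-cell expression matrices, via **exact interventional Shapley
attribution** of a tree-ensemble cell-type classifier.

## The problem

Annotated single-cell atlases tell you *which* types are present and how
abundant they are, but not which types carry the most distinctive
transcriptional signal, nor which genes make each type recognizable.
Abundance is a poor proxy: a rare population (tens of cells among tens of
thousands) can be the most sharply defined type in the tissue. `shapcell`
answers both questions with a model-interpretation pipeline:

1. train a random-forest cell-type classifier, choosing among **K + 1
   class-balancing schemes** (RAW plus one scheme per type that equalizes
   all classes to that type's count by under-sampling and SMOTE
   interpolation), selected by cross-validation score (BVS);
2. compute, for every test cell, gene and class, the **exact Shapley value**

       phi_ijc :  v(S) = E_z [ f_c(x_S, z_S̄) ]

   of gene j for the predicted probability of class c, with out-of-coalition
   genes imputed from a background set (interventional conditioning). The
   implementation is exact — `base + Σ_j phi = f_c(x)` holds to float
   rounding — and ships a brute-force coalition-enumeration oracle it is
   tested against to 1e-8;
3. partition per-type top-N gene lists into co-expressed / specifically
   expressed sets, and **reconstruct the attribution matrix** of the
   selected genes for all correctly classified test cells (a slice of the
   full tensor, justified by additivity and audited row by row);
4. rank cell types by the per-cell mean of their summed positive
   attributions, extract per-type **key genes**, retrain a classifier on
   the attribution matrix itself to measure how much label information the
   selection retains, and draw correlation screens and UMAP atlases.

A bundled synthetic-data generator (negative-binomial counts, skewed
baseline expression, dropout, exact per-type counts, disjoint planted
markers, one rare and one signal-dominant type) provides ground truth for
every stage, so the whole pipeline is testable without downloads.

## Worked example

`python examples/06_importance_ranking.py` (826 cells, 6 imbalanced types
with counts 480/180/96/48/14/8, 200 genes, 10 planted markers per type;
the third most abundant type is "dominant": same markers, twice the fold
change):

```
cell-type importance (per-cell mean positive attribution):
type2    0.7692
type1    0.6706
type3    0.6505
type0    0.4656
planted dominant type: type2
excluded type4: only 2 correctly classified cells (min_cells=5)

top key genes of type2 (planted markers flagged):
 gene    score  planted
g0029 0.072594     True
g0022 0.070539     True
g0024 0.065278     True
g0020 0.050360     True
g0028 0.047732     True
g0026 0.043995     True
g0021 0.043581     True
g0027 0.041189     True
g0004 0.039678    False
g0023 0.029494     True

retrain on the attribution matrix, held-out accuracy: 1.000
```

The dominant type ranks first although it is only the third most abundant;
9 of its top-10 key genes are its planted markers; the 14-cell rare type is
excluded by the low-quality filter rather than silently mis-scored; and a
classifier retrained on the attribution matrix alone reclassifies held-out
cells perfectly — the selected attributions retain essentially all label
information.

The other `examples/` scripts cover one capability each: simulation,
decile expression summaries, the balance ladder, raw attribution with the
additivity audit, gene-set partition and subset retraining, and the
correlation/UMAP screens. A thin CLI wraps the two shell-level entry
points: `shapcell simulate --out DIR` and `shapcell run --config cfg.yaml
--out DIR` (full pipeline with a checksummed manifest).

## License

MIT
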