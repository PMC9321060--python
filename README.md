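# lymphoscape

SOM expression portraits, spot-module extraction, gene-set Z-score (GSZ)
signature scoring and classifier benchmarking for germinal-center-derived
lymphoma transcriptomes.

## The problem

Germinal-center-derived B-cell lymphomas — Burkitt lymphoma (BL), diffuse
large B-cell lymphoma (DLBCL) with its GCB/ABC cell-of-origin split,
follicular lymphoma (FL), MYC/BCL2 double-hit lymphoma (DHL) and rarer
entities — form a *continuum* of transcriptional states rather than
clear-cut classes. Competing classifier gene signatures published for the
same task (BL-vs-DLBCL, ABC-vs-GCB, DHL-vs-non-DHL) overlap only weakly in
their genes yet perform almost identically, because they all sample from the
same handful of co-expression modules. This package implements the
whole-transcriptome machinery to make that structure visible and testable:

1. **Metagene portraits** — a batch self-organizing map distributes genes
   over a planar pixel grid so co-expressed genes cluster in adjacent
   pixels ("metagenes"); evaluating all metagenes for one sample yields its
   portrait.
2. **Spot modules** — connected regions of over-expressed, coherently
   co-expressed metagenes in the summary map (pixel-wise maximum over
   group-mean portraits); their gene sets are candidate classifiers.
3. **GSZ scoring** — one standardized activity value per sample and gene
   set: with `m_set` the mean centered expression over the `n` matched set
   genes and `m_all`, `sd_all` the mean/sd over all `N` genes of a sample,

       GSZ = (m_set − m_all) / sqrt( (sd_all² / n) · (N − n) / (N − 1) )

   i.e. the z-score of the set mean against random sets of equal size.
4. **Benchmarking** — ROC/AUC (tie-corrected Mann–Whitney) of GSZ scores
   for two-group contrasts, GSZ > 0 detection matrices, gene-overlap
   matrices, random-subset resampling stability, GSZ correlation
   clustering, and pattern-type (PAT) stratification by activated spot
   combinations; optionally a small neural network classifying whole
   portraits.

Because the reference cohort is not publicly deposited, the package ships a
first-class **synthetic cohort generator**: thirteen subtype strata in the
published proportions, ten planted co-expression modules A–K with
subtype-specific activation (sign and strength), per-sample activation
jitter producing fuzzy subtype borders, and Gaussian array noise — all on
log2 scale and fully seeded. Every downstream stage is tested against this
generator's ground truth.

## Worked example

```python
from lymphoscape import run_synthetic_landscape
from lymphoscape.pipeline import recovery_jaccard, spot_auc
from lymphoscape.simulate import DLBCL_LIKE

result = run_synthetic_landscape(seed=1)   # 20,000 genes x 300 samples, 20x20 SOM
print(result.spots.table().head(3))
#         n_pixels  n_genes   peak  seed_pixel
# letter
# A             10      596  0.860          16
# B             10      458  0.846         380
# C             14     1158  0.842          17

print(recovery_jaccard(result))
# module A -> 0.97, B -> 0.67, D -> 1.00, F -> 1.00, ... (8/10 >= 0.5)

print(spot_auc(result, "B", "BL", DLBCL_LIKE))
# 1.0
```

The spot table lists the recovered over-expression modules ranked by their
summary-map peak; `recovery_jaccard` compares each planted module's gene set
with its best-matching recovered spot (a Jaccard of 1.0 means exact
recovery); `spot_auc` scores the spot's gene set by GSZ and reports the AUC
of the BL-vs-DLBCL contrast — here the recovered spot-B classifier separates
the groups perfectly, on par with the emulated literature signatures of 6 to
47 genes (see `examples/04_benchmark_classifiers.py`, which also shows that
random 20% subsets of the spot keep a median AUC of 1.0 over 100 draws).

The `examples/` directory holds one short narrative script per capability:
cohort simulation, landscape training, signature scoring and enrichment,
classifier benchmarking, PAT stratification, and the portrait network.

A thin CLI wraps the same library calls
(`lymphoscape simulate|train|portraits|spots|score|evaluate|pat|nn`); every
subcommand writes a run manifest and is byte-reproducible at a fixed seed.

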