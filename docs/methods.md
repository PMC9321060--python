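# Methods

This note documents the models, default parameters and numerical choices of
the package, what the synthetic cohort does and does not emulate, and the
known limitations.

## Synthetic cohort model

Expression is additive Gaussian on log2 scale:

    x[g, s] = mu_g + a~[s, m(g)] * e_m(g) + eps[g, s]

* `mu_g ~ N(8, 1)` — gene baseline, typical of log2 microarray intensities.
* `m(g)` — the gene's planted module (A–K) or background; module gene sets
  are pairwise disjoint. Module sizes (600, 400, 200, 1154, 129, 700, 350,
  300, 450, 250 for A–K) span the published spot-module size range, with D
  the largest (1154) and E the smallest (129). The background holds 15,467
  genes, giving a 20,000-gene universe — the scale of a whole-transcriptome
  microarray — of which ~23% carry module structure.
* `a[subtype, module] ∈ [−1, 1]` — the activation matrix; sign is
  direction, magnitude is strength. Signs encode the landscape biology: BL
  up in A/B/C/D and down in the inflammation module F; DLBCL up in F and in
  the stroma module G (which FL shares); ABC additionally in the
  plasma-cell module H; GCB moderately in A and the B-cell module K; DHL
  with marked singular over-expression of A (stronger than the 0.5 carried
  by GCB and FL), moderate D and down F; FL up in I/G/A/K; mnBLL-11q
  BL-resembling with elevated E; IRF4-LCL dominated by E with proliferative
  and plasma-cell traits; MM plasma-cell only; the "intermediate" stratum is
  the 50/50 mixture of the BL and generic-DLBCL rows. Where the magnitudes
  were open, they were fixed once from the qualitative descriptions (e.g.
  "to a lesser degree" -> 0.5) and not revisited.
* `a~[s, ·] = a[subtype(s), ·] + N(0, σ_act²)` with `σ_act = 0.15` — the
  per-sample activation jitter that realizes the subtype *continuum*
  (fuzzy borders); there is no parametric germinal-center clock.
* `e_m = 1.0` log2 units; `eps ~ N(0, σ_ε²)` with `σ_ε = 0.5` — effect and
  noise scales chosen so that classification is strong but module recovery
  is not trivially saturated at n = 300 samples.

Strata counts scale the published cohort proportions (DLBCL split into
GCB 142 / ABC 133 / unclassified 97 / DHL 58, plus BL 74, FL 145,
intermediate 81, FL/DLBCL 48, PMBL 23, MM 20, IRF4-LCL 10, mnBLL-11q 6,
MCL 4) to any total by largest-remainder rounding, keeping every stratum
represented. The default analysis cohort holds 300 samples.

**What the generator does not emulate.** Within-stratum substructure (e.g.
the proliferative subset of DLBCL that shares module D with BL), graded
module membership (planted modules are flat blocks, real spots have cores
and shoulders), genetics, survival, and single-cell counts. Consequences:
spot D behaves like spot B in DLBCL false-detection (no planted
proliferative DLBCL), and passing tests show pipeline correctness on block
co-expression structure, not performance on real arrays.

Emulated literature classifiers sample their published cardinalities
(BL_up 47/16/6, DLBCL_up 18/11/4, ABC_up 9/7/13, GCB_up 11/6/7, DHL_up 31,
non-DHL_up 47) from their source modules (B, F, H, A, A/F respectively)
plus a 10% background-decoy fraction, seeded and without replacement.

## SOM portrayal

Batch SOM, fully deterministic given the input: per epoch every gene is
assigned to its Euclidean best-matching prototype (ties to the lowest pixel
index), then each prototype is recomputed as the Gaussian-neighborhood-
weighted mean of assigned gene profiles. The neighborhood radius decays
linearly from `max(rows, cols)/2` to 1 over the epochs; the grid is planar
(portraits are bordered images) and initialized on the plane of the first
two principal components of the gene cloud (eigen-decomposition of the
sample-space covariance, deterministic sign convention), which removes seed
sensitivity. Defaults: 50×50 grid for real-data-scale landscapes; the
default synthetic analysis uses 20×20 with 20 epochs — at 20,000 genes this
keeps a full five-seed benchmark under a minute while leaving ~45 genes per
pixel. Input must be per-gene centered (`preprocess`: optional quantile
normalization, then mandatory centering); training rejects non-centered
input and reports NaNs with their epoch. The quantization-error history is
stored; it is non-increasing across batch updates (the first entry measures
the PCA initialization).

## Spot segmentation

Spots are segmented on the summary map (pixel-wise maximum over group-mean
portraits): pixels strictly above the `threshold_quantile` of map values
are kept, partitioned into *profile-coherence clusters* (average-linkage
hierarchical clustering of the pixels' prototype profiles on Pearson
correlation distance, cut at correlation 0.85), and 8-connected components
are formed within clusters; components under `min_size = 3` pixels are
dropped and survivors lettered by decreasing peak. The coherence step is
essential on planted (and plausibly real) data: modules co-activated in the
same subtype sit side by side at equal summary height, so a pure
height-threshold segmentation fuses them even though their expression
profiles across samples differ sharply. The 0.85 cut sits between the
maximal between-module activation correlation of the default design
(≈ 0.73, the near-collinear B/C pair) and the within-plateau coherence
(≥ 0.9); it was fixed from that geometry, not fitted.

The threshold quantile is 0.98 by default — appropriate when
over-expression spots occupy a few percent of a 50×50 landscape. For the
synthetic cohort the planted modules occupy roughly their gene share of the
map (~23%), so the pipeline derives the quantile from the planted geometry
(`synthetic_spot_quantile`: one minus the module gene share minus a 10%
margin, ≈ 0.75 for the default cohort). Raising the quantile never enlarges
the segmented area. Only over-expression (red) spots are extracted.

On the default cohort this recovers 8–9 of 10 planted modules at gene-set
Jaccard ≥ 0.5 (seeds 1–5); the exceptions are informative: B/C merge
partially because their planted activation vectors are nearly collinear
(C's private signal rests on ~3 samples), and E (129 genes ≈ 2–3 pixels)
sits at the resolution limit of a 20×20 grid. In the noise-free limit with
pairwise-distinguishable activation patterns, recovery is exact.

## GSZ

The gene-set Z-score standardizes the set mean against equally sized random
sets within each sample:

    GSZ_s = (m_set − m_all) / sqrt( (sd_all²/n) · (N − n)/(N − 1) )

with `sd_all` the sample standard deviation (ddof = 1) over all N genes of
sample s. Degenerate cases score 0: a constant sample column and a set
spanning the whole universe. For realistic N the score is calibrated — a
uniformly random set has mean ≈ 0 and variance ≈ 1 (the exact finite-sample
variance is (N−1)/N). Scores are invariant under positive rescaling of a
sample and, through the mandatory centering, under additive shifts. The
score is unweighted; signatures are scored unidirectionally (up-sets), and
a combined up-minus-down convenience score is deliberately not part of the
benchmark path. Signature-to-spot enrichment is the one-sided Fisher exact
(hypergeometric upper tail) with the SOM-assigned genes as universe;
multiple-testing correction is off by default with an optional Bonferroni
table alongside.

## Classifier benchmarking

AUC uses the tie-corrected Mann–Whitney rank formula (verified against
exhaustive pair counting); ROC curves come from a threshold sweep over the
unique scores. Two-group contrasts exclude out-of-contrast strata;
"DLBCL-like" means the GCB/ABC/unclassified strata (DHL is its own
stratum). Detection uses the GSZ > 0 rule. Resampling stability draws
seeded random subsets without replacement and reports the per-fraction
median and IQR of AUCs. GSZ-profile correlation clustering uses average
linkage on correlation distance cut at two clusters.

PAT assignment: a spot is activated in a sample when its mean portrait
value is strictly positive *and* strictly above the sample's
`activation_quantile` (default 0.90) portrait quantile — a sign-plus-
prominence rule that keeps PATs sparse, scale-free, and monotone (raising
the quantile only removes letters). The empty combination renders as "∅".

## Portrait network

An optional fully connected classifier on flattened portraits: per-pixel
standardization with training statistics, one hidden layer of 64 ReLU
units, Adam mini-batches, stratified 80/20 train/validation split and early
stopping — a deliberately small, CPU-scale architecture. It is deterministic
given a seed; note that seeded dense initialization is not
permutation-covariant, so consistent pixel permutations change the fitted
function (equivariance holds only in distribution). The network never feeds
other stages.

## Numerical and interface choices

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; batch SOM and PCA initialization are
  deterministic, so CLI stages are byte-reproducible.
* Expression I/O: TSV with a header and GCT 1.2; floats are written at full
  precision and parsed correctly rounded, so write→read round-trips
  bit-exactly. Missing values are rejected by default (array summaries are
  complete); an impute-by-gene-mean flag exists but is off. Gene IDs are
  opaque strings — no symbol/Ensembl mapping.
* GMT direction convention: `_up` / `_down` name suffix, with a description
  token fallback; duplicate genes within a line are collapsed with a
  warning.
* Spot letters are ranks (peak order), not identities: matching recovered
  spots to planted modules (or across runs) goes through gene-set Jaccard.
* The 1×1-grid SOM is supported as a degenerate oracle (its prototype is
  the mean gene profile); the pipeline configuration enforces ≥ 4 pixels
  for real runs.

## Known limitations

* Spot-letter correspondence to any published landscape holds only by
  construction of the synthetic activation matrix.
* The coherence-based segmentation assumes spots are internally coherent
  co-expression plateaus; heavily graded real spots may oversplit at the
  default cut.
* The GSZ > 0 false-detection rate of BL classifiers on the synthetic
  cohort (~23% of non-BL samples at default jitter) is dominated by the
  intermediate stratum, which by construction carries half the BL
  activation and is genuinely detected — the planted Gaussian continuum is
  less bimodal than real cohorts, where published false-positive rates are
  far lower.
* No survival analysis, similarity trees, chromosome-position tracks, raw
  array calibration, or interactive browsing.
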