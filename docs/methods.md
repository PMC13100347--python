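# Methods

`tmegraph` implements a hierarchical, tissue-specific pipeline for
predicting pathologic complete response (pCR) to neoadjuvant
chemotherapy in HER2-positive breast cancer from tile-level maps of H&E
whole-slide images. This note records the models, the parameter choices
and their rationale, the numerical conventions, and what the synthetic
cohorts do and do not establish.

## Pipeline overview

1. **Preprocessing.** A slide raster is partitioned into nonoverlapping
   square tiles of 175 px at 0.5 um/px (87.5 um per side, a mesoscale
   unit large enough to hold local tissue architecture). Tissue pixels
   are separated from glass by Otsu's threshold on the grayscale
   histogram — tissue is the dark class — and tiles with less than 20%
   tissue are discarded (a tile at exactly 20% is retained; the filter
   removes only tiles *below* the threshold). Retained tiles are
   labeled by a sequential binary classifier chain — tumor vs. stroma,
   then necrosis within tumor (necrosis is tested before intratumoral
   lymphocytes because the two are morphologically similar), then iTIL
   within the remaining tumor, then sTIL within stroma — and assembled
   into a tissue-type annotation image (TTA-image), a 2-D grid with one
   label per tile. TIL is defined as the union of iTIL and sTIL, so
   `|TIL| = |iTIL| + |sTIL|` holds by construction.
2. **Graph construction.** Each of the five compartments (tumor,
   stroma, iTIL, sTIL, TIL) is modeled as an undirected spatial graph:
   affinity propagation (AP) clusters the compartment's tile
   coordinates, the exemplars become nodes, and each node is joined to
   its K nearest neighbors by Euclidean distance.
3. **SNA features.** Seven graph-theoretic metrics: node degree,
   clustering coefficient, closeness centrality, degree centrality,
   Katz centrality, community structure (all node-level), and network
   density (graph-level). Node-level metrics are summarized by a 10-bin
   histogram plus mean, standard deviation, maximum, minimum, and
   median (15 features per metric); appending density gives the 91-dim
   vector per graph.
4. **DLPS.** Tile-level embedding vectors from a frozen, pluggable
   encoder (1,024-dim) are scored by a lightweight per-compartment MLP
   trained under weak supervision (each tile inherits its patient's
   slide-level pCR label); per patient and compartment the mean and
   standard deviation of tile probabilities give 10 deep-learning pCR
   score (DLPS) features.
5. **Modeling.** Per compartment, a 99-dim vector (91 SNA + 2 DLPS + 6
   clinical: ER/PR status and percentage, CEP17, HER2/CEP17 ratio) is
   z-scored, reduced by LASSO (penalty chosen by stratified 5-fold CV),
   and classified by a small grid-searched MLP. Compartments are never
   merged into one model, to avoid cross-compartment collinearity and
   preserve tissue-specific interpretability.

## Parameters that matter

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| tile_px / microns_per_px | 175 / 0.5 | px, um/px | 87.5-um mesoscale tiles |
| min_tissue_fraction | 0.20 | — | discard tiles below 20% tissue |
| K (KNN edges) | 4 | neighbors | operating point of the K x P sensitivity grid |
| P (AP preference) | −50 | −(tile units)² | exemplars absorb tiles within ~7 tiles (~612 um); more negative = coarser graphs |
| AP damping / max_iter / conv_iter | 0.9 / 1000 / 50 | — | conservative damping, convergence = exemplar set stable for 50 iterations |
| n_bins | 10 | bins | histogram summarization |
| Katz alpha, beta | min(0.1, 0.85/λmax), 1 | — | guarantees (I − αA) is invertible |
| DLPS optimizer | Adam, lr 1e-4, batch 512 | — | tile-scorer training |
| DLPS architecture | 1024→256→64→1, dropout 0.25 | — | lightweight scorer, sigmoid output |
| DLPS stopping | 500 epochs max, patience 20, 80/20 patient-stratified split | — | early stopping on validation loss |
| LASSO grid | logspace(−3, 0, 25) | penalty | chosen by stratified 5-fold CV error |
| MLP grid | {(32,), (64,), (64,16)} × L2 {1e-4,1e-3,1e-2} | — | small tabular inputs after selection |
| threshold | 0.5 | probability | operating point for F1/PPV/recall/NPV |

## Numerical conventions and tie-breaks

- **Tiling** drops partial edge tiles rather than padding them: padded
  tiles would carry truncated, label-noisy content. Coordinates are
  0-based, row-major; pixel boxes are half-open intervals.
- **Otsu** maximizes between-class variance over all 256 candidate
  thresholds; ties resolve to the smallest maximizing threshold; a
  single-intensity histogram is returned with a degenerate flag.
- **Classifier chain** uses a fixed 0.5 positive-class cutoff at every
  stage. Adipose/artifact exclusion is delegated to the chain or to the
  synthetic mask; no rule-based detector ships with the package.
- **AP** uses similarity = negative squared Euclidean distance in tile
  units with a shared scalar preference on the diagonal, plus a seeded
  jitter of magnitude 1e-6 that breaks exact symmetry degeneracies and
  makes runs deterministic given (input, seed). Non-convergent runs
  return the current exemplar estimate with a warning rather than
  failing — batch robustness over strictness. Message-passing AP is a
  local method: on heavily overlapping clusters it can settle on
  near-tied suboptimal exemplar sets (reference implementations do the
  same); the test suite checks exact optimality on well-separated
  configurations and net-similarity equivalence with an independent
  implementation elsewhere.
- **KNN edges** are the undirected union of each node's K nearest links
  (union, not intersection, so boundary nodes stay connected);
  distance ties break toward the lower node index after the canonical
  row-major sort, so graphs are reproducible and invariant to input
  tile order. With at most K other nodes, a node connects to all.
- **Closeness** uses the component-size-scaled (Wasserman–Faust) form
  because KNN graphs can be disconnected; isolated nodes score 0.
- **Community structure** partitions by greedy modularity maximization;
  the node-level value is the node's community size divided by the node
  count, which makes the "CS histogram" the community-size
  distribution. Edgeless graphs fall back to singleton communities.
- **Histograms** span the per-graph [min, max] range and are emitted as
  frequencies (counts/n) so graphs of different sizes are comparable;
  an all-equal (or float-noise-range) metric collapses to frequency 1
  in bin 0. Standard deviations are the population (n-denominator)
  form everywhere, defined even for single-node graphs.
- **Empty compartments** produce a valid empty graph and an all-zero
  91-dim vector flagged invalid; missing DLPS compartments contribute
  (0, 0) with a missing flag.
- **LASSO** is the linear (Gaussian) form on 0/1 labels — its
  orthonormal-design solution is the soft-threshold closed form used as
  a test oracle. Binary clinical columns are centered but not rescaled;
  constant columns are forced to zero with a warning; if every
  coefficient shrinks to zero the model falls back to all non-constant
  columns with a warning.
- **Fold hygiene**: inside every cross-validation fold the scaler,
  LASSO selection, and classifier are refit on the training fold only.
- **AUC** is the rank (Mann–Whitney) form with half-credit for ties;
  DeLong compares correlated AUCs via placement-value covariance, with
  p = 1 and a warning when the difference has zero variance. BH-FDR is
  the step-up procedure capped at 1. Chi-square tests use the
  continuity correction only for 2x2 tables with an expected count
  below 5.

## The synthetic cohort

Real slide cohorts are not required anywhere. The generator emulates,
at tile scale, the features the modeling stages consume:

- **Geometry.** A 60x60 tile grid (5.25 mm — a core-needle-biopsy-scale
  section). Tissue is a union of 5 discs of radius 4.5 tiles (tumor)
  with a 2.5-tile stromal band; a few hundred tissue tiles per patient,
  consistent with biopsy fragments. Disc centers scatter around the
  grid center with spread set by the per-group `cluster_scale`
  (non-pCR 12, pCR 5 tiles): responders present compact tissue,
  non-responders dispersed fragments. This is the planted structural
  ("stromal clustering") effect the graph features are meant to
  recover.
- **Lymphocytes.** iTIL/sTIL tiles are placed by a Matérn-style cluster
  process (parents + Gaussian offspring with spread `cluster_scale`/3)
  at per-group rates (iTIL 0.10/0.18, sTIL 0.20/0.30; responders carry
  more TILs). Necrosis is sprinkled inside tumor at rate 0.03 before
  iTIL placement, mirroring the labeling order.
- **Embeddings.** Isotropic unit Gaussians with (compartment, group)
  dependent means; `embedding_effect` (default 0.5 noise SDs) shifts
  the pCR group along a fixed per-compartment direction.
- **Clinical.** ER/PR Bernoulli (base 0.80/0.78, −0.15 in the pCR
  group), lognormal CEP17 (median 2.2) and HER2/CEP17 ratio (median
  3.5, +0.35 log-shift for pCR), pCR prevalence 0.42, cohort n = 150 by
  default — all echoing the development cohort's published
  characteristics. RIS is 0 for pCR patients and lognormal (median
  1.35 cm) otherwise, multiplied by the patient's realized dispersion
  draw, so the Spearman feature-vs-RIS analysis has recoverable signal
  coupled to the same latent parameter that drives the graphs.
- A `null()` configuration equalizes every per-group parameter and
  zeroes the embedding and clinical effects.

**What passing synthetic tests show — and don't.** Recovery of the
planted effect demonstrates that the graph/feature/model chain detects
group differences in spatial organization at realistic cohort sizes and
that the null pipeline is calibrated (held-out AUC ~0.5 without
effects). It does not establish clinical performance: synthetic tissue
lacks staining variation, scanner effects, classifier label noise,
irregular tissue shapes, and the correlation structure of real
morphology. Replicating the published external-validation AUCs requires
the original slide cohorts and trained tissue classifiers, which are
outside this package's scope.

## Experiment harnesses and problem sizes

- **Sensitivity grid**: for each (K, P) in {4,5,6} x {−100,−50,−20},
  graphs are rebuilt, SNA features re-extracted, and the pipeline
  scored by stratified 5-fold CV AUC — SNA features alone, so graph
  parameters are not confounded with deep or clinical features.
- **Ablation**: stratified subsamples of the training cohort at 20, 40,
  60, 80% (seeded), full pipeline refit, fixed held-out evaluation;
  fraction 1.0 reproduces the main model exactly.
- **Recovery study** (the heavy acceptance check): 20 replicate cohorts
  of n = 200 at 70/30 train/held-out split, stroma compartment, SNA
  features alone — matching the sensitivity-analysis design, where
  structural signal is evaluated unconfounded; the planted effect is
  purely structural, so embedding generation (1,024-dim per tile) is
  unnecessary there and the study stays desk-scale. The same 20 seeds
  rerun on null cohorts bound the false-signal rate.

## Known limitations

- AP on ambiguous (heavily overlapping) clusters may return near-tied
  suboptimal exemplar sets; downstream features are insensitive to
  these ties, but exact exemplar identities should not be
  over-interpreted.
- The DLPS tile scorer is a compact in-package network; it trains on
  CPU and is intended for embedding-space inputs, not raw pixels.
- Greedy modularity communities are deterministic but only one of the
  possibly many modularity-maximizing partitions.
- Univariate chi-square/Mann–Whitney p values use asymptotic
  approximations; at very small group sizes exact tests would differ.
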