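# tmegraph

Tissue-compartment spatial graphs and hierarchical feature models for
predicting **pathologic complete response (pCR)** to neoadjuvant
chemotherapy in HER2-positive breast cancer from tile-level maps of
H&E whole-slide images.

## Who this is for

Computational pathology researchers who want an interpretable,
mesoscale alternative (or complement) to end-to-end weakly supervised
slide models: instead of treating a slide as a bag of tiles, the
pipeline models the *spatial organization* of each tissue compartment
of the tumor microenvironment — tumor, stroma, intratumoral and
stromal tumor-infiltrating lymphocytes (iTILs, sTILs), and their union
(TILs) — and turns it into explicit, auditable graph features.

## The model

1. **TTA-images.** A slide is partitioned into nonoverlapping 175-px
   tiles (87.5 um per side at 0.5 um/px); Otsu thresholding separates
   tissue from glass, tiles with < 20% tissue are discarded, and a
   sequential binary classifier chain labels retained tiles (tumor vs
   stroma → necrosis → iTIL → sTIL), giving a 2-D tissue-type
   annotation image (TTA-image).
2. **Tissue graphs.** Per compartment, affinity propagation (AP) on
   tile coordinates with similarity s(i,k) = −‖x_i − x_k‖² and shared
   preference *P* selects exemplar tiles as nodes V; edges E join each
   node to its *K* nearest neighbors (defaults K = 4, P = −50), giving
   G = (V, E).
3. **SNA features.** Node degree (ND), clustering coefficient (CL),
   closeness centrality (CC), degree centrality (DC), Katz centrality
   (KC), and community structure (CS) are each summarized by a 10-bin
   histogram + {mean, SD, max, min, median} (15 features per metric);
   network density NED = 2m/(n(n−1)) is appended: **91 features** per
   graph.
4. **DLPS.** 1,024-dim tile embeddings from a frozen encoder are scored
   by a per-compartment MLP (1024→256→64→1, weak slide-level labels);
   the per-compartment mean and SD of tile probabilities give **10
   deep-learning pCR score (DLPS) features** per patient.
5. **Prediction.** Per compartment, the 99-dim vector (91 SNA + 2 DLPS
   + 6 clinical: ER/PR status and %, CEP17, HER2/CEP17 ratio) is
   z-scored, LASSO-selected, and classified by a small grid-searched
   MLP under stratified 5-fold cross-validation. Evaluation reports
   AUC, F1, PPV, recall, NPV; correlated AUCs are compared with the
   DeLong test; univariate screening uses Mann–Whitney U / chi-square
   with Benjamini–Hochberg FDR, and feature–RIS associations use
   Spearman's ρ.

A synthetic-cohort generator (spatially structured TTA-images whose
clustering differs by response group, class-conditional Gaussian
embeddings, and group-shifted clinical covariates) makes every stage
runnable and testable without any slide data. See `docs/methods.md`
for conventions, parameter rationale, and limitations.

## Worked example

```python
import numpy as np
from tmegraph.synthetic_cohort import SimConfig, simulate_cohort
from tmegraph.graph_construction import GraphParams, build_tissue_graph
from tmegraph.sna_features import extract_sna_features
from tmegraph.pipeline import cohort_feature_matrix, holdout_split
from tmegraph.modeling_eval import ModelConfig, PCRModel, evaluate

cohort = simulate_cohort(150, SimConfig(seed=7))
patient = cohort.patients[0]
graph = build_tissue_graph(patient.tta, "STROMA", GraphParams(K=4, P=-50))
print(f"{graph.n_tiles} stroma tiles -> {graph.n_nodes} exemplar nodes, "
      f"{graph.n_edges} edges")
vec = extract_sna_features(graph)
print(f"SNA vector: {vec.values.shape[0]} features, "
      f"NED = {vec.values[-1]:.3f}")

train, test = holdout_split(cohort, train_frac=0.7, seed=7)
X_tr = cohort_feature_matrix(train, "STROMA", "sna").to_numpy()
X_te = cohort_feature_matrix(test, "STROMA", "sna").to_numpy()
model = PCRModel(ModelConfig(seed=7)).fit(X_tr, train.labels)
report = evaluate(model.predict_proba(X_te), test.labels)
print(f"held-out AUC = {report.auc:.3f}, F1 = {report.f1:.3f}")
```

Output:

```
281 stroma tiles -> 24 exemplar nodes, 57 edges
SNA vector: 91 features, NED = 0.207
held-out AUC = 0.971, F1 = 0.889
```

The synthetic responders present compact tissue with tightly clustered
lymphocytes while non-responders are dispersed, so the stroma-graph
features separate the groups on held-out patients — the qualitative
behavior the pipeline is designed to expose on real cohorts.

A CLI mirrors the library (`tmegraph simulate | preprocess | graph |
features | dlps-train | dlps-aggregate | train | evaluate |
sensitivity | ablate`); run `tmegraph --help`.

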