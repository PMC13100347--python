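"""End-to-end experiment helpers over synthetic cohorts.

These functions wire the simulator to the graph, feature, and modeling
modules for the experiments the package ships: held-out evaluation of a
compartment pipeline, replicate recovery/null studies, exemplar-count
granularity checks, and the training-size ablation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dlps import DLPSConfig, aggregate_dlps, score_tiles, train_tile_scorer
from .graph_construction import GraphParams, ap_cluster, build_tissue_graph
from .modeling_eval import (
    CLINICAL_ORDER, ModelConfig, PCRModel, ablation_run, evaluate, rank_auc,
)
from .sna_features import SNAParams, extract_sna_features, feature_names
from .synthetic_cohort import Cohort, SimConfig, simulate_cohort

__all__ = [
    "cohort_sna_matrix", "cohort_clinical_matrix", "cohort_dlps_features",
    "cohort_feature_matrix", "holdout_split", "holdout_auc",
    "recovery_aucs", "null_aucs", "exemplar_counts_vs_preference",
    "ablation_mean_aucs",
]


def cohort_sna_matrix(
    cohort: Cohort,
    compartment: str,
    graph_params: GraphParams | None = None,
    sna_params: SNAParams | None = None,
) -> pd.DataFrame:
    """91-column SNA feature frame, one row per patient."""
    graph_params = graph_params or GraphParams()
    sna_params = sna_params or SNAParams()
    rows = [
        extract_sna_features(
            build_tissue_graph(p.tta, compartment, graph_params), sna_params
        ).values
        for p in cohort.patients
    ]
    return pd.DataFrame(np.vstack(rows), columns=feature_names(),
                        index=cohort.ids)


def cohort_clinical_matrix(cohort: Cohort) -> pd.DataFrame:
    rows = [p.clinical.clinical_vector() for p in cohort.patients]
    return pd.DataFrame(np.vstack(rows), columns=list(CLINICAL_ORDER),
                        index=cohort.ids)


def cohort_dlps_features(
    train: Cohort,
    score: Cohort,
    config: DLPSConfig | None = None,
) -> pd.DataFrame:
    """Train per-compartment tile scorers on ``train`` and produce the
    10-column DLPS frame for ``score`` (both cohorts need embeddings).

    One scorer per scoreable compartment; TIL reuses the ITIL/STIL tile
    scores.  Scorers only ever see training-cohort tiles.
    """
    config = config or DLPSConfig()
    labels = {p.patient_id: p.pcr for p in train.patients}

    def stack(cohort: Cohort, comp: str):
        X, pid = [], []
        for p in cohort.patients:
            if p.embeddings is None:
                raise ValueError(f"patient {p.patient_id} has no embeddings")
            sel = p.embedding_index["compartment"] == comp
            X.append(p.embeddings[sel.to_numpy()])
            pid += [p.patient_id] * int(sel.sum())
        if any(len(x) for x in X):
            return np.vstack([x for x in X if len(x)]), np.array(pid)
        return np.empty((0, train.config.embedding_dim)), np.array(pid)

    score_rows = []
    for comp in ("TUMOR", "STROMA", "ITIL", "STIL"):
        Xtr, ptr = stack(train, comp)
        scorer = train_tile_scorer(Xtr, ptr, labels, comp, config)
        Xsc, psc = stack(score, comp)
        if len(Xsc):
            s = score_tiles(scorer, Xsc)
            score_rows.append(pd.DataFrame(
                {"patient_id": psc, "compartment": comp, "score": s}
            ))
    scores = pd.concat(score_rows, ignore_index=True)
    feats = aggregate_dlps(scores)
    cols = []
    for comp in ("TUMOR", "STROMA", "ITIL", "STIL", "TIL"):
        cols += [f"DLPS_{comp}_mean", f"DLPS_{comp}_std"]
    data = {pid: feats[pid].as_vector() if pid in feats else np.zeros(10)
            for pid in score.ids}
    return pd.DataFrame.from_dict(data, orient="index", columns=cols).loc[score.ids]


def cohort_feature_matrix(
    cohort: Cohort,
    compartment: str,
    feature_set: str = "sna",
    graph_params: GraphParams | None = None,
    sna_params: SNAParams | None = None,
    dlps_frame: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-patient design matrix for one compartment and feature set.

    ``feature_set`` is a '+'-joined subset of {sna, dlps, clinical}; the
    full set gives the 99-column vector in the documented order.  DLPS
    columns (the compartment's mean and std) come from a precomputed
    ``dlps_frame`` (see :func:`cohort_dlps_features`); without one they
    are zero-filled, the missing-compartment convention.
    """
    parts = []
    wanted = set(feature_set.lower().split("+"))
    unknown = wanted - {"sna", "dlps", "clinical"}
    if unknown:
        raise ValueError(f"unknown feature set component(s): {sorted(unknown)}")
    comp = compartment.upper()
    if "sna" in wanted:
        parts.append(cohort_sna_matrix(cohort, comp, graph_params, sna_params))
    if "dlps" in wanted:
        if dlps_frame is not None:
            sub = dlps_frame[[f"DLPS_{comp}_mean", f"DLPS_{comp}_std"]].copy()
            sub.columns = ["DLPS_mean", "DLPS_std"]
        else:
            sub = pd.DataFrame(0.0, index=cohort.ids,
                               columns=["DLPS_mean", "DLPS_std"])
        parts.append(sub)
    if "clinical" in wanted:
        parts.append(cohort_clinical_matrix(cohort))
    return pd.concat(parts, axis=1)


def holdout_split(
    cohort: Cohort, train_frac: float = 0.7, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Stratified patient-level train/held-out split of a cohort."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(cohort))
    tr, te = train_test_split(
        idx, train_size=train_frac, stratify=cohort.labels, random_state=seed
    )
    return (Cohort([cohort.patients[i] for i in tr], cohort.config),
            Cohort([cohort.patients[i] for i in te], cohort.config))


def holdout_auc(
    seed: int,
    n_patients: int = 200,
    effect: bool = True,
    compartment: str = "STROMA",
    feature_set: str = "sna",
    train_frac: float = 0.7,
    base_config: SimConfig | None = None,
    model_config: ModelConfig | None = None,
) -> float:
    """Simulate a cohort, fit the compartment pipeline on a stratified
    training split, and return the held-out AUC."""
    cfg = base_config or SimConfig()
    cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
    if not effect:
        cfg = cfg.null()
    cohort = simulate_cohort(n_patients, cfg)
    train, test = holdout_split(cohort, train_frac, seed=seed)
    mc = model_config or ModelConfig(seed=seed % (2 ** 31))
    Xtr = cohort_feature_matrix(train, compartment, feature_set).to_numpy()
    Xte = cohort_feature_matrix(test, compartment, feature_set).to_numpy()
    model = PCRModel(mc).fit(Xtr, train.labels)
    return rank_auc(model.predict_proba(Xte), test.labels)


def recovery_aucs(seeds, n_patients: int = 200, **kw) -> list[float]:
    """Held-out stroma AUC per replicate seed, planted effect present."""
    return [holdout_auc(s, n_patients, effect=True, **kw) for s in seeds]


def null_aucs(seeds, n_patients: int = 200, **kw) -> list[float]:
    """Held-out stroma AUC per replicate seed with all effects zeroed."""
    return [holdout_auc(s, n_patients, effect=False, **kw) for s in seeds]


def exemplar_counts_vs_preference(
    points: np.ndarray, preferences=(-20.0, -50.0, -100.0), seed: int = 0
) -> list[int]:
    """Exemplar counts on one point set across AP preference values;
    granularity coarsens (counts non-increasing) as P grows more negative."""
    return [len(ap_cluster(points, preference=p, seed=seed).exemplars)
            for p in preferences]


def ablation_mean_aucs(
    seed: int,
    n_patients: int = 200,
    fractions=(0.2, 0.4, 0.6, 0.8),
    n_subsample_seeds: int = 10,
    compartment: str = "STROMA",
    feature_set: str = "sna",
) -> dict[float, float]:
    """Mean held-out AUC per training fraction over subsample seeds.

    The cohort, its train/held-out split, and the patient features are
    computed once; each (fraction, subsample seed) refits the model on a
    stratified subsample and evaluates on the fixed held-out set.
    """
    cfg = SimConfig(seed=seed)
    cohort = simulate_cohort(n_patients, cfg)
    train, test = holdout_split(cohort, 0.7, seed=seed)
    Xtr = cohort_feature_matrix(train, compartment, feature_set).to_numpy()
    Xte = cohort_feature_matrix(test, compartment, feature_set).to_numpy()
    mc = ModelConfig(seed=seed % (2 ** 31))
    acc: dict[float, list[float]] = {f: [] for f in fractions}
    for sub in range(n_subsample_seeds):
        reports = ablation_run(Xtr, train.labels, Xte, test.labels,
                               fractions, mc, subsample_seed=sub)
        for f, rep in reports.items():
            acc[f].append(rep.auc)
    return {f: float(np.mean(v)) for f, v in acc.items() if v}
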