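"""Hierarchical feature integration, LASSO-selected MLP classifiers, and
the evaluation / statistics / sensitivity / ablation harnesses.

Per compartment, a 99-dimensional patient vector is assembled: 91 SNA
graph features + 2 DLPS values (mean, std of tile scores) + 6 clinical
variables (ER/PR status and percentage, CEP17, HER2/CEP17 ratio).
Features are z-scored (binary columns centered only), reduced by LASSO
with the penalty chosen by stratified 5-fold cross-validation, and
classified by a small MLP whose hidden size and L2 strength are grid
searched by CV AUC.  Compartment models are never merged, to avoid
cross-compartment collinearity.

Evaluation reports AUC (rank form with tie credit), F1, PPV, recall and
NPV at a fixed 0.5 threshold; correlated AUCs are compared by the DeLong
test; univariate screening uses Mann-Whitney U (continuous/ordinal) or
chi-square (categorical) with Benjamini-Hochberg FDR adjustment, and
feature-RIS associations use Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from statsmodels.stats.multitest import multipletests

from . import sna_features as snaf
from .dlps import DLPSFeatures
from .graph_construction import GraphParams, build_tissue_graph
from .sna_features import SNAFeatureVector, SNAParams, extract_sna_features

__all__ = [
    "CLINICAL_ORDER", "ClinicalRecord", "PatientFeatureVector", "ModelConfig",
    "EvalReport", "assemble_features", "patient_feature_names",
    "FeatureScaler", "lasso_select", "LassoResult",
    "train_compartment_classifier", "PCRModel", "evaluate", "delong_test",
    "univariate_tests", "bh_adjust", "spearman_with_ris", "cross_val_auc",
    "sensitivity_grid", "ablation_run", "group_percentages",
]

CLINICAL_ORDER = (
    "er_status", "er_percent", "pr_status", "pr_percent",
    "cep17", "her2_cep17_ratio",
)


@dataclass
class ClinicalRecord:
    """Per-patient clinical variables plus outcome and residual size.

    ``ris_cm`` is the residual infiltration size (longest diameter of the
    residual invasive lesion, cm); by convention it is 0 for pCR patients.
    """

    er_status: int
    er_percent: float
    pr_status: int
    pr_percent: float
    cep17: float
    her2_cep17_ratio: float
    pcr: int
    ris_cm: float

    def __post_init__(self) -> None:
        if self.er_status not in (0, 1) or self.pr_status not in (0, 1):
            raise ValueError("er_status and pr_status must be binary")
        if not (0 <= self.er_percent <= 100 and 0 <= self.pr_percent <= 100):
            raise ValueError("receptor percentages must be in [0, 100]")
        if self.cep17 < 0 or self.her2_cep17_ratio < 0:
            raise ValueError("cep17 and her2_cep17_ratio must be nonnegative")
        if self.pcr not in (0, 1):
            raise ValueError("pcr must be binary")
        if self.ris_cm < 0:
            raise ValueError("ris_cm must be nonnegative")
        if self.pcr == 1 and self.ris_cm != 0:
            raise ValueError("pCR implies ris_cm = 0 under the simulated convention")

    def clinical_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in CLINICAL_ORDER], float)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ClinicalRecord":
        missing = [f.name for f in dc_fields(cls) if f.name not in d]
        if missing:
            raise ValueError(f"missing clinical field(s): {', '.join(missing)}")
        return cls(**{f.name: d[f.name] for f in dc_fields(cls)})


def patient_feature_names() -> list[str]:
    """The documented 99-column order: 91 SNA + 2 DLPS + 6 clinical."""
    return snaf.feature_names() + ["DLPS_mean", "DLPS_std"] + list(CLINICAL_ORDER)


@dataclass
class PatientFeatureVector:
    """The 99-dim per-compartment model input for one patient."""

    compartment: str
    values: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (99,):
            raise ValueError("patient feature vector must have length 99")


def assemble_features(
    sna: SNAFeatureVector,
    dlps: DLPSFeatures | tuple[float, float],
    clinical: ClinicalRecord,
    compartment: str,
    patient_id: str = "",
) -> PatientFeatureVector:
    """Concatenate SNA, DLPS (mean, std), and clinical blocks in the
    documented order.  A missing DLPS compartment contributes (0, 0)."""
    if isinstance(dlps, DLPSFeatures):
        d = dlps.get(compartment)
    else:
        d = (float(dlps[0]), float(dlps[1]))
    vec = np.concatenate([sna.values, np.array(d), clinical.clinical_vector()])
    return PatientFeatureVector(compartment.upper(), vec, patient_id)


@dataclass(frozen=True)
class ModelConfig:
    """LASSO + MLP pipeline configuration."""

    lasso_lambda_grid: tuple[float, ...] = tuple(np.logspace(-3, 0, 25))
    cv_folds: int = 5
    mlp_hidden: tuple[tuple[int, ...], ...] = ((32,), (64,), (64, 16))
    mlp_alphas: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


class FeatureScaler:
    """Column-wise z-scoring with training-set statistics only.

    Binary columns (values within {0, 1}) are centered but not rescaled;
    constant columns are centered with unit divisor.
    """

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        binary = np.array([set(np.unique(col)) <= {0.0, 1.0} for col in X.T])
        sd = np.where(binary | (sd == 0), 1.0, sd)
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass
class LassoResult:
    selected: np.ndarray          # indices of nonzero coefficients
    coef: np.ndarray              # full-length coefficient vector
    intercept: float
    lambda_: float


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
    lambda_: float | None = None,
) -> LassoResult:
    """L1-penalized (Gaussian) LASSO selection on standardized features.

    The penalty is chosen by stratified k-fold cross-validated prediction
    error over ``config.lasso_lambda_grid`` unless ``lambda_`` is fixed.
    Selected features are those with nonzero coefficients.  Constant
    columns are forced to zero with a warning.  Deterministic given the
    config seed (which drives fold assignment).
    """
    config = config or ModelConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("lasso_select requires >= 2 samples in each class")

    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature column(s) forced to zero "
            "coefficient",
            stacklevel=2,
        )
    keep = np.nonzero(~const)[0]
    Xk = X[:, keep]

    if lambda_ is None:
        folds = min(config.cv_folds, int(counts.min()))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
        splits = list(skf.split(Xk, y))
        errs = []
        for lam in config.lasso_lambda_grid:
            fold_err = []
            for tr, te in splits:
                model = Lasso(alpha=lam, max_iter=50_000)
                model.fit(Xk[tr], y[tr])
                pred = model.predict(Xk[te])
                fold_err.append(float(np.mean((pred - y[te]) ** 2)))
            errs.append(np.mean(fold_err))
        lambda_ = float(config.lasso_lambda_grid[int(np.argmin(errs))])

    model = Lasso(alpha=lambda_, max_iter=50_000)
    model.fit(Xk, y)
    coef = np.zeros(X.shape[1])
    coef[keep] = model.coef_
    selected = np.nonzero(coef != 0)[0]
    return LassoResult(selected, coef, float(model.intercept_), float(lambda_))


def _cv_splits(y: np.ndarray, folds: int, seed: int):
    counts = np.bincount(y.astype(int))
    if counts.min() < folds:
        raise ValueError(
            f"a class has only {counts.min()} samples: stratified "
            f"{folds}-fold CV would produce single-class folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def train_compartment_classifier(
    X_selected: np.ndarray, y: np.ndarray, config: ModelConfig | None = None
):
    """Grid-search a small MLP by mean stratified k-fold CV AUC and refit.

    Returns ``(classifier, best_params, best_cv_auc)``.  A fixed seed
    drives fold assignment and weight initialization, so repeated runs
    choose identical hyperparameters.
    """
    config = config or ModelConfig()
    X = np.asarray(X_selected, float)
    y = np.asarray(y, int).ravel()
    if len(y) < 10:
        raise ValueError("need at least 10 samples to train the classifier")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    splits = _cv_splits(y, config.cv_folds, config.seed)

    best = (-np.inf, None)
    for hidden in config.mlp_hidden:
        for alpha in config.mlp_alphas:
            aucs = []
            for tr, te in splits:
                clf = _make_mlp(hidden, alpha, config.seed)
                clf.fit(X[tr], y[tr])
                p = clf.predict_proba(X[te])[:, 1]
                aucs.append(rank_auc(p, y[te]))
            mean_auc = float(np.mean(aucs))
            if mean_auc > best[0]:
                best = (mean_auc, (hidden, alpha))
    hidden, alpha = best[1]
    clf = _make_mlp(hidden, alpha, config.seed)
    clf.fit(X, y)
    return clf, {"hidden_sizes": hidden, "alpha": alpha}, best[0]


def _make_mlp(hidden: tuple[int, ...], alpha: float, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=hidden,
        alpha=alpha,
        solver="lbfgs",
        max_iter=2000,
        random_state=seed,
    )


class PCRModel:
    """The per-compartment pipeline: scale -> LASSO select -> MLP.

    Fitting learns the scaler statistics, the LASSO-selected feature set
    and the grid-searched classifier from the training data only; if the
    LASSO shrinks every coefficient to zero, all (non-constant) features
    are retained with a warning.
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PCRModel":
        X = np.asarray(X, float)
        y = np.asarray(y, int).ravel()
        self.scaler_ = FeatureScaler().fit(X)
        Z = self.scaler_.transform(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lres = lasso_select(Z, y, self.config)
        if lres.selected.size == 0:
            warnings.warn(
                "LASSO selected no features; retaining all non-constant columns",
                stacklevel=2,
            )
            sel = np.nonzero(Z.std(axis=0) > 0)[0]
        else:
            sel = lres.selected
        self.lasso_ = lres
        self.selected_ = sel
        self.classifier_, self.best_params_, self.cv_auc_ = (
            train_compartment_classifier(Z[:, sel], y, self.config)
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler_.transform(np.asarray(X, float))
        return self.classifier_.predict_proba(Z[:, self.selected_])[:, 1]

    def manifest(self) -> dict:
        """Versioned description of the fitted model for serialization."""
        return {
            "version": 1,
            "seed": self.config.seed,
            "lasso_lambda": self.lasso_.lambda_,
            "selected_indices": self.selected_.tolist(),
            "selected_coefficients": self.lasso_.coef[self.selected_].tolist(),
            "mlp": {k: list(v) if isinstance(v, tuple) else v
                    for k, v in self.best_params_.items()},
            "cv_auc": self.cv_auc_,
        }


# --------------------------------------------------------------------------
# evaluation metrics and statistics
# --------------------------------------------------------------------------

def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation with 0.5 credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class EvalReport:
    auc: float
    f1: float
    ppv: float
    recall: float
    npv: float

    def as_dict(self) -> dict[str, float]:
        return {"auc": self.auc, "f1": self.f1, "ppv": self.ppv,
                "recall": self.recall, "npv": self.npv}


def evaluate(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """AUC plus thresholded F1 / PPV / recall / NPV.

    Predictions are positive when score >= threshold.  A metric whose
    denominator is empty (e.g. PPV with no predicted positives) is
    reported as 0 with a warning.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must be probabilities in [0, 1]")
    auc = rank_auc(scores, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))

    def _safe(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (empty denominator); reporting 0",
                          stacklevel=3)
            return 0.0
        return num / den

    ppv = _safe(tp, tp + fp, "PPV")
    rec = _safe(tp, tp + fn, "recall")
    npv = _safe(tn, tn + fn, "NPV")
    f1 = 2 * ppv * rec / (ppv + rec) if (ppv + rec) > 0 else 0.0
    return EvalReport(auc=auc, f1=f1, ppv=ppv, recall=rec, npv=npv)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """DeLong test for two correlated AUCs on the same samples.

    Uses placement-value (structural-component) covariance; returns the
    asymptotic z statistic (AUC_a - AUC_b, standardized) and the
    two-sided normal p value.  Zero variance of the difference (e.g.
    identical score vectors) yields (0, 1) with a warning.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    y = np.asarray(labels, int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("paired scores and labels must share one length")
    pos, neg = a[y == 1], a[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    m, n = int(y.sum()), int((1 - y).sum())

    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((a, b)):
        p, q = s[y == 1], s[y == 0]
        all_r = _midrank(np.concatenate([p, q]))
        rp, rq = _midrank(p), _midrank(q)
        auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
        v10[k] = (all_r[:m] - rp) / n
        v01[k] = 1.0 - (all_r[m:] - rq) / m
        aucs[k] = auc
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        warnings.warn("zero variance of the AUC difference; p = 1", stacklevel=2)
        return 0.0, 1.0
    z = float((aucs[0] - aucs[1]) / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, capped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def univariate_tests(
    features: pd.DataFrame,
    labels: Sequence[int],
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-feature group comparison with BH-FDR adjustment.

    Continuous/ordinal features: Mann-Whitney U with normal approximation
    and tie correction.  Categorical features: chi-square on the
    contingency table (2x2 tables get the continuity correction only when
    an expected count is below 5; larger tables are uncorrected).
    Constant features get p = 1.
    """
    y = np.asarray(labels, int)
    if min(int(y.sum()), int((1 - y).sum())) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for col in features.columns:
        v = features[col].to_numpy()
        if len(np.unique(v)) < 2:
            rows.append((col, "constant", 1.0))
            continue
        if col in categorical:
            tab = pd.crosstab(features[col], y)
            expected = stats.contingency.expected_freq(tab.to_numpy())
            correction = tab.shape == (2, 2) and bool((expected < 5).any())
            chi2 = stats.chi2_contingency(tab.to_numpy(), correction=correction)
            rows.append((col, "chi-square", float(chi2.pvalue)))
        else:
            res = stats.mannwhitneyu(
                v[y == 1], v[y == 0], alternative="two-sided"
            )
            rows.append((col, "mann-whitney", float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["feature", "test", "p_raw"])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def spearman_with_ris(
    feature_values: Sequence[float], ris_values: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between a feature and residual
    infiltration size, with average ranks on ties and the two-sided t
    approximation.  Constant input is flagged (NaN) with a warning."""
    x = np.asarray(feature_values, float)
    r = np.asarray(ris_values, float)
    if len(x) != len(r) or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.std(x) == 0 or np.std(r) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(x, r)
    return float(res.statistic), float(res.pvalue)


def group_percentages(counts: Mapping[str, int], total: int) -> dict[str, float]:
    """Descriptive cohort proportions as percentages at printed precision
    (two decimals), e.g. for pCR / residual-tumor case counts."""
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: round(100.0 * c / total, 2) for k, c in counts.items()}


# --------------------------------------------------------------------------
# cross-validation, sensitivity, ablation harnesses
# --------------------------------------------------------------------------

def cross_val_auc(
    X: np.ndarray, y: np.ndarray, config: ModelConfig | None = None
) -> float:
    """Mean stratified k-fold CV AUC of the full pipeline.

    The scaler, LASSO selection and classifier are refit inside each
    training fold, so no information leaks from the test folds.
    """
    config = config or ModelConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, int).ravel()
    splits = _cv_splits(y, config.cv_folds, config.seed)
    aucs = []
    for tr, te in splits:
        model = PCRModel(config).fit(X[tr], y[tr])
        aucs.append(rank_auc(model.predict_proba(X[te]), y[te]))
    return float(np.mean(aucs))


def sensitivity_grid(
    cohort,
    K_values: Sequence[int] = (4, 5, 6),
    P_values: Sequence[float] = (-100.0, -50.0, -20.0),
    compartments: Sequence[str] = ("STROMA",),
    config: ModelConfig | None = None,
    sna_params: SNAParams | None = None,
) -> pd.DataFrame:
    """Graph-parameter sensitivity using SNA features alone.

    For every (K, P) cell the compartment graphs are rebuilt, the 91-dim
    SNA vectors re-extracted, and the pipeline scored by stratified
    5-fold CV mean AUC: a 3x3 grid per compartment by default.  Empty
    graphs contribute all-zero (invalid) feature rows, which the model
    tolerates.  ``cohort`` needs ``patients`` with ``tta`` and ``pcr``.
    """
    config = config or ModelConfig()
    sna_params = sna_params or SNAParams()
    y = np.array([p.pcr for p in cohort.patients], int)
    rows = []
    for comp in compartments:
        for K in K_values:
            for P in P_values:
                gp = GraphParams(K=int(K), P=float(P), seed=config.seed)
                X = np.vstack([
                    extract_sna_features(
                        build_tissue_graph(p.tta, comp, gp), sna_params
                    ).values
                    for p in cohort.patients
                ])
                auc = cross_val_auc(X, y, config)
                rows.append((comp.upper(), int(K), float(P), auc))
    return pd.DataFrame(rows, columns=["compartment", "K", "P", "auc"])


def ablation_run(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    config: ModelConfig | None = None,
    subsample_seed: int = 0,
) -> dict[float, EvalReport]:
    """Training-set-size ablation against a fixed held-out set.

    Each fraction subsamples the training cohort (stratified, seeded),
    refits the full pipeline, and evaluates on the unchanged test set.
    Fraction 1.0 is the identity (full training set).  Fractions too
    small to retain both classes and at least 10 samples are skipped
    with a warning.
    """
    config = config or ModelConfig()
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, int).ravel()
    out: dict[float, EvalReport] = {}
    for frac in fractions:
        if frac >= 1.0:
            Xs, ys = X_train, y_train
        else:
            n_sub = int(round(frac * len(y_train)))
            counts = np.bincount(y_train)
            if n_sub < 10 or frac * counts.min() < config.cv_folds:
                warnings.warn(
                    f"fraction {frac} leaves too few samples per class; skipped",
                    stacklevel=2,
                )
                continue
            Xs, _, ys, _ = train_test_split(
                X_train, y_train,
                train_size=frac,
                stratify=y_train,
                random_state=subsample_seed,
            )
        model = PCRModel(config).fit(Xs, ys)
        out[float(frac)] = evaluate(
            model.predict_proba(X_test), y_test, config.threshold
        )
    return out
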