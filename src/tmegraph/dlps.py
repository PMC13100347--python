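"""Deep-learning-derived pCR scores (DLPS).

Tile-level embedding vectors (1,024-dim, produced by a frozen pluggable
encoder) are scored by a lightweight per-compartment multilayer
perceptron trained under weak supervision: every tile inherits its
patient's slide-level pCR label.  Per patient and compartment, tile
probabilities are summarized by their mean and population standard
deviation; applied to tumor, stroma, iTILs, sTILs, and their union TILs
this yields 10 response-related features per patient.

The scorer is a 1024 -> 256 -> 64 -> 1 feed-forward network with ReLU
activations, inverted dropout, a sigmoid output, binary cross-entropy
loss, and Adam updates, trained on a patient-level stratified 80/20
split with early stopping on validation loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .preprocessing import COMPARTMENTS

__all__ = [
    "EMBEDDING_DIM", "DLPSConfig", "DLPSFeatures", "TileScorerMLP",
    "train_tile_scorer", "score_tiles", "aggregate_dlps",
]

EMBEDDING_DIM = 1024


@dataclass(frozen=True)
class DLPSConfig:
    """Training configuration for the tile scorer."""

    learning_rate: float = 1e-4
    batch_size: int = 512
    dropout_rate: float = 0.25
    max_epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.2
    seed: int = 0
    hidden_sizes: tuple[int, ...] = (256, 64)

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


class TileScorerMLP:
    """Minimal feed-forward scorer with dropout, Adam, and early stopping.

    Deterministic given the data and ``config.seed`` (the seed drives
    weight initialization, batch shuffling, dropout masks, and the
    patient-level split).
    """

    def __init__(self, input_dim: int, config: DLPSConfig | None = None):
        self.config = config or DLPSConfig()
        self.input_dim = int(input_dim)
        rng = np.random.default_rng(self.config.seed)
        sizes = (self.input_dim, *self.config.hidden_sizes, 1)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._rng = rng
        self.history_: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self.best_val_loss_: float = np.inf
        self.n_epochs_: int = 0

    # ---- forward/backward -------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool = False):
        p_drop = self.config.dropout_rate
        acts = [X]
        masks = []
        h = X
        for layer, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if layer < len(self.W) - 1:
                h = np.maximum(z, 0.0)
                if train and p_drop > 0:
                    mask = (self._rng.random(h.shape) >= p_drop) / (1.0 - p_drop)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = 1.0 / (1.0 + np.exp(-z))
            acts.append(h)
        return acts, masks

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    def _backward(self, acts, masks, y):
        grads_W, grads_b = [], []
        n = y.shape[0]
        delta = (acts[-1].ravel() - y).reshape(-1, 1) / n  # sigmoid + BCE
        for layer in range(len(self.W) - 1, -1, -1):
            h_prev = acts[layer]
            grads_W.insert(0, h_prev.T @ delta)
            grads_b.insert(0, delta.sum(axis=0))
            if layer > 0:
                delta = delta @ self.W[layer].T
                if masks[layer - 1] is not None:
                    delta = delta * masks[layer - 1]
                delta = delta * (acts[layer] > 0)
        return grads_W, grads_b

    # ---- training ---------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        patient_ids: Sequence[str],
    ) -> "TileScorerMLP":
        """Train on tiles with weak (patient-inherited) labels.

        Splits patients (not tiles) 80/20 stratified by patient label,
        minimizes binary cross-entropy by Adam, and stops early when the
        validation loss has not improved for ``patience`` epochs; the
        best-validation weights are restored.
        """
        cfg = self.config
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        patient_ids = np.asarray(patient_ids)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"embedding dim {X.shape[1]} != scorer input dim {self.input_dim}"
            )
        patients = pd.unique(patient_ids)
        pat_label = {p: y[patient_ids == p][0] for p in patients}
        labels = np.array([pat_label[p] for p in patients])
        if len(np.unique(labels)) < 2:
            raise ValueError("training requires tiles from both pCR classes")
        if len(patients) < 5:
            raise ValueError(
                f"need at least 5 patients for a stratified split, got {len(patients)}"
            )
        train_p, val_p = train_test_split(
            patients,
            test_size=cfg.val_fraction,
            stratify=labels,
            random_state=cfg.seed,
        )
        tr = np.isin(patient_ids, train_p)
        Xtr, ytr = X[tr], y[tr]
        Xval, yval = X[~tr], y[~tr]

        mW = [np.zeros_like(W) for W in self.W]
        vW = [np.zeros_like(W) for W in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        best = (np.inf, None)
        since_best = 0
        n = Xtr.shape[0]
        for epoch in range(1, cfg.max_epochs + 1):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                acts, masks = self._forward(Xtr[sel], train=True)
                gW, gb = self._backward(acts, masks, ytr[sel])
                t += 1
                for k in range(len(self.W)):
                    mW[k] = b1 * mW[k] + (1 - b1) * gW[k]
                    vW[k] = b2 * vW[k] + (1 - b2) * gW[k] ** 2
                    mb[k] = b1 * mb[k] + (1 - b1) * gb[k]
                    vb[k] = b2 * vb[k] + (1 - b2) * gb[k] ** 2
                    lr_t = cfg.learning_rate * np.sqrt(1 - b2 ** t) / (1 - b1 ** t)
                    self.W[k] -= lr_t * mW[k] / (np.sqrt(vW[k]) + eps)
                    self.b[k] -= lr_t * mb[k] / (np.sqrt(vb[k]) + eps)
            train_loss = self._bce(self._forward(Xtr)[0][-1].ravel(), ytr)
            val_loss = self._bce(self._forward(Xval)[0][-1].ravel(), yval)
            self.history_["train_loss"].append(train_loss)
            self.history_["val_loss"].append(val_loss)
            self.n_epochs_ = epoch
            if val_loss < best[0] - 1e-9:
                best = (val_loss, ([W.copy() for W in self.W],
                                   [b.copy() for b in self.b]))
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        if best[1] is not None:
            self.W, self.b = best[1]
            self.best_val_loss_ = best[0]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"embedding dim {X.shape[1]} != scorer input dim {self.input_dim}"
            )
        return self._forward(X)[0][-1].ravel()


def train_tile_scorer(
    embeddings: np.ndarray,
    patient_ids: Sequence[str],
    patient_labels: Mapping[str, int],
    compartment: str | None = None,
    config: DLPSConfig | None = None,
) -> TileScorerMLP:
    """Train one compartment's tile scorer from embeddings + weak labels.

    ``patient_labels`` maps patient id to the slide-level pCR label that
    every tile of that patient inherits.
    """
    X = np.asarray(embeddings, float)
    pid = np.asarray(patient_ids)
    if len(pid) != X.shape[0]:
        raise ValueError("one patient id per embedding row required")
    y = np.array([patient_labels[p] for p in pid], float)
    scorer = TileScorerMLP(X.shape[1], config)
    scorer.compartment = (compartment or "").upper() or None
    return scorer.fit(X, y, pid)


def score_tiles(scorer: TileScorerMLP, embeddings: np.ndarray) -> np.ndarray:
    """Probability score per tile, order-preserving."""
    return scorer.predict_proba(embeddings)


@dataclass
class DLPSFeatures:
    """Per-patient DLPS summary: (mean, std) per compartment, 10 values.

    Compartments with no tiles carry (0, 0) and appear in ``missing``.
    """

    per_compartment: dict[str, tuple[float, float]] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)

    def as_vector(self) -> np.ndarray:
        """Fixed order: (mean, std) for TUMOR, STROMA, ITIL, STIL, TIL."""
        out = []
        for comp in COMPARTMENTS:
            m, s = self.per_compartment.get(comp, (0.0, 0.0))
            out += [m, s]
        return np.array(out)

    def get(self, compartment: str) -> tuple[float, float]:
        return self.per_compartment.get(compartment.upper(), (0.0, 0.0))


def aggregate_dlps(
    scores: pd.DataFrame, compartments: Sequence[str] = COMPARTMENTS
) -> dict[str, DLPSFeatures]:
    """Aggregate tile scores into per-patient DLPS features.

    ``scores`` has columns (patient_id, compartment, score) with
    compartment in {TUMOR, STROMA, ITIL, STIL}; the TIL summary is
    computed over the union (concatenation) of each patient's ITIL and
    STIL tile scores, reusing those scores rather than a sixth model.
    Standard deviations are the population form.
    """
    req = {"patient_id", "compartment", "score"}
    if not req.issubset(scores.columns):
        raise ValueError(f"scores frame must have columns {sorted(req)}")
    s = scores.copy()
    s["compartment"] = s["compartment"].str.upper()
    bad = ~s["score"].between(0.0, 1.0)
    if bad.any():
        raise ValueError("tile scores must be in [0, 1]")
    out: dict[str, DLPSFeatures] = {}
    for pid, grp in s.groupby("patient_id", sort=True):
        feats = DLPSFeatures()
        for comp in compartments:
            if comp == "TIL":
                vals = grp.loc[grp["compartment"].isin(["ITIL", "STIL"]), "score"]
            else:
                vals = grp.loc[grp["compartment"] == comp, "score"]
            if len(vals) == 0:
                feats.per_compartment[comp] = (0.0, 0.0)
                feats.missing.add(comp)
            else:
                v = vals.to_numpy(float)
                feats.per_compartment[comp] = (float(v.mean()), float(v.std()))
        out[str(pid)] = feats
    return out
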