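"""Synthetic cohorts: TTA-images, tile embeddings, and clinical records.

The generator emulates the structure a core-needle-biopsy H&E cohort
exhibits at tile scale, so the whole pipeline can be exercised without
any slide data:

* **TTA-images** -- tissue is a union of random discs (tumor cores plus a
  surrounding stromal band); iTIL/sTIL tiles are placed by a Matern-style
  cluster process (parent points + Gaussian offspring) inside tumor and
  stroma respectively; necrosis is sprinkled inside tumor.  The per-group
  ``cluster_scale`` controls both the dispersion of the tissue discs and
  the tightness of lymphocyte clusters, planting the clustered-versus-
  dispersed contrast between response groups that the graph features are
  meant to recover.
* **Embeddings** -- per-tile vectors from an isotropic Gaussian whose mean
  depends on (compartment, group); ``embedding_effect`` is the group mean
  shift, in units of the unit noise scale.
* **Clinical records** -- ER/PR Bernoulli with group-dependent prevalence,
  lognormal CEP17 and HER2/CEP17 ratio with a group shift of the ratio,
  and residual infiltration size (RIS) that is 0 for pCR patients and
  lognormal otherwise, positively coupled to the patient's realized
  stromal dispersion so feature-RIS correlation analyses have
  recoverable signal.

Group label 1 = pCR, 0 = residual tumor; per-group parameter pairs are
indexed ``(non-pCR value, pCR value)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .modeling_eval import ClinicalRecord
from .preprocessing import (
    BACKGROUND, ITIL, NECROSIS, STIL, STROMA, TUMOR,
    PreprocessConfig, TTAImage,
)

__all__ = ["SimConfig", "SimPatient", "Cohort", "simulate_tta_image",
           "simulate_embeddings", "simulate_clinical", "simulate_cohort"]

_SCOREABLE = {TUMOR: "TUMOR", STROMA: "STROMA", ITIL: "ITIL", STIL: "STIL"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults echo the real cohorts the pipeline targets: a 60x60 tile
    grid (5.25 mm at 87.5 um/tile, a core-biopsy-scale section),
    pCR prevalence 0.42, a higher HER2/CEP17 ratio and somewhat lower
    ER/PR positivity in the pCR group, more and tighter TILs in
    responders, and dispersed tissue fragments in non-responders.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    tumor_seed_count: int = 5
    tumor_disc_radius: float = 4.5
    stroma_band: float = 2.5
    itil_rate: tuple[float, float] = (0.10, 0.18)
    stil_rate: tuple[float, float] = (0.20, 0.30)
    cluster_scale: tuple[float, float] = (12.0, 5.0)
    necrosis_rate: float = 0.03
    embedding_dim: int = 1024
    embedding_effect: float = 0.5
    clinical_effects: dict[str, float] = field(default_factory=lambda: {
        "her2_ratio_log_shift": 0.35,
        "er_rate_shift": -0.15,
        "pr_rate_shift": -0.15,
    })
    prevalence: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 10 or self.grid_cols < 10:
            raise ValueError("grid must be at least 10x10")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        for name in ("itil_rate", "stil_rate", "necrosis_rate"):
            vals = getattr(self, name)
            vals = vals if isinstance(vals, tuple) else (vals,)
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} must be nonnegative")
            if any(v > 1 for v in vals):
                raise ValueError(
                    f"{name} > 1 would imply replacing more than 100% of tiles"
                )
        if any(s <= 0 for s in self.cluster_scale):
            raise ValueError("cluster_scale must be positive")

    def null(self) -> "SimConfig":
        """The matching no-effect configuration: identical structural,
        embedding, and clinical distributions in both response groups."""
        mid_scale = float(np.sqrt(self.cluster_scale[0] * self.cluster_scale[1]))
        return replace(
            self,
            cluster_scale=(mid_scale, mid_scale),
            itil_rate=(float(np.mean(self.itil_rate)),) * 2,
            stil_rate=(float(np.mean(self.stil_rate)),) * 2,
            embedding_effect=0.0,
            clinical_effects={k: 0.0 for k in self.clinical_effects},
        )


def _patient_rng(config: SimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, int(index)])


def _clustered_choice(
    cells: np.ndarray, n_pick: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Pick ``n_pick`` of ``cells`` ((m, 2) coordinates) by a Matern-style
    cluster process: parent points among the cells, offspring sampled
    with probability proportional to a Gaussian kernel around parents."""
    m = len(cells)
    if n_pick >= m:
        return np.arange(m)
    n_parents = max(1, n_pick // 8 + 1)
    parents = cells[rng.choice(m, size=n_parents, replace=False)]
    d2 = np.sum((cells[:, None, :] - parents[None, :, :]) ** 2, axis=-1)
    w = np.exp(-d2 / (2.0 * sigma ** 2)).sum(axis=1)
    w = w / w.sum()
    return rng.choice(m, size=n_pick, replace=False, p=w)


def simulate_tta_image(
    config: SimConfig,
    group: int,
    rng: np.random.Generator | None = None,
    latent_scale: float | None = None,
    patient_id: str = "",
) -> TTAImage:
    """Generate one TTA-image for a patient of the given response group.

    ``latent_scale`` is the patient's realized dispersion parameter
    (defaults to the group's ``cluster_scale``); it sets both the spread
    of tissue-disc centers around the grid center and the lymphocyte
    cluster tightness.
    """
    rng = rng or _patient_rng(config, 0)
    scale = float(latent_scale if latent_scale is not None
                  else config.cluster_scale[group])
    R, C = config.grid_rows, config.grid_cols
    center = np.array([R / 2.0, C / 2.0])
    centers = center + rng.normal(0.0, scale, size=(config.tumor_seed_count, 2))
    margin = config.tumor_disc_radius + 1.0
    centers[:, 0] = np.clip(centers[:, 0], margin, R - margin)
    centers[:, 1] = np.clip(centers[:, 1], margin, C - margin)

    rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dmin = np.sqrt(
        np.min(np.sum((pts[:, None, :] - centers[None, :, :]) ** 2, axis=-1), axis=1)
    )
    grid = np.full(R * C, BACKGROUND, dtype=np.int8)
    tumor = dmin <= config.tumor_disc_radius
    stroma = (dmin > config.tumor_disc_radius) & (
        dmin <= config.tumor_disc_radius + config.stroma_band
    )
    grid[tumor] = TUMOR
    grid[stroma] = STROMA

    sigma = max(1.0, scale / 3.0)
    tumor_idx = np.nonzero(tumor)[0]
    # necrosis first (mirrors the labeling order: necrosis shadows iTIL)
    n_nec = rng.binomial(len(tumor_idx), config.necrosis_rate) if len(tumor_idx) else 0
    if n_nec:
        nec = rng.choice(len(tumor_idx), size=n_nec, replace=False)
        grid[tumor_idx[nec]] = NECROSIS
        tumor_idx = np.delete(tumor_idx, nec)
    # iTILs inside the remaining tumor
    n_itil = rng.binomial(len(tumor_idx), config.itil_rate[group]) if len(tumor_idx) else 0
    if n_itil:
        sel = _clustered_choice(pts[tumor_idx], n_itil, sigma, rng)
        grid[tumor_idx[sel]] = ITIL
    # sTILs inside stroma
    stroma_idx = np.nonzero(stroma)[0]
    n_stil = rng.binomial(len(stroma_idx), config.stil_rate[group]) if len(stroma_idx) else 0
    if n_stil:
        sel = _clustered_choice(pts[stroma_idx], n_stil, sigma, rng)
        grid[stroma_idx[sel]] = STIL

    return TTAImage(grid=grid.reshape(R, C), patient_id=patient_id,
                    config=PreprocessConfig())


def _compartment_directions(dim: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Fixed (base mean, unit effect direction) per compartment, shared by
    every patient so group separation is consistent across the cohort."""
    out = {}
    for i, comp in enumerate(sorted(set(_SCOREABLE.values()))):
        rng = np.random.default_rng(7_654_321 + i)
        base = rng.normal(0.0, 0.3, size=dim)
        u = rng.normal(size=dim)
        out[comp] = (base, u / np.linalg.norm(u))
    return out


def simulate_embeddings(
    tta: TTAImage,
    group: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-tile embedding vectors for the scoreable compartments.

    Each tile's vector is drawn from an isotropic unit-variance Gaussian
    whose mean depends on (compartment, group); the pCR group's mean is
    shifted by ``embedding_effect`` along a fixed per-compartment
    direction.  Returns the (n_tiles, dim) matrix plus an index frame
    with (row, col, compartment) per matrix row.
    """
    rng = rng or _patient_rng(config, 0)
    dirs = _compartment_directions(config.embedding_dim)
    rows = []
    vecs = []
    for (r, c) in np.argwhere(np.isin(tta.grid, list(_SCOREABLE))):
        comp = _SCOREABLE[int(tta.grid[r, c])]
        base, u = dirs[comp]
        mean = base + group * config.embedding_effect * u
        vecs.append(mean + rng.normal(size=config.embedding_dim))
        rows.append((int(r), int(c), comp))
    index = pd.DataFrame(rows, columns=["row", "col", "compartment"])
    X = np.vstack(vecs) if vecs else np.empty((0, config.embedding_dim))
    return X, index


def simulate_clinical(
    group: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    latent_scale: float | None = None,
) -> ClinicalRecord:
    """Clinical covariates, pCR label, and residual infiltration size.

    RIS is 0 for pCR patients; otherwise lognormal (median ~1.35 cm) and
    proportional to the patient's realized stromal dispersion, coupling
    the Spearman feature-RIS analysis to the same latent parameter that
    drives the tissue graphs.
    """
    rng = rng or _patient_rng(config, 0)
    eff = config.clinical_effects
    er_p = float(np.clip(0.80 + group * eff.get("er_rate_shift", 0.0), 0.01, 0.99))
    pr_p = float(np.clip(0.78 + group * eff.get("pr_rate_shift", 0.0), 0.01, 0.99))
    er = int(rng.random() < er_p)
    pr = int(rng.random() < pr_p)
    er_pct = float(rng.beta(5, 1.5) * 100) if er else float(rng.uniform(0, 9))
    pr_pct = float(rng.beta(4, 2) * 100) if pr else float(rng.uniform(0, 9))
    cep17 = float(np.exp(rng.normal(np.log(2.2), 0.25)))
    ratio = float(np.exp(rng.normal(
        np.log(3.5) + group * eff.get("her2_ratio_log_shift", 0.0), 0.45
    )))
    if group == 1:
        ris = 0.0
    else:
        ref = config.cluster_scale[0]
        rel = (latent_scale / ref) if latent_scale is not None else 1.0
        ris = float(max(0.02, np.exp(rng.normal(np.log(1.35), 0.4)) * rel))
    return ClinicalRecord(
        er_status=er, er_percent=er_pct, pr_status=pr, pr_percent=pr_pct,
        cep17=cep17, her2_cep17_ratio=ratio, pcr=int(group), ris_cm=ris,
    )


@dataclass
class SimPatient:
    """One synthetic patient: TTA-image, clinical record, optional
    embeddings, and the latent dispersion draw that generated both the
    tissue geometry and (for non-pCR patients) the RIS."""

    patient_id: str
    group: int
    tta: TTAImage
    clinical: ClinicalRecord
    latent_scale: float
    embeddings: np.ndarray | None = None
    embedding_index: pd.DataFrame | None = None

    @property
    def pcr(self) -> int:
        return self.group

    @property
    def ris_cm(self) -> float:
        return self.clinical.ris_cm


@dataclass
class Cohort:
    patients: list[SimPatient]
    config: SimConfig

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.pcr for p in self.patients], int)

    @property
    def ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def __len__(self) -> int:
        return len(self.patients)

    # ---- disk round trip -------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        clin_rows = []
        for p in self.patients:
            p.tta.to_tsv(path / f"{p.patient_id}.tta.tsv")
            if p.embeddings is not None:
                np.save(path / f"{p.patient_id}.emb.npy", p.embeddings)
                p.embedding_index.to_csv(
                    path / f"{p.patient_id}.emb.index.csv", index=False
                )
            clin_rows.append({
                "patient_id": p.patient_id, "group": p.group,
                "latent_scale": p.latent_scale,
                **{f: getattr(p.clinical, f) for f in (
                    "er_status", "er_percent", "pr_status", "pr_percent",
                    "cep17", "her2_cep17_ratio", "pcr", "ris_cm")},
            })
        # %.17g guarantees float64 round-trip through the CSV
        pd.DataFrame(clin_rows).to_csv(path / "clinical.csv", index=False,
                                       float_format="%.17g")
        (path / "sim_config.json").write_text(json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.config.__dict__.items()}, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        raw = json.loads((path / "sim_config.json").read_text())
        for k in ("itil_rate", "stil_rate", "cluster_scale"):
            raw[k] = tuple(raw[k])
        config = SimConfig(**raw)
        clin = pd.read_csv(path / "clinical.csv", float_precision="round_trip")
        patients = []
        for _, row in clin.iterrows():
            pid = str(row["patient_id"])
            tta = TTAImage.from_tsv(path / f"{pid}.tta.tsv")
            emb = None
            idx = None
            emb_path = path / f"{pid}.emb.npy"
            if emb_path.exists():
                emb = np.load(emb_path)
                idx = pd.read_csv(path / f"{pid}.emb.index.csv")
            rec = ClinicalRecord(
                er_status=int(row["er_status"]), er_percent=float(row["er_percent"]),
                pr_status=int(row["pr_status"]), pr_percent=float(row["pr_percent"]),
                cep17=float(row["cep17"]),
                her2_cep17_ratio=float(row["her2_cep17_ratio"]),
                pcr=int(row["pcr"]), ris_cm=float(row["ris_cm"]),
            )
            patients.append(SimPatient(
                patient_id=pid, group=int(row["group"]), tta=tta, clinical=rec,
                latent_scale=float(row["latent_scale"]),
                embeddings=emb, embedding_index=idx,
            ))
        return cls(patients=patients, config=config)


def simulate_patient(
    config: SimConfig, group: int, index: int, include_embeddings: bool = False
) -> SimPatient:
    """Deterministic per (config.seed, patient index)."""
    rng = _patient_rng(config, index)
    latent = float(config.cluster_scale[group] * np.exp(rng.normal(0.0, 0.15)))
    pid = f"P{config.seed}_{index:04d}"
    tta = simulate_tta_image(config, group, rng, latent_scale=latent, patient_id=pid)
    emb = idx = None
    if include_embeddings:
        emb, idx = simulate_embeddings(tta, group, config, rng)
    clinical = simulate_clinical(group, config, rng, latent_scale=latent)
    return SimPatient(
        patient_id=pid, group=group, tta=tta, clinical=clinical,
        latent_scale=latent, embeddings=emb, embedding_index=idx,
    )


def simulate_cohort(
    n_patients: int = 150,
    config: SimConfig | None = None,
    include_embeddings: bool = False,
) -> Cohort:
    """Draw response groups from the prevalence, then compose the TTA,
    embedding, and clinical simulators per patient."""
    config = config or SimConfig()
    if n_patients < 10:
        raise ValueError("n_patients must be >= 10")
    rng = np.random.default_rng([config.seed, 1_000_003])
    groups = (rng.random(n_patients) < config.prevalence).astype(int)
    patients = [
        simulate_patient(config, int(g), i, include_embeddings)
        for i, g in enumerate(groups)
    ]
    return Cohort(patients=patients, config=config)
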