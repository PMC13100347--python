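"""Tile extraction, tissue filtering, and tissue-type-annotation (TTA) images.

A whole-slide raster is partitioned into nonoverlapping square tiles
(default 175 px at 0.5 um/px, i.e. 87.5 um per side).  Tissue pixels are
separated from glass background by Otsu thresholding of the grayscale
histogram; tiles with less than 20% tissue area are discarded.  Retained
tiles are labeled by a sequential binary classifier chain -- tumor vs.
stroma first, then necrosis within tumor, then intratumoral lymphocytes
(iTIL) within the remaining tumor, then stromal lymphocytes (sTIL) within
stroma -- and reassembled into a 2-D grid of tile labels, the TTA-image,
which is the structural substrate for all downstream graph construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "BACKGROUND", "EXCLUDED", "TUMOR", "STROMA", "ITIL", "STIL", "NECROSIS",
    "LABEL_NAMES", "LABEL_CHARS", "COMPARTMENTS",
    "PreprocessConfig", "TileRecord", "TTAImage", "ClassifierChain",
    "OtsuResult", "tile_partition", "otsu_threshold", "filter_tiles",
    "assign_tissue_labels", "extract_compartment", "tiles_from_raster",
    "oracle_chain",
]

# Integer label codes for TTA-image grids.
BACKGROUND = 0
EXCLUDED = 1
TUMOR = 2
STROMA = 3
ITIL = 4
STIL = 5
NECROSIS = 6

LABEL_NAMES = {
    BACKGROUND: "BACKGROUND",
    EXCLUDED: "EXCLUDED",
    TUMOR: "TUMOR",
    STROMA: "STROMA",
    ITIL: "ITIL",
    STIL: "STIL",
    NECROSIS: "NECROSIS",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

# Single-character codes used by the TSV serialization.
LABEL_CHARS = {
    BACKGROUND: ".",
    EXCLUDED: "X",
    TUMOR: "T",
    STROMA: "S",
    ITIL: "i",
    STIL: "s",
    NECROSIS: "N",
}
CHAR_TO_LABEL = {v: k for k, v in LABEL_CHARS.items()}

# Compartments on which tissue graphs are built. TIL = ITIL union STIL.
COMPARTMENTS = ("TUMOR", "STROMA", "ITIL", "STIL", "TIL")

# Fixed palette for PNG label-map export (RGB).
_PALETTE = {
    BACKGROUND: (255, 255, 255),
    EXCLUDED: (200, 200, 200),
    TUMOR: (178, 34, 34),
    STROMA: (255, 200, 120),
    ITIL: (30, 60, 200),
    STIL: (80, 170, 230),
    NECROSIS: (60, 60, 60),
}


@dataclass(frozen=True)
class PreprocessConfig:
    """Tiling geometry and the tissue-content filter threshold.

    ``tile_px`` pixels per tile side, ``microns_per_px`` scanner
    resolution, ``min_tissue_fraction`` minimum tissue area for a tile to
    be retained (tiles with *less* tissue are discarded).
    """

    tile_px: int = 175
    microns_per_px: float = 0.5
    min_tissue_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.tile_px < 1:
            raise ValueError("tile_px must be >= 1")
        if not (0.0 <= self.min_tissue_fraction <= 1.0):
            raise ValueError("min_tissue_fraction must be in [0, 1]")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")

    @property
    def tile_side_microns(self) -> float:
        """Physical tile side length in microns."""
        return self.tile_px * self.microns_per_px


@dataclass
class TileRecord:
    """One tile of the partition: grid position, tissue content, label."""

    row: int
    col: int
    tissue_fraction: float = 1.0
    label: int = BACKGROUND

    def __post_init__(self) -> None:
        if not (0.0 <= self.tissue_fraction <= 1.0):
            raise ValueError(
                f"tissue_fraction must be in [0, 1], got {self.tissue_fraction}"
            )


@dataclass
class TTAImage:
    """Tissue-type annotation image: a 2-D grid of tile labels.

    Every cell carries exactly one label, so compartments are mutually
    exclusive by construction (in particular ITIL and STIL are disjoint,
    and their union defines TIL).
    """

    grid: np.ndarray
    patient_id: str = ""
    config: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or min(self.grid.shape) < 1:
            raise ValueError("TTA grid must be 2-D with dimensions >= 1x1")
        bad = set(np.unique(self.grid)) - set(LABEL_NAMES)
        if bad:
            raise ValueError(f"unknown label codes in grid: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def label_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.grid, return_counts=True)
        return {LABEL_NAMES[int(v)]: int(c) for v, c in zip(vals, counts)}

    # ---- serialization ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the label grid as a TSV of single-character codes with a
        sidecar ``<path>.json`` metadata block."""
        path = Path(path)
        lines = [
            "\t".join(LABEL_CHARS[int(v)] for v in row) for row in self.grid
        ]
        path.write_text("\n".join(lines) + "\n")
        meta = {
            "patient_id": self.patient_id,
            "tile_px": self.config.tile_px,
            "microns_per_px": self.config.microns_per_px,
            "min_tissue_fraction": self.config.min_tissue_fraction,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TTAImage":
        path = Path(path)
        rows = []
        for line in path.read_text().splitlines():
            if line.strip():
                rows.append([CHAR_TO_LABEL[c] for c in line.split("\t")])
        meta_path = Path(str(path) + ".json")
        cfg = PreprocessConfig()
        pid = ""
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            pid = meta.get("patient_id", "")
            cfg = PreprocessConfig(
                tile_px=meta.get("tile_px", 175),
                microns_per_px=meta.get("microns_per_px", 0.5),
                min_tissue_fraction=meta.get("min_tissue_fraction", 0.20),
            )
        return cls(grid=np.array(rows, dtype=np.int8), patient_id=pid, config=cfg)

    def to_png(self, path: str | Path) -> None:
        """Export a color label map with the package's fixed palette."""
        from PIL import Image

        rgb = np.zeros(self.grid.shape + (3,), dtype=np.uint8)
        for code, color in _PALETTE.items():
            rgb[self.grid == code] = color
        Image.fromarray(rgb, mode="RGB").save(Path(path))


def tile_partition(
    image_height_px: int, image_width_px: int, tile_px: int
) -> list[tuple[int, int, int, int]]:
    """Partition an image into nonoverlapping square tiles.

    Returns half-open pixel boxes ``(r0, r1, c0, c1)`` in row-major order.
    Partial tiles at the right/bottom edges are dropped rather than padded.
    An image smaller than one tile yields an empty list with a warning.
    """
    if tile_px < 1:
        raise ValueError("tile_px must be >= 1")
    if image_height_px < tile_px or image_width_px < tile_px:
        warnings.warn(
            f"image {image_height_px}x{image_width_px} smaller than one "
            f"{tile_px}-px tile; no tiles produced",
            stacklevel=2,
        )
        return []
    boxes = []
    for r0 in range(0, image_height_px - tile_px + 1, tile_px):
        for c0 in range(0, image_width_px - tile_px + 1, tile_px):
            boxes.append((r0, r0 + tile_px, c0, c0 + tile_px))
    return boxes


@dataclass(frozen=True)
class OtsuResult:
    threshold: int
    degenerate: bool = False

    def __int__(self) -> int:  # allow use as a plain threshold
        return self.threshold


def otsu_threshold(gray_histogram: Sequence[float] | np.ndarray) -> OtsuResult:
    """Otsu's threshold over a 256-bin grayscale histogram.

    Returns the integer threshold t in [0, 255] maximizing the
    between-class variance of the split ``[0, t) | [t, 255]``; pixels with
    intensity strictly below t count as tissue (H&E tissue is darker than
    glass background).  Ties resolve to the smallest maximizing t.  A
    histogram with all mass at one intensity is degenerate: that intensity
    is returned with the ``degenerate`` flag set.
    """
    hist = np.asarray(gray_histogram, dtype=float)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if np.any(hist < 0) or not np.any(hist > 0):
        raise ValueError("histogram must be nonnegative with some mass")

    nonzero = np.nonzero(hist)[0]
    if len(nonzero) == 1:
        return OtsuResult(threshold=int(nonzero[0]), degenerate=True)

    p = hist / hist.sum()
    levels = np.arange(256)
    omega0 = np.cumsum(p)                      # mass of [0, t] inclusive
    mu_cum = np.cumsum(p * levels)
    mu_total = mu_cum[-1]
    # split after level t-1, i.e. classes [0, t) and [t, 255] for t=1..255
    w0 = omega0[:-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum[:-1] / w0
        mu1 = (mu_total - mu_cum[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    t = int(np.argmax(sigma_b)) + 1
    return OtsuResult(threshold=t, degenerate=False)


def filter_tiles(
    tiles: Iterable[TileRecord], min_tissue_fraction: float
) -> list[TileRecord]:
    """Keep tiles whose tissue fraction is >= the threshold, in order.

    Only tiles with *less* than the threshold are discarded, so a tile
    exactly at the boundary (e.g. 20%) is retained.
    """
    if not (0.0 <= min_tissue_fraction <= 1.0):
        raise ValueError("min_tissue_fraction must be in [0, 1]")
    return [t for t in tiles if t.tissue_fraction >= min_tissue_fraction]


TileScorer = Callable[[TileRecord], float]


@dataclass
class ClassifierChain:
    """The four tile-scoring stages of the sequential labeling scheme.

    Each callable maps a TileRecord to a probability in [0, 1]:
    ``tumor_vs_stroma`` scores P(tumor); ``necrosis`` scores P(necrotic)
    among tumor tiles; ``itil`` scores P(lymphocytic) among the remaining
    tumor tiles; ``stil`` scores P(lymphocytic) among stroma tiles.
    Probability >= 0.5 triggers the positive class.
    """

    tumor_vs_stroma: TileScorer
    necrosis: TileScorer
    itil: TileScorer
    stil: TileScorer


def _score(chain_stage: TileScorer, stage_name: str, tile: TileRecord) -> float:
    p = float(chain_stage(tile))
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise ValueError(
            f"classifier stage {stage_name!r} returned probability {p} "
            f"outside [0, 1] for tile ({tile.row}, {tile.col})"
        )
    return p


def assign_tissue_labels(
    tiles: Sequence[TileRecord],
    classifier_chain: ClassifierChain,
    grid_shape: tuple[int, int],
    config: PreprocessConfig | None = None,
    patient_id: str = "",
) -> TTAImage:
    """Label retained tiles by the sequential binary scheme and assemble
    the TTA-image.

    Order of decisions per retained tile: (1) tumor vs stroma; (2) tumor
    tiles scored necrotic become NECROSIS (necrosis is tested before iTIL
    because the two are morphologically similar); (3) remaining tumor
    tiles scored lymphocytic become ITIL; (4) stroma tiles scored
    lymphocytic become STIL.  Tiles failing the tissue filter become
    EXCLUDED; grid cells with no tile record stay BACKGROUND.
    """
    config = config or PreprocessConfig()
    grid = np.full(grid_shape, BACKGROUND, dtype=np.int8)
    for tile in tiles:
        if not (0 <= tile.row < grid_shape[0] and 0 <= tile.col < grid_shape[1]):
            raise ValueError(f"tile ({tile.row}, {tile.col}) outside grid {grid_shape}")
        if tile.tissue_fraction < config.min_tissue_fraction:
            grid[tile.row, tile.col] = EXCLUDED
            continue
        if _score(classifier_chain.tumor_vs_stroma, "tumor_vs_stroma", tile) >= 0.5:
            if _score(classifier_chain.necrosis, "necrosis", tile) >= 0.5:
                grid[tile.row, tile.col] = NECROSIS
            elif _score(classifier_chain.itil, "itil", tile) >= 0.5:
                grid[tile.row, tile.col] = ITIL
            else:
                grid[tile.row, tile.col] = TUMOR
        else:
            if _score(classifier_chain.stil, "stil", tile) >= 0.5:
                grid[tile.row, tile.col] = STIL
            else:
                grid[tile.row, tile.col] = STROMA
    return TTAImage(grid=grid, patient_id=patient_id, config=config)


def extract_compartment(tta: TTAImage, compartment: str) -> list[tuple[int, int]]:
    """Tile coordinates of one compartment, in deterministic row-major order.

    ``TIL`` returns the union of ITIL and STIL coordinates; every other
    name returns exact-label matches only (so TUMOR excludes tiles that
    were relabeled NECROSIS or ITIL).
    """
    name = compartment.upper()
    if name == "TIL":
        mask = (tta.grid == ITIL) | (tta.grid == STIL)
    elif name in NAME_TO_LABEL and name not in ("BACKGROUND", "EXCLUDED"):
        mask = tta.grid == NAME_TO_LABEL[name]
    elif name in ("BACKGROUND", "EXCLUDED"):
        mask = tta.grid == NAME_TO_LABEL[name]
    else:
        raise ValueError(
            f"unknown compartment {compartment!r}; expected one of "
            f"{COMPARTMENTS}"
        )
    rows, cols = np.nonzero(mask)
    return list(zip(rows.tolist(), cols.tolist()))


def tiles_from_raster(
    gray: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[list[TileRecord], OtsuResult]:
    """Tile a grayscale raster and compute per-tile tissue fractions.

    The Otsu threshold is estimated once from the whole-image histogram;
    a pixel is tissue when its intensity is strictly below the threshold.
    Returns all tiles of the partition (unfiltered) plus the threshold, so
    callers can apply :func:`filter_tiles` or pass the records straight to
    :func:`assign_tissue_labels`, which excludes low-tissue tiles itself.
    """
    config = config or PreprocessConfig()
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale raster")
    hist = np.bincount(
        np.clip(gray.astype(int).ravel(), 0, 255), minlength=256
    ).astype(float)
    otsu = otsu_threshold(hist)
    tiles = []
    for (r0, r1, c0, c1) in tile_partition(*gray.shape, config.tile_px):
        patch = gray[r0:r1, c0:c1]
        frac = float(np.mean(patch < otsu.threshold))
        tiles.append(
            TileRecord(row=r0 // config.tile_px, col=c0 // config.tile_px,
                       tissue_fraction=frac)
        )
    return tiles, otsu


def oracle_chain(truth_grid: np.ndarray) -> ClassifierChain:
    """A classifier chain that reproduces a ground-truth label grid.

    Used to couple synthetic ground truth to the sequential labeling
    contract: running :func:`assign_tissue_labels` with this chain on
    full-tissue tiles returns exactly ``truth_grid`` on its tissue cells.
    """
    truth = np.asarray(truth_grid)

    def prob(label_set: tuple[int, ...]) -> TileScorer:
        def scorer(tile: TileRecord) -> float:
            return 1.0 if truth[tile.row, tile.col] in label_set else 0.0

        return scorer

    return ClassifierChain(
        tumor_vs_stroma=prob((TUMOR, NECROSIS, ITIL)),
        necrosis=prob((NECROSIS,)),
        itil=prob((ITIL,)),
        stil=prob((STIL,)),
    )
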