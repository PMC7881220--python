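"""Histology-to-MSI registration and per-component mean spectra.

Histology segmentation images (necrotic core, fibrin, foam cells,
erythrocytes, calcium) live in their own pixel frame. A point-based
translation+scaling transform estimated from paired landmarks maps the
histology frame onto the MSI grid; masks are resampled nearest-neighbor
(labels must never be interpolated), and the mean log-scale spectrum of each
plaque component — and of the rest of the tissue — is extracted per section.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msi_data import SectionImage

logger = logging.getLogger("plaquemap")

#: fixed label → integer codebook for 8-bit indexed mask images
LABEL_CODES = {
    "background": 0,
    "other_tissue": 1,
    "NC": 2,
    "fibrin": 3,
    "FC": 4,
    "erythrocyte": 5,
    "calcium": 6,
}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}
#: plaque components drawn by the histologist (statistics targets)
COMPONENT_LABELS = ("NC", "fibrin", "FC", "erythrocyte", "calcium")

#: palette for indexed PNG masks (background, tissue, then components)
_PALETTE = [
    (0, 0, 0), (200, 200, 200), (230, 60, 60), (250, 160, 40),
    (70, 120, 220), (140, 40, 140), (245, 245, 120),
]


class SingularLandmarkConfiguration(ValueError):
    """All landmarks coincide: scale is unidentifiable."""


@dataclass(frozen=True)
class SimilarityTransform:
    """Isotropic scaling + translation, q = s·p + t, on (x, y) pixel points."""

    scale: float
    translation: tuple[float, float]

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("transform scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, dtype=float) + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        s = 1.0 / self.scale
        t = (-self.translation[0] * s, -self.translation[1] * s)
        return SimilarityTransform(s, t)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ other: apply ``other`` first."""
        s = self.scale * other.scale
        t = self.apply(np.asarray(other.translation))
        return SimilarityTransform(s, (float(t[0]), float(t[1])))


@dataclass
class LandmarkSet:
    """Paired fiducial points: ``hist`` in the histology frame, ``msi`` in MSI."""

    hist: np.ndarray   # (n, 2) float (x, y)
    msi: np.ndarray    # (n, 2) float (x, y)

    def __post_init__(self):
        self.hist = np.atleast_2d(np.asarray(self.hist, dtype=float))
        self.msi = np.atleast_2d(np.asarray(self.msi, dtype=float))
        if self.hist.shape != self.msi.shape or self.hist.shape[1] != 2:
            raise ValueError("landmark sets must be aligned (n, 2) point arrays")
        if not (np.isfinite(self.hist).all() and np.isfinite(self.msi).all()):
            raise ValueError("landmarks must be finite")
        if len(self.hist) < 2:
            raise ValueError("at least two landmark pairs are required")

    def __len__(self) -> int:
        return len(self.hist)

    @staticmethod
    def read(hist_path: str | Path, msi_path: str | Path) -> "LandmarkSet":
        return LandmarkSet(_read_points(hist_path), _read_points(msi_path))

    def write(self, hist_path: str | Path, msi_path: str | Path) -> None:
        _write_points(self.hist, hist_path)
        _write_points(self.msi, msi_path)


def _read_points(path: str | Path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            x, y = line.split(",")
            rows.append((float(x), float(y)))
    return np.asarray(rows, dtype=float)


def _write_points(points: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{x:.6f},{y:.6f}\n" for x, y in np.atleast_2d(points)))


@dataclass
class SegmentationMask:
    """Label image; exactly one plaque-component label per pixel."""

    labels: np.ndarray     # (rows, cols) uint8 codes per LABEL_CODES

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        bad = set(np.unique(self.labels)) - set(CODE_LABELS)
        if bad:
            raise ValueError(f"unknown label codes in mask: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region(self, label: str) -> np.ndarray:
        return self.labels == LABEL_CODES[label]

    def pixel_count(self, label: str) -> int:
        return int(self.region(label).sum())

    @staticmethod
    def read(path: str | Path) -> "SegmentationMask":
        from PIL import Image

        img = Image.open(path)
        if img.mode not in ("P", "L"):
            raise ValueError(f"mask image must be 8-bit indexed, got mode {img.mode}")
        return SegmentationMask(np.asarray(img, dtype=np.uint8))

    def write(self, path: str | Path) -> None:
        from PIL import Image

        img = Image.fromarray(self.labels, mode="P")
        palette = []
        for rgb in _PALETTE:
            palette.extend(rgb)
        img.putpalette(palette + [0] * (768 - len(palette)))
        img.save(path)


# ---------------------------------------------------------------------------
# transform estimation and mask resampling
# ---------------------------------------------------------------------------

def estimate_transform(landmarks: LandmarkSet) -> SimilarityTransform:
    """Least-squares translation+scaling from paired landmarks.

    Minimizes Σᵢ ‖s·pᵢ + t − qᵢ‖² in closed form via centered moments:
    s = Σ⟨p̃ᵢ, q̃ᵢ⟩ / Σ‖p̃ᵢ‖², t = q̄ − s·p̄.
    """
    p, q = landmarks.hist, landmarks.msi
    pc, qc = p - p.mean(axis=0), q - q.mean(axis=0)
    denom = float((pc ** 2).sum())
    if denom < 1e-12:
        raise SingularLandmarkConfiguration(
            "landmarks are coincident: scale cannot be estimated")
    s = float((pc * qc).sum()) / denom
    if s <= 0:
        raise SingularLandmarkConfiguration(
            f"estimated scale {s:.3g} is not positive: landmark pairing is invalid")
    t = q.mean(axis=0) - s * p.mean(axis=0)
    return SimilarityTransform(s, (float(t[0]), float(t[1])))


def resample_mask(mask: SegmentationMask, transform: SimilarityTransform,
                  msi_grid_shape: tuple[int, int]) -> SegmentationMask:
    """Resample a histology mask onto the MSI grid.

    Each MSI pixel looks up its label through the *inverse* transform with
    nearest-neighbor rounding; pixels mapping outside the histology image
    become background.
    """
    rows, cols = msi_grid_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    q = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    p = transform.inverse().apply(q)
    px = np.rint(p[:, 0]).astype(int)
    py = np.rint(p[:, 1]).astype(int)
    h, w = mask.shape
    inside = (px >= 0) & (px < w) & (py >= 0) & (py < h)
    out = np.zeros(rows * cols, dtype=np.uint8)
    out[inside] = mask.labels[py[inside], px[inside]]
    return SegmentationMask(out.reshape(rows, cols))


# ---------------------------------------------------------------------------
# component mean spectra
# ---------------------------------------------------------------------------

@dataclass
class ComponentSpectra:
    """Per-section mean spectra of each plaque component and of the rest.

    ``mean_in[label]`` averages the log-scale spectra over that label's MSI
    pixels; ``mean_rest[label]`` over all other non-background tissue pixels
    (the "rest of the tissue", calcium included).
    """

    patient_id: str
    section_id: str
    mean_in: dict[str, np.ndarray] = field(default_factory=dict)
    mean_rest: dict[str, np.ndarray] = field(default_factory=dict)
    n_pixels: dict[str, int] = field(default_factory=dict)
    n_rest: dict[str, int] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return list(self.mean_in)


def component_mean_spectra(section: SectionImage, registered_mask: SegmentationMask,
                           min_pixels: int = 20) -> ComponentSpectra:
    """Mean spectrum per plaque component per section.

    Only components covering at least ``min_pixels`` MSI tissue pixels are
    reported (smaller regions give unstable means). Expects log-scale
    intensities when feeding the discriminant models.
    """
    if registered_mask.shape != section.grid_shape:
        raise ValueError("mask must be registered onto the section's MSI grid")
    labels_at = registered_mask.labels[section.coords[:, 0], section.coords[:, 1]]
    tissue_codes = labels_at != LABEL_CODES["background"]
    out = ComponentSpectra(section.patient_id, section.section_id)
    if not tissue_codes.any():
        logger.warning("section %s/%s: registered mask has no tissue labels",
                       section.patient_id, section.section_id)
        return out
    for label in COMPONENT_LABELS:
        inside = labels_at == LABEL_CODES[label]
        n = int(inside.sum())
        if n == 0:
            continue
        if n < min_pixels:
            logger.info("section %s/%s: %s has %d px < %d, skipped",
                        section.patient_id, section.section_id, label, n, min_pixels)
            continue
        rest = tissue_codes & ~inside
        if not rest.any():
            continue
        out.mean_in[label] = section.intensities[inside].mean(axis=0)
        out.mean_rest[label] = section.intensities[rest].mean(axis=0)
        out.n_pixels[label] = n
        out.n_rest[label] = int(rest.sum())
    return out


def register_study_masks(study, min_pixels: int = 20):
    """Estimate transforms and resample every section's mask onto its grid.

    Requires the study manifest to reference mask and landmark files.
    Returns ``{(patient_id, section_id): SegmentationMask}``.
    """
    if study.manifest is None:
        raise ValueError("study carries no manifest; cannot locate masks")
    masks = {}
    for rec in study.manifest.itertuples():
        lm = LandmarkSet.read(rec.landmarks_hist, rec.landmarks_msi)
        transform = estimate_transform(lm)
        section = study.section(str(rec.patient_id), str(rec.section_id))
        mask = SegmentationMask.read(rec.mask)
        masks[(str(rec.patient_id), str(rec.section_id))] = resample_mask(
            mask, transform, section.grid_shape)
    return masks
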