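"""Synthetic plaque-MSI phantom generator.

Emulates the design of a multi-patient carotid-plaque imaging study
(12 patients, ~106 sections, 45 µm pixels, centroided peaks in 300–1,200 m/z)
with planted ground truth: each tissue section is an eccentric-lumen ellipse
carrying histology-style component blobs (necrotic core, fibrin, foam cells,
erythrocytes, calcium), and every lipid class has a class-specific smooth
spatial field plus class→component enrichment folds. The defaults plant the
associations the downstream pipeline is meant to recover: SM and oxidized CE
×3 in the necrotic core, DG and TG ×3 in fibrin, PC ×2 in the cell-rich
foam-cell and erythrocyte areas.

Each species also emits a first-isotopologue satellite at +1.00335 Da with
intensity ratio 0.011 × carbon count, and each section's histology mask is
delivered in a displaced histology frame together with landmark pairs and
the hidden similarity transform, so preprocessing, deisotoping and
registration are all exercised against known answers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .msi_data import ISOTOPE_DELTA, MzAxis, SectionImage, Study
from .registration import (
    COMPONENT_LABELS,
    LABEL_CODES,
    LandmarkSet,
    SegmentationMask,
    SimilarityTransform,
)

logger = logging.getLogger("plaquemap")

LIPID_CLASSES = ("Chol", "oxChol", "CE", "oxCE", "LPC", "PC", "SM", "DG", "TG", "unknown")

#: species observed in carotid plaque imaging, used verbatim in every panel
ANCHOR_SPECIES = [
    (369.350, "Chol", "[M-H2O+H]+", 27),    # cholesteryl ion
    (401.343, "oxChol", "[M+H]+", 27),      # 7-ketocholesterol
    (671.580, "CE", "[M+Na]+", 45),
    (685.567, "oxCE", "[M+Na]+", 45),       # oxoODE-CE
    (701.571, "SM", "[M+H]+", 39),          # SM(34:2)
    (929.768, "TG", "[M+H]+", 58),
    (955.774, "TG", "[M+H]+", 60),
]

#: m/z windows for randomized fill species, by class
CLASS_MZ_RANGES = {
    "Chol": (365.0, 480.0), "oxChol": (380.0, 500.0),
    "CE": (600.0, 720.0), "oxCE": (620.0, 740.0),
    "LPC": (450.0, 580.0), "PC": (700.0, 850.0), "SM": (650.0, 820.0),
    "DG": (550.0, 680.0), "TG": (820.0, 1000.0), "unknown": (305.0, 1100.0),
}
CLASS_CARBONS = {
    "Chol": 27, "oxChol": 27, "CE": 45, "oxCE": 45, "LPC": 24,
    "PC": 40, "SM": 39, "DG": 37, "TG": 55, "unknown": 30,
}
#: arbitrary per-class abundance scales (tests are scale-invariant)
CLASS_BASELINES = {
    "Chol": 8.0, "oxChol": 1.5, "CE": 6.0, "oxCE": 1.5, "LPC": 2.0,
    "PC": 5.0, "SM": 3.0, "DG": 2.0, "TG": 2.5, "unknown": 1.0,
}

#: first 13C isotopologue intensity per carbon atom
ISOTOPE_RATIO_PER_CARBON = 0.011
#: minimum spacing between panel species, Da, so that satellites never
#: collide with a neighboring parent's deisotoping window
MIN_SPECIES_SPACING = 2.2


class PhantomConfigurationError(ValueError):
    """Phantom specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# species panel
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPanel:
    """Monoisotopic species panel: m/z, lipid class, adduct, carbon count."""

    df: pd.DataFrame

    def __post_init__(self):
        mz = self.df["mz"].to_numpy(dtype=float)
        if mz.size and (mz.min() < 300.0 or mz.max() > 1200.0):
            raise ValueError("species m/z outside the acquired 300–1200 range")
        if len(np.unique(np.round(mz, 3))) != len(mz):
            raise ValueError("species m/z not unique at 3 decimals")
        present = set(self.df["lipid_class"])
        missing = set(LIPID_CLASSES) - present
        if missing:
            raise ValueError(f"panel lacks lipid classes: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mz(self) -> np.ndarray:
        return self.df["mz"].to_numpy(dtype=float)

    def species_of_class(self, lipid_class: str) -> np.ndarray:
        return self.df.loc[self.df["lipid_class"] == lipid_class, "mz"].to_numpy()

    def axis_table(self) -> pd.DataFrame:
        """Full acquired-peak table: parents plus isotope satellites, sorted."""
        parents = self.df.assign(is_satellite=False, parent_mz=np.nan)
        sats = self.df.assign(
            mz=np.round(self.df["mz"] + ISOTOPE_DELTA, 5),
            is_satellite=True, parent_mz=self.df["mz"])
        table = pd.concat([parents, sats], ignore_index=True)
        return table.sort_values("mz", ignore_index=True)


def generate_species_panel(n_per_class: int, seed: int) -> SpeciesPanel:
    """Anchor species verbatim plus randomized fill species per class.

    Each class holds at least ``n_per_class`` species; fill m/z values are
    drawn in class-typical windows with ≥2.2 Da spacing (so that isotope
    satellites stay resolvable from neighboring parents) and rounded to
    3 decimals. Deterministic per seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    rng = np.random.default_rng(seed)
    rows = [dict(mz=mz, lipid_class=c, adduct=a, carbon_count=cc)
            for mz, c, a, cc in ANCHOR_SPECIES]
    taken = [r["mz"] for r in rows]
    for lipid_class in LIPID_CLASSES:
        have = sum(r["lipid_class"] == lipid_class for r in rows)
        lo, hi = CLASS_MZ_RANGES[lipid_class]
        for _ in range(max(0, n_per_class - have)):
            for _attempt in range(200):
                mz = float(np.round(rng.uniform(lo, hi), 3))
                if all(abs(mz - t) >= MIN_SPECIES_SPACING for t in taken):
                    break
            else:   # pragma: no cover - window saturated
                raise PhantomConfigurationError(
                    f"cannot place {n_per_class} species in {lipid_class} window")
            carbons = int(np.clip(CLASS_CARBONS[lipid_class] + rng.integers(-4, 5), 10, 89))
            adduct = str(rng.choice(["[M+H]+", "[M+Na]+", "[M+K]+"]))
            rows.append(dict(mz=mz, lipid_class=lipid_class, adduct=adduct,
                             carbon_count=carbons))
            taken.append(mz)
    df = pd.DataFrame(rows).sort_values("mz", ignore_index=True)
    return SpeciesPanel(df)


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass
class Blob:
    """Gaussian-smoothed superellipse in tissue-fraction coordinates."""

    center: tuple[float, float]     # (x, y) as fractions of the grid
    radii: tuple[float, float]
    exponent: float = 2.5


def default_geometry() -> dict[str, list[Blob]]:
    return {
        "NC": [Blob((0.34, 0.42), (0.17, 0.13))],
        "fibrin": [Blob((0.66, 0.64), (0.14, 0.11))],
        "FC": [Blob((0.64, 0.27), (0.10, 0.08))],
        "erythrocyte": [Blob((0.33, 0.71), (0.08, 0.07))],
        "calcium": [Blob((0.76, 0.42), (0.06, 0.05))],
    }


def default_enrichment() -> dict[str, list[tuple[str, float]]]:
    """Planted class→component enrichment folds (the phantom's ground truth)."""
    return {
        "SM": [("NC", 3.0)],
        "oxCE": [("NC", 3.0)],
        "DG": [("fibrin", 3.0)],
        "TG": [("fibrin", 3.0)],
        "PC": [("FC", 2.0), ("erythrocyte", 2.0)],
    }


@dataclass
class PhantomSpec:
    """All knobs of one synthetic section / study template."""

    grid_shape: tuple[int, int] = (64, 64)
    pixel_size_um: float = 45.0
    component_geometry: dict[str, list[Blob]] = field(default_factory=default_geometry)
    enrichment: dict[str, list[tuple[str, float]]] = field(default_factory=default_enrichment)
    noise_sigma: float = 0.3          # multiplicative lognormal σ (log scale)
    # amplitude of the smooth per-class field: within-class abundance
    # *texture*; larger values would constitute additional spatial
    # components, contradicting the phantom's declared component count
    heterogeneity: float = 0.1
    additive_floor: float = 0.02      # half-normal baseline, × class baseline
    isotope_per_carbon: float = ISOTOPE_RATIO_PER_CARBON
    tissue_center: tuple[float, float] = (0.5, 0.5)
    tissue_radii: tuple[float, float] = (0.46, 0.40)
    lumen_center: tuple[float, float] = (0.56, 0.50)
    lumen_radii: tuple[float, float] = (0.10, 0.09)
    seed: int = 0

    def __post_init__(self):
        known = set(COMPONENT_LABELS)
        for lipid_class, targets in self.enrichment.items():
            if lipid_class not in LIPID_CLASSES:
                raise PhantomConfigurationError(f"unknown lipid class {lipid_class!r}")
            for label, fold in targets:
                if label not in known:
                    raise PhantomConfigurationError(
                        f"enrichment references unknown label {label!r}")
                if fold < 0:
                    raise PhantomConfigurationError("enrichment folds must be ≥ 0")
        cx, cy = self.tissue_center
        rx, ry = self.tissue_radii
        for label, blobs in self.component_geometry.items():
            if label not in known:
                raise PhantomConfigurationError(f"unknown component label {label!r}")
            for b in blobs:
                u = ((b.center[0] - cx) / rx) ** 2 + ((b.center[1] - cy) / ry) ** 2
                if u > 1:
                    raise PhantomConfigurationError(
                        f"{label} blob center lies outside the tissue ellipse")

    def noise_free(self) -> "PhantomSpec":
        """Copy with every stochastic intensity term switched off."""
        return replace(self, noise_sigma=0.0, heterogeneity=0.0, additive_floor=0.0)

    @property
    def true_k(self) -> int:
        """Planted spatial component count: distinct enrichment signatures
        plus the base tissue. Labels sharing one signature (e.g. PC enriched
        in both cell-rich areas) form a single spectral component."""
        signatures: dict[str, set] = {}
        for lipid_class, targets in self.enrichment.items():
            for label, fold in targets:
                if fold != 1.0:
                    signatures.setdefault(label, set()).add((lipid_class, fold))
        distinct = {frozenset(s) for s in signatures.values()}
        return len(distinct) + 1

    def enriched_labels(self) -> set[str]:
        return {label for targets in self.enrichment.values() for label, _ in targets}


def rank_recovery_spec(true_k: int, grid: int = 64, fold: float = 3.0,
                       noise_sigma: float = 0.3) -> PhantomSpec:
    """Phantom with ``true_k`` well-separated spatial components.

    Plants ``true_k − 1`` component labels of comparable size, each enriched
    fold-3 in a distinct pair of lipid classes, on the base tissue — the
    controlled geometry used for rank-recovery experiments (the default
    study geometry has deliberately small, weakly contrasted cell-rich
    areas, which is a harder segmentation problem than rank selection is
    meant to solve).
    """
    if not 2 <= true_k <= 6:
        raise PhantomConfigurationError("rank-recovery phantoms support k in 2..6")
    labels = ["NC", "fibrin", "FC", "erythrocyte", "calcium"][: true_k - 1]
    signatures = [("SM", "oxCE"), ("DG", "TG"), ("PC", "LPC"),
                  ("CE", "oxChol"), ("Chol", "unknown")]
    centers = [(0.32, 0.36), (0.68, 0.62), (0.66, 0.28), (0.32, 0.70), (0.52, 0.24)]
    geometry = {label: [Blob(centers[i], (0.13, 0.11))] for i, label in enumerate(labels)}
    enrichment = {}
    for i, label in enumerate(labels):
        for lipid_class in signatures[i]:
            enrichment.setdefault(lipid_class, []).append((label, fold))
    return PhantomSpec(grid_shape=(grid, grid), component_geometry=geometry,
                       enrichment=enrichment, noise_sigma=noise_sigma)


def _ellipse(xx, yy, center, radii, exponent=2.0):
    u = (np.abs((xx - center[0]) / radii[0]) ** exponent
         + np.abs((yy - center[1]) / radii[1]) ** exponent)
    return u <= 1.0


def build_truth_labels(spec: PhantomSpec, rng: np.random.Generator | None = None,
                       labels: tuple[str, ...] | None = None) -> SegmentationMask:
    """Render the planted label image in the MSI frame."""
    h, w = spec.grid_shape
    yy, xx = np.mgrid[0:h, 0:w]
    xx = (xx + 0.5) / w
    yy = (yy + 0.5) / h
    tissue = _ellipse(xx, yy, spec.tissue_center, spec.tissue_radii)
    tissue &= ~_ellipse(xx, yy, spec.lumen_center, spec.lumen_radii)
    out = np.where(tissue, LABEL_CODES["other_tissue"], LABEL_CODES["background"])
    wanted = labels if labels is not None else tuple(spec.component_geometry)
    for label in wanted:
        for blob in spec.component_geometry.get(label, []):
            ind = _ellipse(xx, yy, blob.center, blob.radii, blob.exponent).astype(float)
            ind = gaussian_filter(ind, sigma=1.2) > 0.5
            paint = ind & tissue & (out == LABEL_CODES["other_tissue"])
            out[paint] = LABEL_CODES[label]
    return SegmentationMask(out.astype(np.uint8))


# ---------------------------------------------------------------------------
# section synthesis
# ---------------------------------------------------------------------------

@dataclass
class SectionRecord:
    """One generated section with its observable and hidden parts."""

    section: SectionImage                  # observable spectra (MSI frame)
    hist_mask: SegmentationMask            # observable mask (histology frame)
    landmarks: LandmarkSet                 # observable fiducials, both frames
    truth_mask: SegmentationMask           # hidden: labels in the MSI frame
    transform: SimilarityTransform         # hidden: histology → MSI


@dataclass
class GroundTruth:
    """Everything the phantom planted, for recovery tests."""

    panel: SpeciesPanel
    enrichment: dict[str, list[tuple[str, float]]]
    true_k: int
    truth_masks: dict[tuple[str, str], SegmentationMask] = field(default_factory=dict)
    transforms: dict[tuple[str, str], SimilarityTransform] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        # structured phantoms must plant ≥ 2 spatial components; a *null*
        # phantom (no enrichment anywhere) is base tissue only, true_k = 1
        floor = 2 if any(f != 1.0 for t in self.enrichment.values() for _, f in t) else 1
        if self.true_k < floor:
            raise ValueError("a structured phantom must plant at least two "
                             "spatial components")

    def enriched_species(self, label: str) -> np.ndarray:
        """Parent m/z values planted as enriched in ``label``."""
        out = []
        for lipid_class, targets in self.enrichment.items():
            if any(lbl == label and fold != 1.0 for lbl, fold in targets):
                out.append(self.panel.species_of_class(lipid_class))
        return np.sort(np.concatenate(out)) if out else np.array([])


def _species_factor(mz: np.ndarray) -> np.ndarray:
    # deterministic per-species abundance variation (golden-ratio hash)
    return 0.6 + 0.8 * np.modf(mz * 0.6180339887)[0]


def _draw_transform(rng: np.random.Generator) -> SimilarityTransform:
    """Hidden histology→MSI transform: scale 0.8–1.25, translation ±10 px
    around a fixed −12 px offset that keeps the histology canvas covering
    the section."""
    s = float(rng.uniform(0.8, 1.25))
    t = rng.uniform(-10.0, 10.0, size=2) - 12.0
    return SimilarityTransform(s, (float(t[0]), float(t[1])))


def _hist_frame_mask(truth: SegmentationMask, transform: SimilarityTransform,
                     msi_shape: tuple[int, int]) -> SegmentationMask:
    h, w = msi_shape
    hist_h = int(np.ceil((h + 24) / 0.8))
    hist_w = int(np.ceil((w + 24) / 0.8))
    yy, xx = np.mgrid[0:hist_h, 0:hist_w]
    q = transform.apply(np.column_stack([xx.ravel(), yy.ravel()]).astype(float))
    qx = np.rint(q[:, 0]).astype(int)
    qy = np.rint(q[:, 1]).astype(int)
    inside = (qx >= 0) & (qx < w) & (qy >= 0) & (qy < h)
    out = np.zeros(hist_h * hist_w, dtype=np.uint8)
    out[inside] = truth.labels[qy[inside], qx[inside]]
    return SegmentationMask(out.reshape(hist_h, hist_w))


def generate_section(spec: PhantomSpec, panel: SpeciesPanel,
                     truth_labels: tuple[str, ...] | None = None,
                     rng: np.random.Generator | None = None,
                     patient_id: str = "P01", section_id: str = "S01") -> SectionRecord:
    """Synthesize one section: spectra, displaced histology mask, landmarks.

    Per tissue pixel and species, intensity =
    class baseline × species factor × enrichment fold (if the pixel lies in
    an enriched label) × smooth per-class spatial field × lognormal(σ) noise,
    plus a small half-normal additive floor. Isotope satellites follow their
    parent exactly at ratio 0.011 × carbon count.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    truth = build_truth_labels(spec, rng, labels=truth_labels)
    h, w = spec.grid_shape
    tissue = truth.labels != LABEL_CODES["background"]
    coords = np.argwhere(tissue)
    n_pix = len(coords)

    axis = panel.axis_table()
    n_parents = len(panel)
    parent_mz = panel.mz
    classes = panel.df["lipid_class"].to_numpy()
    carbons = panel.df["carbon_count"].to_numpy()
    base = np.array([CLASS_BASELINES[c] for c in classes]) * _species_factor(parent_mz)

    # per-class smooth multiplicative field
    fields = {}
    for lipid_class in set(classes):
        if spec.heterogeneity > 0:
            g = gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 8)
            g = g / (g.std() + 1e-12) * spec.heterogeneity
            fields[lipid_class] = np.exp(g)[coords[:, 0], coords[:, 1]]
        else:
            fields[lipid_class] = np.ones(n_pix)

    # per-class per-pixel enrichment fold
    label_at = truth.labels[coords[:, 0], coords[:, 1]]
    folds = {}
    for lipid_class in set(classes):
        f = np.ones(n_pix)
        for label, fold in spec.enrichment.get(lipid_class, []):
            f[label_at == LABEL_CODES[label]] *= fold
        folds[lipid_class] = f

    parents = np.empty((n_pix, n_parents))
    for j in range(n_parents):
        signal = base[j] * fields[classes[j]] * folds[classes[j]]
        if spec.noise_sigma > 0:
            signal = signal * rng.lognormal(0.0, spec.noise_sigma, size=n_pix)
        if spec.additive_floor > 0:
            signal = signal + spec.additive_floor * base[j] * np.abs(
                rng.standard_normal(n_pix))
        parents[:, j] = signal

    # satellites track their (noisy) parent exactly: ratio model is exact
    ratios = spec.isotope_per_carbon * carbons
    satellites = parents * ratios[None, :]

    full = np.empty((n_pix, len(axis)))
    parent_pos = {mz: i for i, mz in enumerate(parent_mz)}
    for col, row in enumerate(axis.itertuples()):
        src = parent_pos[row.parent_mz if row.is_satellite else row.mz]
        full[:, col] = satellites[:, src] if row.is_satellite else parents[:, src]

    section = SectionImage(patient_id, section_id, coords, full, spec.grid_shape,
                           spec.pixel_size_um)
    transform = _draw_transform(rng)
    hist_mask = _hist_frame_mask(truth, transform, spec.grid_shape)

    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    msi_points = np.array([
        [c0, r0], [c1, r0], [c0, r1], [c1, r1],
        [(c0 + c1) / 2, (r0 + r1) / 2], [(c0 + 3 * c1) / 4, (3 * r0 + r1) / 4],
    ], dtype=float)
    hist_points = transform.inverse().apply(msi_points)
    landmarks = LandmarkSet(hist_points, msi_points)
    return SectionRecord(section, hist_mask, landmarks, truth, transform)


# ---------------------------------------------------------------------------
# study synthesis
# ---------------------------------------------------------------------------

def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator,
                 center_jitter: float, radius_range: tuple[float, float]) -> PhantomSpec:
    geometry = {}
    for label, blobs in spec.component_geometry.items():
        out = []
        for b in blobs:
            cx = b.center[0] + rng.uniform(-center_jitter, center_jitter)
            cy = b.center[1] + rng.uniform(-center_jitter, center_jitter)
            f = rng.uniform(*radius_range)
            out.append(Blob((cx, cy), (b.radii[0] * f, b.radii[1] * f), b.exponent))
        geometry[label] = out
    return replace(spec, component_geometry=geometry)


def generate_study(n_patients: int, sections_per_patient: tuple[int, int],
                   spec_template: PhantomSpec, seed: int,
                   out_dir: str | Path | None = None,
                   n_per_class: int = 3) -> tuple[Study, GroundTruth]:
    """Generate a multi-patient phantom study, optionally written to disk.

    Per patient the component geometry is jittered (plaque morphology varies
    between patients more than between adjacent sections of one plaque).
    When ``out_dir`` is given, sections go out as continuous-mode imzML,
    masks as 8-bit indexed PNG, landmarks as plain-text x,y pairs, and the
    study manifest, species panel and ground-truth record as CSV/JSON —
    fully reproducible per seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    lo, hi = sections_per_patient
    if not 1 <= lo <= hi:
        raise ValueError("sections_per_patient must be an increasing positive range")

    root = np.random.SeedSequence(seed)
    panel = generate_species_panel(n_per_class, seed=int(root.spawn(1)[0].generate_state(1)[0] % 2**31))
    truth = GroundTruth(panel, spec_template.enrichment, spec_template.true_k, seed=seed)

    sections: list[SectionImage] = []
    records: list[tuple[str, str, SectionRecord]] = []
    count_rng = np.random.default_rng(root.spawn(1)[0])
    for p in range(n_patients):
        patient_id = f"P{p + 1:02d}"
        patient_seq = np.random.SeedSequence(entropy=seed, spawn_key=(1, p))
        patient_rng = np.random.default_rng(patient_seq)
        patient_spec = _jitter_spec(spec_template, patient_rng, 0.04, (0.85, 1.15))
        n_sections = int(count_rng.integers(lo, hi + 1))
        for s in range(n_sections):
            section_id = f"S{s + 1:02d}"
            section_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(2, p, s)))
            section_spec = _jitter_spec(patient_spec, section_rng, 0.015, (0.95, 1.05))
            rec = generate_section(section_spec, panel, rng=section_rng,
                                   patient_id=patient_id, section_id=section_id)
            sections.append(rec.section)
            records.append((patient_id, section_id, rec))
            truth.truth_masks[(patient_id, section_id)] = rec.truth_mask
            truth.transforms[(patient_id, section_id)] = rec.transform

    axis_df = panel.axis_table()
    axis = MzAxis(axis_df["mz"].to_numpy())
    annotations = axis_df.rename(columns={"is_satellite": "is_satellite"})
    manifest = None
    if out_dir is not None:
        manifest = _write_study(Path(out_dir), records, axis_df, spec_template, truth)
    study = Study(sections, axis, annotations=annotations, manifest=manifest)
    return study, truth


def _write_study(out: Path, records, axis_df: pd.DataFrame,
                 spec: PhantomSpec, truth: GroundTruth) -> pd.DataFrame:
    from pyimzml.ImzMLWriter import ImzMLWriter

    for sub in ("sections", "masks", "truth", "landmarks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    mz = axis_df["mz"].to_numpy()
    rows = []
    for patient_id, section_id, rec in records:
        stem = f"{patient_id}_{section_id}"
        imzml = out / "sections" / f"{stem}.imzML"
        with ImzMLWriter(str(imzml), mode="continuous") as writer:
            for i, (r, c) in enumerate(rec.section.coords):
                writer.addSpectrum(mz, rec.section.intensities[i],
                                   (int(c) + 1, int(r) + 1, 1))
        rec.hist_mask.write(out / "masks" / f"{stem}.png")
        rec.truth_mask.write(out / "truth" / f"{stem}.png")
        rec.landmarks.write(out / "landmarks" / f"{stem}_hist.txt",
                            out / "landmarks" / f"{stem}_msi.txt")
        rows.append(dict(
            patient_id=patient_id, section_id=section_id,
            imzml=f"sections/{stem}.imzML", mask=f"masks/{stem}.png",
            truth_mask=f"truth/{stem}.png",
            landmarks_hist=f"landmarks/{stem}_hist.txt",
            landmarks_msi=f"landmarks/{stem}_msi.txt"))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    for col in ("imzml", "mask", "truth_mask", "landmarks_hist", "landmarks_msi"):
        manifest[col] = [str(out / p) for p in manifest[col]]
    axis_df.to_csv(out / "panel.csv", index=False)
    record = dict(
        seed=truth.seed, true_k=truth.true_k,
        enrichment={c: [[l, f] for l, f in t] for c, t in truth.enrichment.items()},
        noise_sigma=spec.noise_sigma, heterogeneity=spec.heterogeneity,
        grid_shape=list(spec.grid_shape),
        sections=[dict(patient_id=p, section_id=s,
                       scale=truth.transforms[(p, s)].scale,
                       translation=list(truth.transforms[(p, s)].translation))
                  for p, s, _ in records],
    )
    (out / "ground_truth.json").write_text(json.dumps(record, indent=1, sort_keys=True))
    return manifest
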