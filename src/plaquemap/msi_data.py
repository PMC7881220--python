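"""Data model and preprocessing for plaque MALDI-MSI studies.

A *study* is a collection of tissue sections from one or more patients, each
section a pixel grid of centroided lipid mass spectra on a shared m/z axis.
Preprocessing follows the standard reduction for this kind of dataset:

1. align peaks across sections onto one m/z axis (tolerance-based),
2. keep peaks measured in more than 30% of all tissue sections,
3. remove first-isotopologue satellites (adducts of the same molecule are
   kept: their mass gaps differ from the ~1.003 Da isotope spacing),
4. ln(1+x) transform for statistics, raw scale kept for image display,
5. per-m/z image normalization (robust 99th-percentile ceiling) for display.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("plaquemap")

#: mass gap between a peak and its first 13C isotopologue, Da
ISOTOPE_DELTA = 1.00335
#: acquired mass range, Da
MZ_RANGE = (300.0, 1200.0)
#: default peak-matching tolerance across sections, Da (TOF-class resolution)
DEFAULT_MZ_TOL = 0.02
#: fraction of tissue pixels that must be nonzero for a peak to count as
#: "measured" in a section (suppresses single-pixel noise)
PRESENCE_PIXEL_QUORUM = 0.01
#: a candidate satellite is only removed if its median intensity ratio to the
#: lighter partner stays below this ceiling (lipids have < 90 carbons)
ISOTOPE_RATIO_CEILING = 0.9

#: display order of lipid classes in figures and correlation matrices
CLASS_ORDER = ("Chol", "oxChol", "CE", "oxCE", "LPC", "PC", "SM", "DG", "TG", "unknown")


class StudyFormatError(RuntimeError):
    """Raised when section files cannot be reconciled into one study."""


@dataclass(frozen=True)
class MzAxis:
    """Shared, strictly increasing m/z axis of a study."""

    values: np.ndarray
    tolerance: float = DEFAULT_MZ_TOL

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("m/z axis must be one-dimensional")
        if values.size and not np.all(np.diff(values) > 0):
            raise ValueError("m/z axis must be strictly increasing")
        if values.size and (values[0] < MZ_RANGE[0] or values[-1] > MZ_RANGE[1] + 2.0):
            # +2 Da headroom: isotope satellites of peaks near the upper edge
            raise ValueError(f"m/z values outside acquired range {MZ_RANGE}")

    def __len__(self) -> int:
        return len(self.values)

    def index_of(self, mz: float) -> int:
        """Index of the axis peak matching ``mz`` within tolerance."""
        i = int(np.argmin(np.abs(self.values - mz)))
        if abs(self.values[i] - mz) > self.tolerance:
            raise KeyError(f"no peak within {self.tolerance} Da of m/z {mz}")
        return i


@dataclass
class SectionImage:
    """One tissue section: tissue-pixel spectra on a regular 45 µm grid.

    ``intensities`` holds only tissue pixels (rows follow ``coords``);
    off-tissue pixels carry no signal and are excluded from all statistics.
    """

    patient_id: str
    section_id: str
    coords: np.ndarray            # (n_pixels, 2) integer (row, col)
    intensities: np.ndarray       # (n_pixels, n_peaks) nonnegative
    grid_shape: tuple[int, int]
    pixel_size_um: float = 45.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape[0] != self.coords.shape[0]:
            raise ValueError("intensity rows must match pixel coordinates")
        if self.intensities.size and self.intensities.min() < 0:
            raise ValueError("negative intensities are not a valid MSI state")

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    @property
    def tissue_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=bool)
        mask[self.coords[:, 0], self.coords[:, 1]] = True
        return mask

    def image(self, peak_index: int, fill: float = 0.0) -> np.ndarray:
        """Render one peak's intensities onto the full grid."""
        img = np.full(self.grid_shape, fill, dtype=float)
        img[self.coords[:, 0], self.coords[:, 1]] = self.intensities[:, peak_index]
        return img


@dataclass
class Study:
    """All sections of a study on a shared axis, plus peak annotations."""

    sections: list[SectionImage]
    mz: MzAxis
    annotations: pd.DataFrame | None = None   # mz, lipid_class, adduct, carbon_count
    scale: str = "raw"                        # "raw" or "log"
    manifest: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.sections)

    def section(self, patient_id: str, section_id: str) -> SectionImage:
        for s in self.sections:
            if s.patient_id == patient_id and s.section_id == section_id:
                return s
        raise KeyError(f"no section {patient_id}/{section_id}")

    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sections:
            seen.setdefault(s.patient_id, None)
        return list(seen)


@dataclass
class PeakTable:
    """Per-peak annotation table.

    ``df`` is indexed by position on the study axis, with columns
    mz, lipid_class, adduct, carbon_count, is_isotope, presence_fraction.
    """

    df: pd.DataFrame

    def __post_init__(self):
        frac = self.df["presence_fraction"]
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("presence_fraction must lie in [0, 1]")

    @property
    def indices(self) -> np.ndarray:
        return self.df.index.to_numpy()

    @property
    def mz(self) -> np.ndarray:
        return self.df["mz"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# study I/O
# ---------------------------------------------------------------------------

def _cluster_axis(per_section_mz: list[np.ndarray], tol: float) -> np.ndarray:
    """Greedy tolerance clustering of all sections' m/z values.

    Returns the global axis (cluster means). Peaks of different sections
    within ``tol`` of each other collapse onto one axis entry.
    """
    allmz = np.sort(np.concatenate(per_section_mz))
    groups: list[list[float]] = []
    for v in allmz:
        if groups and v - groups[-1][-1] <= tol:
            groups[-1].append(v)
        else:
            groups.append([v])
    return np.array([float(np.mean(g)) for g in groups])


def read_study(manifest_path: str | Path, tolerance: float = DEFAULT_MZ_TOL) -> Study:
    """Load a study from its manifest (CSV: patient_id, section_id, imzml, ...).

    All sections are aligned onto one m/z axis by tolerance-based matching;
    sections missing a peak get zero intensity there (peak "not measured").
    """
    from pyimzml.ImzMLParser import ImzMLParser

    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    for col in ("imzml", "mask", "landmarks_hist", "landmarks_msi"):
        if col in manifest.columns:
            manifest[col] = [str(manifest_path.parent / p) for p in manifest[col]]
    if manifest.empty:
        warnings.warn("empty study manifest: returning an empty study")
        return Study([], MzAxis(np.array([]), tolerance), manifest=manifest)

    root = manifest_path.parent
    raw: list[tuple[str, str, np.ndarray, np.ndarray, np.ndarray, tuple[int, int]]] = []
    for rec in manifest.itertuples():
        path = root / rec.imzml
        try:
            parser = ImzMLParser(str(path))
            nx = parser.imzmldict["max count of pixels x"]
            ny = parser.imzmldict["max count of pixels y"]
            coords, spectra = [], []
            mz0 = None
            for i, (x, y, _z) in enumerate(parser.coordinates):
                mzs, ints = parser.getspectrum(i)
                if mz0 is None:
                    mz0 = np.asarray(mzs, dtype=float)
                coords.append((y - 1, x - 1))     # imzML coordinates are 1-based
                spectra.append(ints)
            if mz0 is None:
                raise StudyFormatError("section contains no spectra")
        except Exception as exc:
            raise StudyFormatError(
                f"cannot read section {rec.patient_id}/{rec.section_id} ({path}): {exc}"
            ) from exc
        raw.append((str(rec.patient_id), str(rec.section_id), mz0,
                    np.asarray(coords, dtype=int),
                    np.asarray(spectra, dtype=float), (ny, nx)))

    axis = _cluster_axis([r[2] for r in raw], tolerance)
    sections = []
    for patient_id, section_id, mz0, coords, spectra, shape in raw:
        idx = np.searchsorted(axis, mz0)
        idx = np.clip(idx, 0, len(axis) - 1)
        left_ok = idx > 0
        better_left = left_ok & (np.abs(mz0 - axis[np.maximum(idx - 1, 0)])
                                 < np.abs(mz0 - axis[idx]))
        idx[better_left] -= 1
        if np.any(np.abs(axis[idx] - mz0) > tolerance):
            raise StudyFormatError(
                f"section {patient_id}/{section_id}: m/z axis irreconcilable "
                f"within {tolerance} Da")
        if len(np.unique(idx)) != len(idx):
            raise StudyFormatError(
                f"section {patient_id}/{section_id}: two peaks collapse onto "
                "one axis entry — tolerance too wide for this axis")
        full = np.zeros((spectra.shape[0], len(axis)))
        full[:, idx] = spectra
        sections.append(SectionImage(patient_id, section_id, coords, full, shape))

    annotations = None
    panel_path = root / "panel.csv"
    if panel_path.exists():
        annotations = pd.read_csv(panel_path)
    return Study(sections, MzAxis(axis, tolerance), annotations=annotations,
                 manifest=manifest)


def save_study(study: Study, path: str | Path) -> None:
    """Persist a (preprocessed) study to one hierarchical HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["scale"] = study.scale
        f.create_dataset("mz", data=study.mz.values)
        f.attrs["tolerance"] = study.mz.tolerance
        for s in study.sections:
            g = f.create_group(f"sections/{s.patient_id}/{s.section_id}")
            g.create_dataset("coords", data=s.coords)
            g.create_dataset("intensities", data=s.intensities)
            g.attrs["grid_shape"] = s.grid_shape
            g.attrs["pixel_size_um"] = s.pixel_size_um
        if study.annotations is not None:
            cols = f.create_group("annotations")
            for c in study.annotations.columns:
                data = study.annotations[c].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                cols.create_dataset(c, data=data)


def load_study(path: str | Path) -> Study:
    import h5py

    with h5py.File(path, "r") as f:
        axis = MzAxis(f["mz"][...], float(f.attrs["tolerance"]))
        sections = []
        for pid in sorted(f["sections"]):
            for sid in sorted(f[f"sections/{pid}"]):
                g = f[f"sections/{pid}/{sid}"]
                sections.append(SectionImage(
                    pid, sid, g["coords"][...], g["intensities"][...],
                    tuple(int(v) for v in g.attrs["grid_shape"]),
                    float(g.attrs["pixel_size_um"])))
        annotations = None
        if "annotations" in f:
            cols = {}
            for c in f["annotations"]:
                data = f["annotations"][c][...]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[c] = data
            annotations = pd.DataFrame(cols)
        return Study(sections, axis, annotations=annotations,
                     scale=str(f.attrs["scale"]))


# ---------------------------------------------------------------------------
# peak selection and deisotoping
# ---------------------------------------------------------------------------

def _annotate(axis: MzAxis, annotations: pd.DataFrame | None) -> pd.DataFrame:
    """Join panel annotations onto the axis by m/z within tolerance."""
    n = len(axis)
    out = pd.DataFrame({
        "mz": axis.values,
        "lipid_class": ["unknown"] * n,
        "adduct": [""] * n,
        "carbon_count": np.zeros(n, dtype=int),
    })
    if annotations is not None and len(annotations):
        ann_mz = annotations["mz"].to_numpy(dtype=float)
        for i, mz in enumerate(axis.values):
            j = int(np.argmin(np.abs(ann_mz - mz)))
            if abs(ann_mz[j] - mz) <= axis.tolerance:
                row = annotations.iloc[j]
                out.loc[i, "lipid_class"] = str(row.get("lipid_class", "unknown"))
                out.loc[i, "adduct"] = str(row.get("adduct", ""))
                if "carbon_count" in annotations.columns:
                    out.loc[i, "carbon_count"] = int(row["carbon_count"])
    return out


def select_common_peaks(study: Study, min_fraction: float = 0.30,
                        pixel_quorum: float = PRESENCE_PIXEL_QUORUM) -> PeakTable:
    """Keep peaks measured in *more than* ``min_fraction`` of all sections.

    A peak counts as measured in a section when it is nonzero in at least
    ``pixel_quorum`` of that section's tissue pixels (minimum one pixel).
    The threshold is a strict inequality: at the study scale of 106 sections,
    32/106 ≈ 0.302 is kept and 31/106 ≈ 0.292 is dropped.
    """
    if not study.sections:
        raise ValueError("cannot select peaks from an empty study")
    n_measured = np.zeros(len(study.mz), dtype=int)
    for s in study.sections:
        quorum = max(1, int(np.ceil(pixel_quorum * s.n_pixels)))
        n_measured += (np.count_nonzero(s.intensities > 0, axis=0) >= quorum)
    fraction = n_measured / len(study.sections)

    table = _annotate(study.mz, study.annotations)
    table["is_isotope"] = False
    table["presence_fraction"] = fraction
    keep = fraction > min_fraction
    return PeakTable(table.loc[keep].copy())


#: characteristic adduct mass gaps (Na−H, K−H, K−Na), never treated as isotopes
ADDUCT_GAPS = (21.98194, 37.95588, 15.97394)


def remove_isotopes(peaktable: PeakTable, study: Study,
                    delta: float = ISOTOPE_DELTA, tol: float = DEFAULT_MZ_TOL,
                    ratio_ceiling: float = ISOTOPE_RATIO_CEILING) -> PeakTable:
    """Drop first-isotopologue satellites; keep adducts of the same molecule.

    Peak B is flagged as an isotope when a lighter peak A sits at
    mz(B) − ``delta`` within ``tol`` *and* the median intensity ratio B/A over
    co-detected pixels stays below ``ratio_ceiling``: a first 13C satellite of
    a lipid (< 90 carbons) is always weaker than that, while a genuine peak
    one Dalton up is not. Peaks with no lighter partner are never removed.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    df = peaktable.df.copy()
    mz = df["mz"].to_numpy()
    pooled = np.vstack([s.intensities[:, df.index.to_numpy()] for s in study.sections])

    flagged = np.zeros(len(df), dtype=bool)
    for b in range(len(df)):
        gaps = mz[b] - mz
        cand = np.nonzero(np.abs(gaps - delta) <= tol)[0]
        for a in cand:
            both = (pooled[:, a] > 0) & (pooled[:, b] > 0)
            if not both.any():
                continue
            ratio = float(np.median(pooled[both, b] / pooled[both, a]))
            if ratio < ratio_ceiling:
                flagged[b] = True
                break
    df["is_isotope"] = flagged
    logger.info("deisotoping removed %d of %d peaks", int(flagged.sum()), len(df))
    return PeakTable(df.loc[~flagged].copy())


def preprocess_study(study: Study, min_fraction: float = 0.30,
                     tol: float = DEFAULT_MZ_TOL) -> tuple[Study, PeakTable]:
    """Presence filter + deisotoping; returns the reduced raw-scale study."""
    peaks = select_common_peaks(study, min_fraction=min_fraction)
    peaks = remove_isotopes(peaks, study, tol=tol)
    return subset_study(study, peaks), reindex_peaktable(peaks)


def subset_study(study: Study, peaks: PeakTable) -> Study:
    """Restrict a study to the peaks retained in ``peaks``."""
    idx = peaks.indices
    sections = [replace(s, intensities=s.intensities[:, idx]) for s in study.sections]
    axis = MzAxis(study.mz.values[idx], study.mz.tolerance)
    return Study(sections, axis, annotations=study.annotations,
                 scale=study.scale, manifest=study.manifest)


def reindex_peaktable(peaks: PeakTable) -> PeakTable:
    """Renumber a peak table to positions on the subset axis."""
    return PeakTable(peaks.df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# transforms for statistics and display
# ---------------------------------------------------------------------------

def log_transform(study: Study) -> Study:
    """ln(1 + x) view for statistics; the raw study is left untouched."""
    if study.scale == "log":
        return study
    sections = []
    for s in study.sections:
        if s.intensities.size and s.intensities.min() < 0:
            raise ValueError("negative intensities: not a raw-scale study")
        sections.append(replace(s, intensities=np.log1p(s.intensities)))
    return Study(sections, study.mz, annotations=study.annotations,
                 scale="log", manifest=study.manifest)


def normalize_image_per_mz(section: SectionImage, peak_index: int,
                           percentile: float = 99.0) -> np.ndarray:
    """Display image of one peak scaled to [0, 1] per m/z value.

    The ceiling is the 99th-percentile tissue intensity (robust to hot
    pixels); values above it clip to 1. An all-zero image stays all-zero.
    """
    values = section.intensities[:, peak_index]
    ceiling = float(np.percentile(values, percentile)) if values.size else 0.0
    img = np.zeros(section.grid_shape, dtype=float)
    if ceiling <= 0:
        nz = values > 0
        if nz.any():   # degenerate: nearly-all-zero image, scale by its max
            ceiling = float(values.max())
        else:
            return img
    img[section.coords[:, 0], section.coords[:, 1]] = np.clip(values / ceiling, 0, 1)
    return img
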