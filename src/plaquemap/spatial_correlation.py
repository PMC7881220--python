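"""Spatial cross-correlation of lipid images.

For each tissue section the Pearson correlation of every pair of lipid
images is computed over tissue pixels, and the per-section matrices are
averaged across the study. Displayed class-sorted, the average matrix shows
the block structure of lipid classes sharing spatial patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msi_data import CLASS_ORDER, PeakTable, SectionImage, Study


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over peaks, with per-cell averaging counts.

    Cells where either peak is constant in a section are undefined (NaN),
    not zero; ``n_sections`` records how many sections defined each cell.
    """

    mz: np.ndarray
    lipid_class: np.ndarray
    values: np.ndarray
    n_sections: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(v[finite]) > 1 + 1e-10):
            raise ValueError("|r| must not exceed 1")


def section_correlation(section: SectionImage, peaks: PeakTable | np.ndarray) -> CorrelationMatrix:
    """Pearson correlation of peak images over one section's tissue pixels."""
    idx, mz, classes = _resolve_peaks(section, peaks)
    X = section.intensities[:, idx]
    if X.shape[0] < 2:
        raise ValueError("Pearson correlation needs at least two tissue pixels")
    sd = X.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))
    r = np.clip(r, -1.0, 1.0)
    counts = np.where(np.isfinite(r), 1, 0)
    return CorrelationMatrix(mz, classes, r, counts)


def average_correlation(study: Study, peaks: PeakTable | np.ndarray) -> CorrelationMatrix:
    """Arithmetic per-cell mean of section matrices, over sections where the
    cell is defined."""
    if not study.sections:
        raise ValueError("cannot average correlations of an empty study")
    total = count = mz = classes = None
    for section in study.sections:
        m = section_correlation(section, peaks)
        if total is None:
            mz, classes = m.mz, m.lipid_class
            total = np.zeros_like(m.values)
            count = np.zeros(m.values.shape, dtype=int)
        defined = np.isfinite(m.values)
        total[defined] += m.values[defined]
        count += defined
    with np.errstate(invalid="ignore"):
        avg = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return CorrelationMatrix(mz, classes, avg, count)


def order_by_class(matrix: CorrelationMatrix,
                   peaktable: PeakTable | None = None) -> CorrelationMatrix:
    """Permute rows/cols into lipid-class blocks, ascending m/z within each.

    Block order is fixed (Chol, oxChol, CE, oxCE, LPC, PC, SM, DG, TG);
    unannotated peaks group last.
    """
    classes = matrix.lipid_class
    if peaktable is not None:
        classes = peaktable.df["lipid_class"].to_numpy()
    rank = {c: i for i, c in enumerate(CLASS_ORDER)}
    order = np.lexsort((matrix.mz, [rank.get(c, len(rank)) for c in classes]))
    return CorrelationMatrix(
        matrix.mz[order], np.asarray(classes)[order],
        matrix.values[np.ix_(order, order)], matrix.n_sections[np.ix_(order, order)])


def class_block_means(matrix: CorrelationMatrix) -> tuple[dict[str, float], float]:
    """Mean within-class correlation per class, and the between-class mean.

    Diagonal cells are excluded. Used to verify that lipids of one class
    share spatial patterns more than lipids of different classes do."""
    values = matrix.values.copy()
    np.fill_diagonal(values, np.nan)
    classes = np.asarray(matrix.lipid_class)
    within: dict[str, float] = {}
    for c in np.unique(classes):
        sel = classes == c
        if sel.sum() < 2:
            continue
        block = values[np.ix_(sel, sel)]
        if np.isfinite(block).any():
            within[c] = float(np.nanmean(block))
    between_mask = classes[:, None] != classes[None, :]
    between = float(np.nanmean(values[between_mask])) if between_mask.any() else np.nan
    return within, between


def export_heatmap(matrix: CorrelationMatrix, image_path=None, table_path=None):
    """Write the class-sorted heatmap as an image and/or a CSV table."""
    import pandas as pd

    labels = [f"{c}:{mz:.3f}" for c, mz in zip(matrix.lipid_class, matrix.mz)]
    if table_path is not None:
        pd.DataFrame(matrix.values, index=labels, columns=labels).to_csv(table_path)
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=4)
        ax.set_yticks(range(len(labels)), labels, fontsize=4)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        fig.savefig(image_path, dpi=200)
        plt.close(fig)


def _resolve_peaks(section: SectionImage, peaks):
    if isinstance(peaks, PeakTable):
        return (peaks.indices, peaks.mz, peaks.df["lipid_class"].to_numpy())
    idx = np.asarray(peaks, dtype=int)
    return idx, idx.astype(float), np.array(["unknown"] * len(idx))
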