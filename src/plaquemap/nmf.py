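"""Unsupervised NMF segmentation of pooled MSI data.

The pixel × peak matrix of all sections is factored as X ≈ W·H with
W, H ≥ 0: rows of H are component spectra, columns of W render as spatial
weight images per section. The component count is chosen by consensus
clustering over random restarts — pixels are hard-assigned to their argmax
component, co-clustering fractions across restarts form a consensus matrix,
and its dispersion coefficient ρ = (1/n²)·Σᵢⱼ 4(Cᵢⱼ − ½)² (1 for perfectly
stable partitions) is maximized over candidate ranks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .msi_data import SectionImage, Study

logger = logging.getLogger("plaquemap")

_EPS = 1e-12


@dataclass
class PooledMatrix:
    """Stacked tissue-pixel matrix over sections, with section offsets.

    Peaks are scaled to unit 99th percentile before pooling so that
    high-abundance lipid classes do not dominate the factorization.
    """

    X: np.ndarray
    section_ids: list[tuple[str, str]]
    offsets: list[int]                      # start row per section, + end
    grids: dict[tuple[str, str], tuple[np.ndarray, tuple[int, int]]]
    peak_scale: np.ndarray

    def rows_of(self, patient_id: str, section_id: str) -> slice:
        key = (patient_id, section_id)
        i = self.section_ids.index(key)
        return slice(self.offsets[i], self.offsets[i + 1])


def pool_study(study: Study, peak_indices=None, scale_percentile: float = 99.0) -> PooledMatrix:
    """Stack all sections' tissue pixels into one nonnegative matrix."""
    blocks, ids, offsets, grids = [], [], [0], {}
    for s in study.sections:
        X = s.intensities if peak_indices is None else s.intensities[:, peak_indices]
        blocks.append(X)
        ids.append((s.patient_id, s.section_id))
        offsets.append(offsets[-1] + X.shape[0])
        grids[(s.patient_id, s.section_id)] = (s.coords, s.grid_shape)
    X = np.vstack(blocks)
    scale = np.percentile(X, scale_percentile, axis=0)
    scale[scale <= 0] = 1.0
    return PooledMatrix(X / scale, ids, offsets, grids, scale)


@dataclass
class NMFModel:
    """Nonnegative factorization X ≈ W·H with fit diagnostics."""

    W: np.ndarray
    H: np.ndarray
    k: int
    reconstruction_error: float
    error_trace: np.ndarray
    seed: int
    n_iter: int
    pool: PooledMatrix | None = None


@dataclass
class RankSelection:
    """Consensus-dispersion curve over candidate ranks."""

    k_range: list[int]
    dispersion: list[float]
    chosen_k: int

    def __post_init__(self):
        if any(not -1e-9 <= d <= 1 + 1e-9 for d in self.dispersion):
            raise ValueError("dispersion coefficients must lie in [0, 1]")
        if self.chosen_k not in self.k_range:
            raise ValueError("chosen rank must come from the candidate range")


def fit_nmf(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 300,
            tol: float = 1e-5, pool: PooledMatrix | None = None) -> NMFModel:
    """Multiplicative-update Frobenius NMF, deterministic per seed.

    Runs until the relative change of ‖X − WH‖_F drops below ``tol`` or
    ``max_iter`` is reached. The objective is checked for monotone descent
    every 10 iterations (a violated check indicates a numerical fault).
    """
    X = np.asarray(X, dtype=float)
    if X.min() < 0:
        raise ValueError("NMF requires a nonnegative matrix")
    n, p = X.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"rank must lie in [1, {min(n, p)}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k) + _EPS
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, p)) * scale

    norm_x = np.linalg.norm(X)
    errors = []
    prev = np.inf
    for it in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(X - W @ H))
        errors.append(err)
        if it % 10 == 0 and err > errors[-2] * (1 + 1e-9):
            warnings.warn("NMF objective increased: numerical instability")
        if prev - err < tol * max(norm_x, 1.0) and it > 10:
            break
        prev = err
    # canonical scaling: H rows to unit L2 norm, W takes the magnitude, so
    # that component weights are comparable (argmax W is otherwise undefined
    # up to the W/H scale indeterminacy)
    norms = np.linalg.norm(H, axis=1)
    norms[norms <= 0] = 1.0
    H = H / norms[:, None]
    W = W * norms[None, :]
    return NMFModel(W, H, k, errors[-1], np.asarray(errors), seed, len(errors), pool)


def consensus_dispersion(X: np.ndarray, k: int, n_runs: int = 30,
                         subsample: int = 2000, seed: int = 0,
                         max_iter: int = 200) -> float:
    """Dispersion of the consensus matrix over NMF restarts.

    A fixed random pixel subsample is factored ``n_runs`` times from
    different initializations; each subsampled pixel is assigned to its
    argmax component and C_ij is the fraction of runs co-clustering pixels
    i and j. ρ = (1/n²)·Σ 4(C_ij − ½)² is 1 for perfectly reproducible
    partitions and tends to the diagonal contribution 1/n for coin-flip
    consensus.
    """
    if n_runs < 2:
        raise ValueError("consensus needs at least two runs")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if subsample > n:
        warnings.warn(f"subsample {subsample} exceeds {n} pixels: clamped")
        subsample = n
    idx = rng.choice(n, size=subsample, replace=False)
    Xs = X[idx]
    C = np.zeros((subsample, subsample))
    for run in range(n_runs):
        model = fit_nmf(Xs, k, seed=int(rng.integers(2**31)), max_iter=max_iter)
        labels = np.argmax(model.W, axis=1)
        C += labels[:, None] == labels[None, :]
    C /= n_runs
    return dispersion_coefficient(C)


def dispersion_coefficient(C: np.ndarray) -> float:
    """ρ = (1/n²)·Σᵢⱼ 4(Cᵢⱼ − ½)² for a consensus matrix C ∈ [0,1]ⁿˣⁿ."""
    n = C.shape[0]
    return float(np.sum(4.0 * (C - 0.5) ** 2) / (n * n))


def select_rank(X: np.ndarray, k_range=range(2, 11), n_runs: int = 30,
                seed: int = 0, subsample: int = 2000,
                max_iter: int = 200) -> RankSelection:
    """Choose the rank maximizing consensus dispersion; ties go to smaller k."""
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be nonempty")
    disp = [consensus_dispersion(X, k, n_runs=n_runs, subsample=subsample,
                                 seed=seed, max_iter=max_iter) for k in ks]
    chosen = ks[int(np.argmax(disp))]   # argmax returns the first (smallest) max
    logger.info("rank selection: %s -> k=%d", dict(zip(ks, np.round(disp, 3))), chosen)
    return RankSelection(ks, disp, chosen)


def component_images(model: NMFModel, patient_id: str, section_id: str) -> np.ndarray:
    """Per-component weight images of one section, scaled to [0, 1].

    Returns an array (k, rows, cols); off-tissue pixels are NaN.
    """
    if model.pool is None:
        raise KeyError("model was not fit on a pooled study matrix")
    rows = model.pool.rows_of(patient_id, section_id)
    coords, grid_shape = model.pool.grids[(patient_id, section_id)]
    W = model.W[rows]
    peaks = W.max(axis=0)
    peaks[peaks <= 0] = 1.0
    W = W / peaks
    out = np.full((model.k,) + grid_shape, np.nan)
    out[:, coords[:, 0], coords[:, 1]] = W.T
    return out


def component_threshold_mz(H: np.ndarray, factor: float = 0.4) -> list[np.ndarray]:
    """Peaks above ``factor`` × the max-normalized weight of each component.

    Each component spectrum is scaled to maximum 1; the returned sets hold
    the peak indices with scaled weight strictly above the cutoff.
    """
    H = np.asarray(H, dtype=float)
    sets = []
    for row in H:
        peak = row.max()
        if peak <= 0:
            warnings.warn("all-zero NMF component: empty m/z set")
            sets.append(np.array([], dtype=int))
            continue
        sets.append(np.nonzero(row / peak > factor)[0])
    return sets


def match_components_to_labels(model: NMFModel, truth_masks: dict,
                               labels: tuple[str, ...]) -> dict[str, int]:
    """Map each histology label to the component with the highest mean
    weight ratio inside/outside that label's region (recovery diagnostics)."""
    from .registration import LABEL_CODES

    scores = {label: np.zeros(model.k) for label in labels}
    for (pid, sid), mask in truth_masks.items():
        if (pid, sid) not in model.pool.grids:
            continue
        coords, _shape = model.pool.grids[(pid, sid)]
        W = model.W[model.pool.rows_of(pid, sid)]
        at = mask.labels[coords[:, 0], coords[:, 1]]
        for label in labels:
            inside = at == LABEL_CODES[label]
            if inside.sum() < 5 or (~inside).sum() < 5:
                continue
            ratio = W[inside].mean(axis=0) / (W[~inside].mean(axis=0) + _EPS)
            scores[label] += ratio
    return {label: int(np.argmax(s)) for label, s in scores.items()}
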