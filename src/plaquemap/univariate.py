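"""Univariate confirmation of discriminative peaks.

Each VIP-selected peak is tested on raw (non-log) intensities: per tissue
section containing the target component, the mean pixel intensity inside
the component region is paired with the mean over all other tissue pixels.
The paired section means feed a Wilcoxon signed-rank test (p ≤ 0.05
significant), and an ROC over the two groups of section means yields the
AUC and the optimal cutoff intensity at the maximum of Youden's index
J = sensitivity + specificity − 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .msi_data import SectionImage, Study
from .registration import LABEL_CODES, SegmentationMask

logger = logging.getLogger("plaquemap")


# ---------------------------------------------------------------------------
# paired section means
# ---------------------------------------------------------------------------

@dataclass
class PairedIntensities:
    """Per-section raw mean intensities inside vs outside the target label.

    Only sections containing the target label are included; sections whose
    outside mean is zero are excluded (fold change undefined).
    """

    label: str
    patient_id: np.ndarray
    section_id: np.ndarray
    mean_in: np.ndarray
    mean_out: np.ndarray
    area_px: np.ndarray           # label area per section, pixels

    @property
    def fold_change(self) -> np.ndarray:
        return self.mean_in / self.mean_out

    def __len__(self) -> int:
        return len(self.mean_in)


def paired_means(study: Study, masks: dict[tuple[str, str], SegmentationMask],
                 label: str, peak_index: int) -> PairedIntensities:
    """Raw in/out mean intensities of one peak for every section with the label."""
    if study.scale != "raw":
        raise ValueError("fold changes are defined on raw (non-log) intensities")
    pids, sids, m_in, m_out, areas = [], [], [], [], []
    for s in study.sections:
        mask = masks.get((s.patient_id, s.section_id))
        if mask is None:
            continue
        at = mask.labels[s.coords[:, 0], s.coords[:, 1]]
        inside = at == LABEL_CODES[label]
        outside = (at != LABEL_CODES[label]) & (at != LABEL_CODES["background"])
        if not inside.any() or not outside.any():
            continue
        mo = float(s.intensities[outside, peak_index].mean())
        if mo == 0:
            logger.info("section %s/%s excluded: zero outside mean",
                        s.patient_id, s.section_id)
            continue
        pids.append(s.patient_id); sids.append(s.section_id)
        m_in.append(float(s.intensities[inside, peak_index].mean()))
        m_out.append(mo)
        areas.append(int(inside.sum()))
    if not m_in:
        logger.warning("no section contains label %r", label)
    return PairedIntensities(label, np.array(pids), np.array(sids),
                             np.array(m_in), np.array(m_out), np.array(areas))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    statistic: float              # W+ (sum of positive ranks)
    p_value: float
    n: int                        # non-zero differences used
    underpowered: bool            # n < 5: p-value carries little meaning


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> tuple[float, float]:
    """Exact null CDF/SF of W+ by dynamic programming over sign patterns.

    ``ranks2`` are the (possibly midrank) ranks doubled to integers; the
    distribution over all 2ⁿ equally likely sign assignments is built by
    convolution. Returns (P(W+ ≤ w), P(W+ ≥ w)).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2i = int(round(w2))
    return float(counts[:w2i + 1].sum()), float(counts[w2i:].sum())


def wilcoxon_signed_rank(values_in: np.ndarray,
                         values_out: np.ndarray | None = None) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired values (or differences).

    Zero differences are dropped (Wilcoxon convention), ties are midranked.
    The null distribution is enumerated exactly for n ≤ 25 and approximated
    normally (with continuity and tie correction) above. With fewer than 5
    non-zero differences the result is flagged underpowered.
    """
    d = np.asarray(values_in, dtype=float)
    if values_out is not None:
        d = d - np.asarray(values_out, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, True)
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        cdf, sf = _signed_rank_exact_p(ranks * 2, w_pos * 2)
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mu = n * (n + 1) / 4.0
        _uniq, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / sigma if sigma > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
        p = min(1.0, p)
    return WilcoxonResult(w_pos, p, n, n < 5)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    cutoff: float
    youden_j: float

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")
        if not -1 - 1e-12 <= self.youden_j <= 1 + 1e-12:
            raise ValueError("Youden's J must lie in [-1, 1]")


def roc_youden(values_in: np.ndarray, values_out: np.ndarray) -> RocResult:
    """ROC AUC and the optimal cutoff at maximum Youden's index.

    The in-group counts as positive and scores *above* the cutoff; candidate
    cutoffs are the midpoints between adjacent sorted unique pooled values
    (ties in J resolve to the lowest cutoff). AUC comes from the rank
    (Mann–Whitney) statistic with midrank tie handling.
    """
    x_in = np.asarray(values_in, dtype=float)
    x_out = np.asarray(values_out, dtype=float)
    if len(x_in) == 0 or len(x_out) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x_in, x_out])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:len(x_in)].sum()) - len(x_in) * (len(x_in) + 1) / 2.0
    auc = u / (len(x_in) * len(x_out))

    uniq = np.unique(pooled)
    if len(uniq) == 1:
        return RocResult(0.5, float(uniq[0]), 0.0)
    cutoffs = (uniq[:-1] + uniq[1:]) / 2.0
    best_j, best_c = -np.inf, cutoffs[0]
    for c in cutoffs:
        sens = float((x_in > c).mean())
        spec = float((x_out <= c).mean())
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, float(c)
    return RocResult(float(auc), best_c, float(best_j))


# ---------------------------------------------------------------------------
# VIP confirmation table
# ---------------------------------------------------------------------------

def confirm_vips(study: Study, masks: dict, label: str,
                 vip_peaks: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Univariate test of every VIP-selected peak against a component label.

    Returns one row per peak: median non-log fold change, Wilcoxon W and p,
    significance at ``alpha``, ROC AUC, Youden cutoff and J, plus the
    Spearman correlation of per-section fold change with label area (the
    size-trend diagnostic: contrasts sharpen as the component area grows).
    """
    vip_peaks = np.asarray(vip_peaks, dtype=int)
    if vip_peaks.size == 0:
        raise ValueError("VIP set is empty: nothing to confirm")
    rows = []
    for peak in vip_peaks:
        pairs = paired_means(study, masks, label, int(peak))
        if len(pairs) == 0:
            rows.append(dict(peak=int(peak), mz=float(study.mz.values[peak]),
                             n_sections=0, fold_change=np.nan, wilcoxon_w=np.nan,
                             p_value=np.nan, significant=False, auc=np.nan,
                             youden_cutoff=np.nan, youden_j=np.nan,
                             area_trend_rho=np.nan))
            continue
        wil = wilcoxon_signed_rank(pairs.mean_in, pairs.mean_out)
        roc = roc_youden(pairs.mean_in, pairs.mean_out)
        if len(pairs) >= 3 and np.ptp(pairs.area_px) > 0:
            rho = float(stats.spearmanr(pairs.fold_change, pairs.area_px).statistic)
        else:
            rho = np.nan
        rows.append(dict(
            peak=int(peak), mz=float(study.mz.values[peak]),
            n_sections=len(pairs), fold_change=float(np.median(pairs.fold_change)),
            wilcoxon_w=wil.statistic, p_value=wil.p_value,
            significant=bool(wil.p_value <= alpha and not wil.underpowered),
            auc=roc.auc, youden_cutoff=roc.cutoff, youden_j=roc.youden_j,
            area_trend_rho=rho))
    return pd.DataFrame(rows)
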