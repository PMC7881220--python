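"""Two-class OPLS-DA with VIP extraction and model validation.

Orthogonal projections to latent structures discriminant analysis splits
predictor variation into a part predictive of the class contrast and parts
orthogonal to it (Trygg–Wold deflation). Here it discriminates the mean
spectrum of one histological plaque component from the mean spectrum of the
rest of the tissue, per section: observations are (section, region) mean
log-spectra, variables are the retained m/z values.

Model quality is reported as R²Y (fit) and Q² (sevenfold cross-validated
predictability); significance by cross-validation ANOVA and by permutation
of the class labels. A component's study-level model is *accepted* when the
per-patient models are significant (R² > 0.5, Q² > 0.5, CV-ANOVA p < 0.05)
for at least half of the patients, and its discriminative m/z set is the
peaks with median VIP > 1.0 across the significant patient models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .registration import ComponentSpectra, component_mean_spectra

logger = logging.getLogger("plaquemap")

_EPS = 1e-12


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantDataset:
    """Observations × peaks matrix with ±1 class coding and patient ids."""

    X: np.ndarray
    y: np.ndarray                 # +1 target component, −1 rest of tissue
    patient_id: np.ndarray
    section_id: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not np.isfinite(self.X).all():
            raise ValueError("discriminant matrix must be finite")
        if set(np.unique(self.y)) - {-1.0, 1.0}:
            raise ValueError("class labels must be coded ±1")

    def subset(self, rows) -> "DiscriminantDataset":
        rows = np.asarray(rows)
        return DiscriminantDataset(self.X[rows], self.y[rows],
                                   self.patient_id[rows], self.section_id[rows])


def build_discriminant_dataset(spectra: list[ComponentSpectra],
                               component_label: str) -> DiscriminantDataset:
    """Stack component-vs-rest mean spectra into a two-class dataset."""
    X, y, pids, sids = [], [], [], []
    for cs in spectra:
        if component_label not in cs.mean_in:
            continue
        X.append(cs.mean_in[component_label]); y.append(1.0)
        X.append(cs.mean_rest[component_label]); y.append(-1.0)
        pids.extend([cs.patient_id] * 2)
        sids.extend([cs.section_id] * 2)
    if not X:
        raise ValueError(f"no section carries component {component_label!r}")
    return DiscriminantDataset(np.vstack(X), np.array(y),
                               np.array(pids), np.array(sids))


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class OPLSDAModel:
    """Fitted two-class OPLS-DA model (predictive + orthogonal parts)."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    kept: np.ndarray              # columns retained (non-constant)
    y_mean: float
    w: np.ndarray                 # predictive weights, ‖w‖ = 1
    p: np.ndarray                 # predictive loadings
    q: float                      # y loading of the predictive score
    t: np.ndarray                 # predictive scores (training)
    W_ortho: np.ndarray           # (n_ortho, p) orthogonal weights
    P_ortho: np.ndarray
    T_ortho: np.ndarray           # (n, n_ortho)
    n_ortho: int
    r2x: float
    r2y: float
    q2: float
    press: float
    ss_y: float
    n_obs: int
    folds: int
    vip: np.ndarray = field(default=None)
    cvanova_p: float | None = None
    perm_p: float | None = None


def _uv_scale(X: np.ndarray, scaling: str = "uv"):
    """Center and scale; constant columns are dropped with a warning."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    kept = sd > 1e-12
    if not kept.all():
        warnings.warn(f"dropped {np.count_nonzero(~kept)} constant variable(s)")
    if scaling == "uv":
        scale = sd
    elif scaling == "pareto":
        scale = np.sqrt(sd)
    elif scaling == "center":
        scale = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    scale = np.where(kept, scale, 1.0)
    return (X[:, kept] - mean[kept]) / scale[kept], mean, scale, kept


def _fit_core(Xc: np.ndarray, yc: np.ndarray, n_ortho: int):
    """Trygg–Wold OPLS core on preprocessed data."""
    W_o, P_o, T_o = [], [], []
    Xd = Xc.copy()
    for _ in range(n_ortho):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t + _EPS)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-10:
            break                      # no orthogonal variation left
        w_o /= n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o + _EPS)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o); P_o.append(p_o); T_o.append(t_o)
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    w = w / nw if nw > _EPS else w
    t = Xd @ w
    p = Xd.T @ t / (t @ t + _EPS)
    q = float(yc @ t / (t @ t + _EPS))
    n_fit = len(W_o)
    W_o = np.vstack(W_o) if W_o else np.zeros((0, Xc.shape[1]))
    P_o = np.vstack(P_o) if P_o else np.zeros((0, Xc.shape[1]))
    T_o = np.column_stack(T_o) if n_fit else np.zeros((Xc.shape[0], 0))
    return w, p, q, t, W_o, P_o, T_o


def _predict_core(Xc, w, q, W_o, P_o):
    Xd = np.atleast_2d(Xc).copy()
    for w_o, p_o in zip(W_o, P_o):
        t_o = Xd @ w_o
        Xd = Xd - np.outer(t_o, p_o)
    return (Xd @ w) * q


def predict(model: OPLSDAModel, X: np.ndarray) -> np.ndarray:
    """Continuous class prediction on the ±1 scale for new observations."""
    Xc = (np.atleast_2d(X)[:, model.kept] - model.x_mean[model.kept]) / model.x_scale[model.kept]
    return _predict_core(Xc, model.w, model.q, model.W_ortho, model.P_ortho) + model.y_mean


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    if folds > len(y):
        warnings.warn(f"{folds} folds exceed {len(y)} observations: reduced")
        folds = len(y)
    assignment = [[] for _ in range(folds)]
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            assignment[i % folds].append(int(j))
    return [np.array(sorted(f)) for f in assignment if f]


def cross_validated_q2(X: np.ndarray, y: np.ndarray, folds: int = 7,
                       seed: int = 0, n_ortho: int = 0,
                       scaling: str = "uv") -> tuple[float, float, float]:
    """Sevenfold stratified CV: Q² = 1 − PRESS/SS.

    Preprocessing (centering, scaling, deflation) is re-estimated inside
    every fold. Returns (Q², PRESS, SS) with SS the total corrected sum of
    squares of the coded response.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    press = 0.0
    for test in _stratified_folds(y, folds, rng):
        train = np.setdiff1d(np.arange(len(y)), test)
        if len(np.unique(y[train])) < 2:
            continue        # fold degenerate: no contrast to train on
        Xc, x_mean, x_scale, kept = _uv_scale(X[train], scaling)
        y_mean = y[train].mean()
        yc = y[train] - y_mean
        w, p, q, t, W_o, P_o, T_o = _fit_core(Xc, yc, n_ortho)
        Xt = (X[test][:, kept] - x_mean[kept]) / x_scale[kept]
        yhat = _predict_core(Xt, w, q, W_o, P_o) + y_mean
        press += float(((y[test] - yhat) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss, press, ss


def fit_oplsda(X: np.ndarray, y: np.ndarray, n_ortho: int | str = "auto",
               max_ortho: int = 3, folds: int = 7, seed: int = 0,
               scaling: str = "uv") -> OPLSDAModel:
    """Fit an OPLS-DA model of a two-class contrast.

    X is centered and unit-variance scaled; y is coded ±1 and centered.
    With ``n_ortho="auto"`` orthogonal components are added while the
    cross-validated Q² improves by more than 0.01, up to ``max_ortho``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("OPLS-DA needs exactly two classes in y")
    if len(y) < 4:
        raise ValueError("OPLS-DA needs at least four observations")
    y = np.where(y == classes.max(), 1.0, -1.0)

    if n_ortho == "auto":
        chosen, best = 0, -np.inf
        for cand in range(0, max_ortho + 1):
            q2c, _, _ = cross_validated_q2(X, y, folds=folds, seed=seed,
                                           n_ortho=cand, scaling=scaling)
            if q2c > best + 0.01:
                chosen, best = cand, q2c
            elif cand > 0:
                break
        n_ortho = chosen

    Xc, x_mean, x_scale, kept = _uv_scale(X, scaling)
    y_mean = float(y.mean())
    yc = y - y_mean
    w, p, q, t, W_o, P_o, T_o = _fit_core(Xc, yc, int(n_ortho))

    resid_y = yc - t * q
    r2y = 1.0 - float((resid_y ** 2).sum()) / max(float((yc ** 2).sum()), _EPS)
    Xhat = np.outer(t, p) + (T_o @ P_o if T_o.size else 0.0)
    r2x = 1.0 - float(((Xc - Xhat) ** 2).sum()) / max(float((Xc ** 2).sum()), _EPS)
    q2, press, ss = cross_validated_q2(X, y, folds=folds, seed=seed,
                                       n_ortho=int(n_ortho), scaling=scaling)

    model = OPLSDAModel(x_mean, x_scale, kept, y_mean, w, p, q, t,
                        W_o, P_o, T_o, int(T_o.shape[1]), r2x, r2y, q2,
                        press, ss, len(y), min(folds, len(y)))
    model.vip = compute_vip(model, yc=yc)
    model.cvanova_p = cv_anova(model)
    return model


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def compute_vip(model: OPLSDAModel, yc: np.ndarray | None = None) -> np.ndarray:
    """VIP over predictive plus orthogonal components with SSY weighting.

    VIP_j = sqrt( p · Σ_a SSY_a w_aj² / Σ_a SSY_a ) with unit-norm component
    weights, so that the VIP² values average to exactly 1. Returned on the
    full variable axis (dropped constant columns get VIP 0).
    """
    if yc is None:
        yc = model.t * model.q          # best available y reconstruction
    comps = [model.w]
    ssy = [model.q ** 2 * float(model.t @ model.t)]
    for a in range(model.n_ortho):
        t_o = model.T_ortho[:, a]
        q_o = float(yc @ t_o / (t_o @ t_o + _EPS))
        comps.append(model.W_ortho[a])
        ssy.append(q_o ** 2 * float(t_o @ t_o))
    Wmat = np.vstack(comps)             # (n_comp, p_kept)
    ssy = np.asarray(ssy)
    if ssy.sum() < _EPS:
        ssy = np.array([1.0] + [0.0] * model.n_ortho)
    p_vars = Wmat.shape[1]
    vip_kept = np.sqrt(p_vars * (ssy @ Wmat ** 2) / ssy.sum())
    vip = np.zeros(len(model.kept))
    vip[model.kept] = vip_kept
    return vip


def cv_anova(model: OPLSDAModel) -> float:
    """Cross-validation ANOVA p-value of the fitted model.

    F compares the variance explained by cross-validated prediction with the
    cross-validated residual variance: F = ((SS−PRESS)/df₁)/(PRESS/df₂) with
    df₁ = fitted components, df₂ = N − 1 − df₁. PRESS ≥ SS means the model
    predicts worse than the mean: p = 1.
    """
    ss, press = model.ss_y, model.press
    if press >= ss:
        return 1.0
    df1 = 1 + model.n_ortho
    df2 = max(model.n_obs - 1 - df1, 1)
    if press < _EPS:
        return 0.0
    F = ((ss - press) / df1) / (press / df2)
    return float(stats.f.sf(F, df1, df2))


def permutation_test(X: np.ndarray, y: np.ndarray, n_perm: int = 200,
                     seed: int = 0, folds: int = 7,
                     n_ortho: int | None = None, scaling: str = "uv") -> float:
    """Permutation p-value of the model's Q².

    The class labels are permuted ``n_perm`` times, the model refit and its
    cross-validated Q² recorded; p = (1 + #{Q²_perm ≥ Q²_obs}) / (n_perm + 1).
    """
    if n_perm < 20:
        raise ValueError("at least 20 permutations are required")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_ortho is None:
        n_ortho = fit_oplsda(X, y, folds=folds, seed=seed, scaling=scaling).n_ortho
    q2_obs, _, _ = cross_validated_q2(X, y, folds=folds, seed=seed,
                                      n_ortho=n_ortho, scaling=scaling)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        q2_perm, _, _ = cross_validated_q2(X, y_perm, folds=folds,
                                           seed=int(rng.integers(2**31)),
                                           n_ortho=n_ortho, scaling=scaling)
        exceed += q2_perm >= q2_obs
    return (1 + exceed) / (n_perm + 1)


# ---------------------------------------------------------------------------
# study-level component models
# ---------------------------------------------------------------------------

@dataclass
class ComponentModelReport:
    """Per-patient OPLS-DA summaries for one plaque component."""

    component: str
    summary: pd.DataFrame            # patient, n_obs, r2y, q2, cvanova_p, ...
    accepted: bool
    quorum: float
    vip_median: np.ndarray           # median VIP across significant patients
    discriminative: np.ndarray       # peak indices with median VIP > 1
    contrast: np.ndarray = None      # mean in-minus-rest log intensity per peak

    @property
    def n_significant(self) -> int:
        return int(self.summary["significant"].sum())

    @property
    def discriminative_elevated(self) -> np.ndarray:
        """VIP > 1 peaks that are *elevated* in the component (the species a
        report would list as characteristic of it; VIP itself is unsigned)."""
        if self.contrast is None:
            return self.discriminative
        return self.discriminative[self.contrast[self.discriminative] > 0]


def evaluate_component_model(dataset: DiscriminantDataset, component: str,
                             quorum: float = 0.5, folds: int = 7, seed: int = 0,
                             mode: str = "per_patient",
                             r2_threshold: float = 0.5, q2_threshold: float = 0.5,
                             p_threshold: float = 0.05,
                             scaling: str = "uv") -> ComponentModelReport:
    """Patient-wise OPLS-DA acceptance rule for one plaque component.

    A patient's model is significant when R²Y > 0.5, Q² > 0.5 and the
    CV-ANOVA p-value < 0.05; the component's report is accepted when at
    least ``quorum`` of the modeled patients are significant. The
    discriminative m/z set takes the median VIP > 1.0 across significant
    patients. ``mode="pooled"`` instead fits one model on all patients.
    """
    rows, vips = [], []
    if mode == "pooled":
        groups = [("all", dataset)]
    elif mode == "per_patient":
        groups = [(pid, dataset.subset(dataset.patient_id == pid))
                  for pid in dict.fromkeys(dataset.patient_id)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for pid, sub in groups:
        n_target = int((sub.y == 1).sum())
        n_rest = int((sub.y == -1).sum())
        if n_target < 3 or n_rest < 3:
            logger.info("%s model: patient %s skipped (%d/%d observations)",
                        component, pid, n_target, n_rest)
            continue
        model = fit_oplsda(sub.X, sub.y, folds=folds, seed=seed, scaling=scaling)
        significant = (model.r2y > r2_threshold and model.q2 > q2_threshold
                       and model.cvanova_p < p_threshold)
        rows.append(dict(patient=pid, n_obs=len(sub.y), r2y=model.r2y,
                         q2=model.q2, cvanova_p=model.cvanova_p,
                         n_ortho=model.n_ortho, significant=significant))
        if significant:
            vips.append(model.vip)

    summary = pd.DataFrame(rows, columns=["patient", "n_obs", "r2y", "q2",
                                          "cvanova_p", "n_ortho", "significant"])
    n_models = len(summary)
    accepted = n_models > 0 and summary["significant"].sum() >= quorum * n_models
    if vips:
        vip_median = np.median(np.vstack(vips), axis=0)
    else:
        vip_median = np.zeros(dataset.X.shape[1])
    discriminative = np.nonzero(vip_median > 1.0)[0] if accepted else np.array([], dtype=int)
    contrast = (dataset.X[dataset.y == 1].mean(axis=0)
                - dataset.X[dataset.y == -1].mean(axis=0))
    return ComponentModelReport(component, summary, bool(accepted), quorum,
                                vip_median, discriminative, contrast)


def component_spectra_for_study(study_log, masks: dict, min_pixels: int = 20):
    """Mean component-vs-rest spectra for every section of a study."""
    out = []
    for s in study_log.sections:
        mask = masks.get((s.patient_id, s.section_id))
        if mask is None:
            continue
        out.append(component_mean_spectra(s, mask, min_pixels=min_pixels))
    return out
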