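"""Concordance of histology-driven VIPs with unsupervised NMF components.

The histology-registered discriminant models name, per plaque component,
the m/z values with VIP > 1.0; the unsupervised NMF names, per spectral
component, the m/z values above 0.4 of the max-normalized component weight.
Cross-tabulating the two shows whether supervised and unsupervised views of
the data agree — e.g. whether necrotic-core VIPs concentrate in the
SM/oxidized-CE-dominated NMF component. Spatial agreement is quantified by
the Dice overlap of thresholded NMF weight images with registered masks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import msi_data, nmf, oplsda, registration, synthetic, univariate
from .registration import LABEL_CODES

logger = logging.getLogger("plaquemap")


@dataclass
class ConcordanceTable:
    """Counts of each histology component's VIP peaks per NMF component.

    A VIP peak may belong to several NMF components' m/z sets (memberships
    overlap); peaks in none are counted as unallocated.
    """

    counts: pd.DataFrame          # rows: NMF components, cols: histology labels
    unallocated: pd.Series
    plurality: dict[str, int]     # histology label -> NMF component index


def allocate_vips(vip_sets: dict[str, np.ndarray],
                  nmf_mz_sets: list[np.ndarray]) -> ConcordanceTable:
    """Cross-tabulate VIP peak sets against NMF component m/z sets."""
    labels = list(vip_sets)
    k = len(nmf_mz_sets)
    counts = pd.DataFrame(0, index=[f"component_{i + 1}" for i in range(k)],
                          columns=labels, dtype=int)
    unallocated = pd.Series(0, index=labels, dtype=int)
    plurality: dict[str, int] = {}
    member = [set(np.asarray(s, dtype=int).tolist()) for s in nmf_mz_sets]
    for label in labels:
        vips = set(np.asarray(vip_sets[label], dtype=int).tolist())
        for i in range(k):
            counts.loc[f"component_{i + 1}", label] = len(vips & member[i])
        unallocated[label] = sum(1 for v in vips if not any(v in m for m in member))
        if vips:
            col = counts[label].to_numpy()
            plurality[label] = int(np.argmax(col))   # ties -> lowest component
    return ConcordanceTable(counts, unallocated, plurality)


def spatial_overlap(model: nmf.NMFModel,
                    masks: dict[tuple[str, str], registration.SegmentationMask],
                    weight_threshold: float | str = "upper-quartile") -> pd.DataFrame:
    """Dice overlap of binarized component weight images with mask labels.

    Per section each component's weight image is binarized at the threshold
    (default: the upper quartile of that component's tissue weights) and
    compared against every present label region; empty labels are skipped.
    """
    rows = []
    for (pid, sid), mask in masks.items():
        if (pid, sid) not in model.pool.grids:
            continue
        coords, _ = model.pool.grids[(pid, sid)]
        W = model.W[model.pool.rows_of(pid, sid)]
        at = mask.labels[coords[:, 0], coords[:, 1]]
        for comp in range(model.k):
            w = W[:, comp]
            thr = (np.percentile(w, 75) if weight_threshold == "upper-quartile"
                   else float(weight_threshold))
            binary = w > thr
            for label in registration.COMPONENT_LABELS:
                region = at == LABEL_CODES[label]
                if not region.any():
                    continue
                inter = int((binary & region).sum())
                dice = 2 * inter / (int(binary.sum()) + int(region.sum()))
                rows.append(dict(patient_id=pid, section_id=sid,
                                 component=comp, label=label, dice=dice))
    return pd.DataFrame(rows, columns=["patient_id", "section_id",
                                       "component", "label", "dice"])


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = dict(
    simulate=dict(n_patients=12, sections_min=5, sections_max=12,
                  grid=48, n_per_class=3, noise_sigma=0.3, seed=0),
    preprocess=dict(min_fraction=0.30, tol=0.02),
    nmf=dict(k=None, k_range=[2, 8], n_runs=10, subsample=1500, seed=0,
             threshold_factor=0.4),
    oplsda=dict(components=["NC", "fibrin"], quorum=0.5, folds=7, seed=0),
    univariate=dict(alpha=0.05),
)


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _validate_config(config: dict) -> dict:
    config = _merge(DEFAULT_CONFIG, config)
    sim = config["simulate"]
    if not (sim.get("study_dir") or sim.get("n_patients", 0) >= 1):
        raise ValueError("config must name an input study_dir or n_patients ≥ 1")
    for key in ("preprocess", "nmf", "oplsda", "univariate"):
        if key not in config:
            raise ValueError(f"config section {key!r} missing")
    return config


def run_full_pipeline(config: dict | str | Path, workdir: str | Path | None = None,
                      dry_run: bool = False) -> dict:
    """Run simulate → preprocess → correlate → NMF → register → OPLS-DA →
    univariate → concordance and return one structured report.

    ``config`` may be a dict or a YAML file path. With ``dry_run`` the
    configuration is validated and returned without touching any data.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    config = _validate_config(config or {})
    if dry_run:
        return dict(config=config, dry_run=True)

    report: dict = {"config": config, "stages": {}}
    try:
        study_raw, truth = _stage_input(config, workdir)
        report["stages"]["input"] = dict(
            n_sections=len(study_raw), n_patients=len(study_raw.patients()),
            n_peaks=len(study_raw.mz))

        # preprocessing: presence filter + deisotoping
        pp = config["preprocess"]
        study_raw, peaks = msi_data.preprocess_study(
            study_raw, min_fraction=pp["min_fraction"], tol=pp["tol"])
        study_log = msi_data.log_transform(study_raw)
        report["stages"]["preprocess"] = dict(n_peaks_retained=len(peaks))

        # spatial correlation
        from .spatial_correlation import average_correlation, class_block_means, order_by_class

        corr = order_by_class(average_correlation(study_raw, peaks))
        within, between = class_block_means(corr)
        report["stages"]["correlation"] = dict(
            within_class_mean={k: round(v, 4) for k, v in within.items()},
            between_class_mean=round(between, 4))

        # NMF segmentation
        nc = config["nmf"]
        pool = nmf.pool_study(study_raw)
        if nc.get("k"):
            k = int(nc["k"])
            rank = None
        else:
            lo, hi = nc["k_range"]
            rank = nmf.select_rank(pool.X, range(lo, hi + 1), n_runs=nc["n_runs"],
                                   seed=nc["seed"], subsample=nc["subsample"])
            k = rank.chosen_k
        model = nmf.fit_nmf(pool.X, k, seed=nc["seed"], pool=pool)
        mz_sets = nmf.component_threshold_mz(model.H, nc["threshold_factor"])
        report["stages"]["nmf"] = dict(
            k=k, dispersion=dict(zip(rank.k_range, np.round(rank.dispersion, 3)))
            if rank else None,
            reconstruction_error=model.reconstruction_error)

        # registration
        masks = _stage_masks(study_raw, truth)
        report["stages"]["registration"] = dict(n_masks=len(masks))

        # per-component OPLS-DA + univariate confirmation
        oc, uv = config["oplsda"], config["univariate"]
        vip_sets: dict[str, np.ndarray] = {}
        comp_reports = {}
        for label in oc["components"]:
            spectra = oplsda.component_spectra_for_study(study_log, masks)
            dataset = oplsda.build_discriminant_dataset(spectra, label)
            rep = oplsda.evaluate_component_model(
                dataset, label, quorum=oc["quorum"], folds=oc["folds"],
                seed=oc["seed"])
            comp_reports[label] = rep
            vip_sets[label] = rep.discriminative_elevated
            entry = dict(accepted=rep.accepted,
                         n_significant=rep.n_significant,
                         n_patients=len(rep.summary),
                         n_vips=len(rep.discriminative))
            if rep.accepted and len(rep.discriminative):
                table = univariate.confirm_vips(study_raw, masks, label,
                                                rep.discriminative, alpha=uv["alpha"])
                entry["univariate_significant_fraction"] = float(
                    table["significant"].mean())
                entry["median_fold_change"] = float(table["fold_change"].median())
            report["stages"].setdefault("oplsda", {})[label] = entry

        # concordance
        table = allocate_vips(vip_sets, mz_sets)
        overlap = spatial_overlap(model, masks)
        report["stages"]["concordance"] = dict(
            counts=table.counts.to_dict(), plurality=table.plurality,
            unallocated=table.unallocated.to_dict(),
            mean_dice_best=_best_dice(overlap))
        report["digest"] = _digest(report)
    except Exception as exc:
        stage = list(report["stages"])[-1] if report["stages"] else "input"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc
    return report


def _stage_input(config, workdir):
    sim = config["simulate"]
    if sim.get("study_dir"):
        study = msi_data.read_study(Path(sim["study_dir"]) / "manifest.csv",
                                    tolerance=config["preprocess"]["tol"])
        return study, None
    spec = synthetic.PhantomSpec(grid_shape=(sim["grid"], sim["grid"]),
                                 noise_sigma=sim["noise_sigma"])
    out_dir = Path(workdir) / "phantom" if workdir else None
    study, truth = synthetic.generate_study(
        sim["n_patients"], (sim["sections_min"], sim["sections_max"]),
        spec, seed=sim["seed"], out_dir=out_dir, n_per_class=sim["n_per_class"])
    return study, truth


def _stage_masks(study, truth):
    """Register histology masks; phantoms re-estimate transforms from the
    generated landmark files when the study lives on disk, else reuse the
    truth masks through the exact landmark pairs held in memory."""
    if study.manifest is not None and "landmarks_hist" in study.manifest.columns:
        return registration.register_study_masks(study)
    if truth is None:
        raise ValueError("no masks available: study has neither manifest nor truth")
    return dict(truth.truth_masks)


def _best_dice(overlap: pd.DataFrame) -> dict:
    out = {}
    if overlap.empty:
        return out
    mean = overlap.groupby(["label", "component"])["dice"].mean()
    for label in mean.index.get_level_values(0).unique():
        sub = mean[label]
        out[label] = dict(component=int(sub.idxmax()), dice=float(sub.max()))
    return out


def _digest(report: dict) -> str:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    payload = json.dumps({k: v for k, v in report.items() if k != "digest"},
                         sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()
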