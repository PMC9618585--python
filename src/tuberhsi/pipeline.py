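"""Config-driven orchestration of the two classification experiments.

``run_experiment`` reproduces the study workflow end to end on either a
written dataset (ENVI cubes + manifest CSV) or an in-memory simulation:

calibrate -> trim leading bands -> segment -> (mean spectrum | unfold)
-> calibration/validation split -> pre-processing chain -> LV selection
-> venetian-blinds CV -> external validation -> optional forward iPLS
-> metric tables -> classification maps (pixel mode).

``compare_chains`` runs the ten standard pre-processing chains against a
single feature extraction and returns one combined table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import (
    ConfusionStats,
    confusion_stats,
    cross_validate,
    plsda_fit,
    plsda_predict,
    select_n_lv,
    venetian_blinds,
)
from .cube_io import (
    ReferencePair,
    calibrate_reflectance,
    mean_spectrum,
    read_envi,
    trim_leading_bands,
    unfold,
)
from .errors import ConfigError
from .ipls import forward_ipls
from .maps import CategoryImage, categorize, render
from .preprocess import build_chain
from .segmentation import SegmentationParams, segment_slice
from .synthetic_data import (
    COOKING,
    MEAN_SPECTRA_SPLIT,
    PIXELWISE_SPLIT,
    SliceSpec,
    iter_slices,
    select_cultivars,
    split_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["SimulateConfig", "RunConfig", "FeatureSet", "extract_features",
           "run_experiment", "compare_chains", "metrics_table"]


@dataclasses.dataclass
class SimulateConfig:
    """In-memory synthetic dataset in place of a manifest on disk."""

    n_cultivars: int = 10
    tubers_per_cultivar: int = 8
    slice_spec: SliceSpec | None = None


@dataclasses.dataclass
class RunConfig:
    mode: str = "mean"  # "mean" | "pixel"
    chain: str = "SM+SNV+MC"
    max_lv: int = 10
    cv_splits: int = 10
    cv_width: int = 1
    n_drop_bands: int = 30
    ipls_enabled: bool = False
    ipls_interval_size: int = 5
    ipls_rel_tol: float = 1e-3
    ipls_max_intervals: int | None = None
    seed: int = 0
    positive_class: str = COOKING
    manifest: str | pathlib.Path | None = None
    simulate: SimulateConfig | None = None
    segmentation: SegmentationParams = dataclasses.field(default_factory=SegmentationParams)
    max_pixels_per_slice: int | None = None
    out_dir: str | pathlib.Path | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("mean", "pixel"):
            raise ConfigError(f"mode must be 'mean' or 'pixel', got {self.mode!r}")
        if self.manifest is None and self.simulate is None:
            self.simulate = SimulateConfig()


@dataclasses.dataclass
class FeatureSet:
    """Extracted spectra ready for chemometric modelling.

    In mean mode one row per tuber; in pixel mode one row per foreground
    pixel with image coordinates and per-sample spatial metadata kept for
    folding maps back.
    """

    mode: str
    X: np.ndarray
    y: np.ndarray
    sample_ids: np.ndarray
    split: np.ndarray  # "calibration" / "validation" per row
    spacing_nm: float
    coords: np.ndarray | None = None
    sample_meta: dict | None = None  # sample_id -> {shape, regions, class}


def _simulated_manifest(sim: SimulateConfig) -> pd.DataFrame:
    rows = []
    for cv in select_cultivars(sim.n_cultivars):
        for t in range(sim.tubers_per_cultivar):
            rows.append(
                {
                    "sample_id": f"{cv.name.replace(' ', '_')}_{t + 1:02d}",
                    "cultivar": cv.name,
                    "class": cv.class_label,
                }
            )
    return pd.DataFrame.from_records(rows)


def _iter_samples(config: RunConfig):
    """Yield (sample_id, class_label, raw cube, refs) for every sample."""
    if config.manifest is not None:
        root = pathlib.Path(config.manifest).parent
        manifest = pd.read_csv(config.manifest)
        for _, row in manifest.iterrows():
            cube = read_envi(root / row["cube"])
            white = read_envi(root / row["white"])
            dark = read_envi(root / row["dark"])
            refs = ReferencePair(white.data[0], dark.data[0])
            yield str(row["sample_id"]), str(row["class"]), cube, refs
    else:
        sim = config.simulate
        for sample in iter_slices(
            sim.n_cultivars, sim.tubers_per_cultivar, config.seed, sim.slice_spec
        ):
            yield sample.sample_id, sample.class_label, sample.raw, sample.refs


def load_manifest(config: RunConfig) -> pd.DataFrame:
    if config.manifest is not None:
        return pd.read_csv(config.manifest)[["sample_id", "cultivar", "class"]]
    return _simulated_manifest(config.simulate)


def extract_features(config: RunConfig, split: pd.Series | None = None) -> FeatureSet:
    """Calibrate, trim, segment and unfold/average every used sample."""
    manifest = load_manifest(config)
    if split is None:
        mode_name = MEAN_SPECTRA_SPLIT if config.mode == "mean" else PIXELWISE_SPLIT
        split = split_dataset(manifest, mode_name, config.seed)
    split_by_id = dict(zip(manifest["sample_id"], split))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5AB5)))

    spectra, labels, ids, splits, coords_list = [], [], [], [], []
    sample_meta: dict = {}
    spacing = None
    for sample_id, class_label, raw, refs in _iter_samples(config):
        assignment = split_by_id.get(sample_id, "unused")
        if assignment == "unused":
            continue
        cube = calibrate_reflectance(raw, refs)
        cube = trim_leading_bands(cube, config.n_drop_bands)
        spacing = cube.axis.spacing_nm
        mask = segment_slice(cube, config.segmentation)
        if config.mode == "mean":
            spectra.append(mean_spectrum(cube, mask))
            labels.append(class_label)
            ids.append(sample_id)
            splits.append(assignment)
        else:
            pm = unfold(cube, mask)
            keep = np.arange(pm.n_pixels)
            if (
                config.max_pixels_per_slice is not None
                and pm.n_pixels > config.max_pixels_per_slice
            ):
                keep = np.sort(
                    rng.choice(pm.n_pixels, config.max_pixels_per_slice, replace=False)
                )
            spectra.append(pm.spectra[keep].astype(np.float32))
            coords_list.append(pm.coords[keep])
            n = len(keep)
            labels.extend([class_label] * n)
            ids.extend([sample_id] * n)
            splits.extend([assignment] * n)
            sample_meta[sample_id] = {
                "shape": cube.spatial_shape,
                "class": class_label,
                "n_pixels": n,
            }
    if not spectra:
        raise ConfigError("no samples extracted; check manifest/split")
    if config.mode == "mean":
        X = np.vstack(spectra)
        coords = None
    else:
        X = np.vstack(spectra)
        coords = np.vstack(coords_list)
    return FeatureSet(
        mode=config.mode,
        X=X,
        y=np.asarray(labels, dtype=object),
        sample_ids=np.asarray(ids, dtype=object),
        split=np.asarray(splits, dtype=object),
        spacing_nm=float(spacing),
        coords=coords,
        sample_meta=sample_meta or None,
    )


def _round_metrics(stats: ConfusionStats) -> dict:
    """Rounded presentation values (errors 3 dp, accuracy 2 dp, half-even)."""
    return {
        "sensitivity": float(np.round(stats.sensitivity, 3)),
        "specificity": float(np.round(stats.specificity, 3)),
        "error": float(np.round(stats.class_error, 3)),
        "accuracy_pct": float(np.round(stats.accuracy_pct, 2)),
    }


def metrics_table(results: Sequence[dict]) -> pd.DataFrame:
    """Two mirrored class rows ("C" positive, "FC") per model result."""
    rows = []
    for res in results:
        cv, val = res["cv_stats"], res["val_stats"]
        cv_r, val_r = _round_metrics(cv), _round_metrics(val)
        common = {
            "preprocessing": res["chain"],
            "n_lv": res["n_lv"],
            "variance_pct": float(np.round(res["explained_x_variance_pct"], 2)),
        }
        if "n_variables" in res:
            common["n_variables"] = res["n_variables"]
        rows.append(
            common
            | {
                "class": "C",
                "cv_sensitivity": cv_r["sensitivity"],
                "cv_specificity": cv_r["specificity"],
                "cv_error": cv_r["error"],
                "cv_accuracy_pct": cv_r["accuracy_pct"],
                "val_sensitivity": val_r["sensitivity"],
                "val_specificity": val_r["specificity"],
                "val_error": val_r["error"],
                "val_accuracy_pct": val_r["accuracy_pct"],
            }
        )
        rows.append(
            common
            | {
                "class": "FC",
                "cv_sensitivity": cv_r["specificity"],
                "cv_specificity": cv_r["sensitivity"],
                "cv_error": cv_r["error"],
                "cv_accuracy_pct": cv_r["accuracy_pct"],
                "val_sensitivity": val_r["specificity"],
                "val_specificity": val_r["sensitivity"],
                "val_error": val_r["error"],
                "val_accuracy_pct": val_r["accuracy_pct"],
            }
        )
    return pd.DataFrame.from_records(rows)


def _fit_and_validate(features: FeatureSet, config: RunConfig, chain_name: str):
    """Core model pass shared by run_experiment and compare_chains."""
    cal = features.split == "calibration"
    val = features.split == "validation"
    X_cal, y_cal = features.X[cal], features.y[cal]
    X_val, y_val = features.X[val], features.y[val]
    plan = venetian_blinds(len(y_cal), config.cv_splits, config.cv_width)
    chain = build_chain(chain_name, spacing_nm=features.spacing_nm)
    n_lv, curves = select_n_lv(
        X_cal, y_cal, chain, config.max_lv, plan, config.positive_class
    )
    cv_stats, cv_details = cross_validate(
        X_cal, y_cal, chain.clone(), n_lv, plan, config.positive_class
    )
    fitted = chain.clone()
    Xp_cal = fitted.fit_transform(X_cal)
    model = plsda_fit(Xp_cal, y_cal, n_lv, chain=fitted)
    Xp_val = fitted.transform(X_val)
    val_pred, val_scores = plsda_predict(model, Xp_val)
    val_stats = confusion_stats(y_val, val_pred, config.positive_class)
    result = {
        "chain": chain_name,
        "n_lv": model.n_lv,
        "explained_x_variance_pct": float(model.explained_x_variance_pct[-1]),
        "lv_curves": curves,
        "cv_stats": cv_stats,
        "val_stats": val_stats,
        "model": model,
        "val_pred": val_pred,
        "val_scores": val_scores,
        "cal_mask": cal,
        "val_mask": val,
        "Xp_cal": Xp_cal,
        "Xp_val": Xp_val,
        "plan": plan,
    }
    return result


def _ipls_pass(result: dict, features: FeatureSet, config: RunConfig):
    cal = result["cal_mask"]
    val = result["val_mask"]
    y_cal, y_val = features.y[cal], features.y[val]
    ipls_result = forward_ipls(
        result["Xp_cal"],
        y_cal,
        config.ipls_interval_size,
        result["plan"],
        max_intervals=config.ipls_max_intervals,
        rel_tol=config.ipls_rel_tol,
        max_lv=config.max_lv,
        positive_class=config.positive_class,
    )
    cols = ipls_result.selected_variables
    Xs_cal = result["Xp_cal"][:, cols]
    Xs_val = result["Xp_val"][:, cols]
    plan = result["plan"]
    n_lv = min(ipls_result.n_lv, Xs_cal.shape[1])
    cv_stats, _ = cross_validate(Xs_cal, y_cal, None, n_lv, plan, config.positive_class)
    model = plsda_fit(Xs_cal, y_cal, n_lv)
    val_pred, val_scores = plsda_predict(model, Xs_val)
    val_stats = confusion_stats(y_val, val_pred, config.positive_class)
    return {
        "chain": result["chain"],
        "ipls": ipls_result,
        "n_variables": ipls_result.n_selected_variables,
        "n_lv": model.n_lv,
        "explained_x_variance_pct": float(model.explained_x_variance_pct[-1]),
        "cv_stats": cv_stats,
        "val_stats": val_stats,
        "model": model,
        "val_pred": val_pred,
        "val_scores": val_scores,
    }


def _make_maps(result: dict, features: FeatureSet, config: RunConfig) -> list[CategoryImage]:
    """One category image per validation tuber from the reported model."""
    val = result["val_mask"] if "val_mask" in result else features.split == "validation"
    ids = features.sample_ids[val]
    pred = result["val_pred"]
    coords = features.coords[val]
    images = []
    for sample_id in pd.unique(ids):
        sel = ids == sample_id
        meta = features.sample_meta[sample_id]
        images.append(
            categorize(
                pred[sel],
                meta["class"],
                coords[sel],
                meta["shape"],
                config.positive_class,
                sample_id=sample_id,
            )
        )
    return images


def run_experiment(config: RunConfig) -> dict:
    """Execute one full experiment and (optionally) write its artifacts.

    Returns a results dict with the fitted model, CV/validation
    :class:`ConfusionStats`, LV-selection curves, the iPLS result when
    enabled, per-slice category images in pixel mode, and the metric
    table.  With ``config.out_dir`` set, metric CSVs, map PNGs + count
    sidecars and a JSON run log are written under
    ``out_dir/{metrics,maps,logs}``.
    """
    features = extract_features(config)
    result = _fit_and_validate(features, config, config.chain)
    results_for_table = [result]
    out: dict = {
        "mode": config.mode,
        "chain": config.chain,
        "n_lv": result["n_lv"],
        "explained_x_variance_pct": result["explained_x_variance_pct"],
        "cv_stats": result["cv_stats"],
        "val_stats": result["val_stats"],
        "lv_curves": result["lv_curves"],
        "model": result["model"],
        "features": features,
    }
    reported = result
    if config.ipls_enabled:
        ipls_res = _ipls_pass(result, features, config)
        results_for_table.append(ipls_res)
        out["ipls"] = ipls_res
        reported = {**ipls_res, "val_mask": result["val_mask"]}
    if config.mode == "pixel":
        images = _make_maps(reported, features, config)
        out["maps"] = images
        agg = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for img in images:
            for k in agg:
                agg[k] += img.counts[k]
        out["map_counts"] = agg
    out["metrics"] = metrics_table(results_for_table)

    if config.out_dir is not None:
        out_dir = pathlib.Path(config.out_dir)
        (out_dir / "metrics").mkdir(parents=True, exist_ok=True)
        out["metrics"].to_csv(out_dir / "metrics" / "metrics.csv", index=False)
        if config.mode == "pixel":
            maps_dir = out_dir / "maps"
            maps_dir.mkdir(exist_ok=True)
            for img in out["maps"]:
                render(img, maps_dir / f"{img.sample_id}.png")
                img.write_counts(maps_dir / f"{img.sample_id}.json")
        (out_dir / "logs").mkdir(exist_ok=True)
        log = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "mode": config.mode,
            "chain": config.chain,
            "n_lv": int(result["n_lv"]),
            "ipls_enabled": config.ipls_enabled,
        }
        (out_dir / "logs" / "run.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return out


def compare_chains(config: RunConfig, chains: Sequence[str]) -> pd.DataFrame:
    """One metric-table block per chain against a single feature extraction.

    The returned table carries a ``best`` marker on the chain with the
    highest external-validation accuracy.
    """
    if not chains:
        raise ConfigError("need at least one chain")
    features = extract_features(config)
    results = [_fit_and_validate(features, config, name) for name in chains]
    table = metrics_table(results)
    accuracies = [res["val_stats"].accuracy_pct for res in results]
    best_chain = chains[int(np.argmax(accuracies))]
    table["best"] = table["preprocessing"] == best_chain
    if config.out_dir is not None:
        out_dir = pathlib.Path(config.out_dir) / "metrics"
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "chain_comparison.csv", index=False)
    return table
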