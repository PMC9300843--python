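"""End-to-end pipeline: simulate -> unmix -> ROI metrics -> growth -> predict.

A :class:`RunConfig` is validated up front, echoed (with a content hash)
into every output's provenance block, and drives the full chain.  With
``use_imaging=True`` each animal-day produces a synthetic tumor scene
that is spectrally unmixed and reduced to ROI biomarkers — the measured
cohort table is then *derived from images*, exactly as in a real study;
with ``use_imaging=False`` the generator's tabulated measurements are
used directly (fast path).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .extinction import load_default_extinction
from .fluence import FluenceModel
from .growth import AUC_PRESETS, fit_cohort, km_estimate
from .predict import (
    GrowthRateModel,
    ResponderModel,
    forward_select,
    per_day_group_tests,
    spearman_matrix,
)
from .roi import roi_statistics
from .synth import (
    CohortSpec,
    CohortTable,
    TumorSpec,
    gompertz_volume,
    simulate_growth_cohort,
    simulate_tumor_scene,
    _treated_sto2_offset,
)
from .unmix import unmix_pair

logger = logging.getLogger("patreat")

__all__ = ["RunConfig", "run_pipeline", "build_feature_table", "PREDICTORS"]

PREDICTORS = ("pretreat_volume_mm3", "dsto2_d7_d10", "dsto2_d10_d14")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str = "patreat_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    use_imaging: bool = True
    scene_voxel_spacing: tuple[float, float, float] = (0.3, 0.2, 0.2)
    noise_floor: float = 0.0
    clamp: str = "flag"
    auc_preset: str = "standard"
    cv_k: int = 5
    cv_train_frac: float = 0.8
    cv_repeats: int = 100
    responder_percentile: float = 25.0
    feature_days: tuple[float, float, float] = (7.0, 10.0, 14.0)

    def __post_init__(self) -> None:
        if self.auc_preset not in AUC_PRESETS:
            raise ValidationError(f"auc_preset must be one of {sorted(AUC_PRESETS)}")
        if self.clamp not in ("flag", "range", "none"):
            raise ValidationError("clamp must be 'flag', 'range' or 'none'")
        if self.cv_k < 2 or self.cv_repeats < 1:
            raise ValidationError("cv_k >= 2 and cv_repeats >= 1 required")
        if not 0 < self.cv_train_frac < 1:
            raise ValidationError("cv_train_frac must lie in (0, 1)")
        if not 0 < self.responder_percentile < 100:
            raise ValidationError("responder_percentile must lie in (0, 100)")
        # constructing the spec validates the cohort overrides immediately
        self.cohort_spec()

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.cohort)
        if "imaging_days" in kwargs:
            kwargs["imaging_days"] = tuple(kwargs["imaging_days"])
        if "treatment_effect" in kwargs and isinstance(
            kwargs["treatment_effect"], list
        ):
            kwargs["treatment_effect"] = tuple(kwargs["treatment_effect"])
        return CohortSpec(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "scene_voxel_spacing" in raw:
            raw["scene_voxel_spacing"] = tuple(raw["scene_voxel_spacing"])
        if "feature_days" in raw:
            raw["feature_days"] = tuple(raw["feature_days"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene_voxel_spacing"] = list(self.scene_voxel_spacing)
        d["feature_days"] = list(self.feature_days)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_feature_table(
    cohort: pd.DataFrame,
    fits: pd.DataFrame,
    feature_days: tuple[float, float, float] = (7.0, 10.0, 14.0),
) -> pd.DataFrame:
    """Per-animal predictor table for the growth-rate model.

    Features: tumor volume on the immediately-pretreatment day and StO2
    average changes over the pretreatment (D7->D10) and peritreatment
    (D10->D14) windows, joined with the fitted growth rate ``beta``.
    Animals missing any required day are dropped.
    """
    d7, d10, d14 = feature_days
    wide = cohort.pivot_table(index="animal_id", columns="day", values="sto2_avg_pct")
    vol = cohort.pivot_table(index="animal_id", columns="day", values="volume_mm3")
    feats = pd.DataFrame(index=wide.index)
    for day in feature_days:
        if day not in wide.columns or day not in vol.columns:
            raise ValidationError(f"cohort lacks measurements on day {day}")
    feats["pretreat_volume_mm3"] = vol[d10]
    feats["dsto2_d7_d10"] = wide[d10] - wide[d7]
    feats["dsto2_d10_d14"] = wide[d14] - wide[d10]
    out = feats.reset_index().merge(
        fits[["animal_id", "group", "beta", "alpha", "kappa", "converged",
              "auc_early", "auc_treat", "auc_late", "t2x", "t5x", "t10x"]],
        on="animal_id",
    )
    out = out[out["converged"].astype(bool)].dropna(
        subset=["pretreat_volume_mm3", "dsto2_d7_d10", "dsto2_d10_d14", "beta"]
    )
    return out.reset_index(drop=True)


def _image_cohort(
    cohort: CohortTable, config: RunConfig, seed: int
) -> pd.DataFrame:
    """Re-measure every animal-day through scene simulation -> unmix -> ROI."""
    ext = load_default_extinction()
    fluence = FluenceModel.for_medium("tissue")
    spec = cohort.spec
    truth = cohort.truth.set_index("animal_id")
    rows = []
    rng = np.random.default_rng(seed)
    for _, rec in cohort.table.iterrows():
        tr = truth.loc[rec["animal_id"]]
        day = rec["day"]
        v_true = float(gompertz_volume(day, tr["alpha"], tr["beta"], tr["kappa"]))
        s_true = float(tr["sto2_baseline"])
        if rec["group"] == 1:
            s_true += _treated_sto2_offset(day, spec)
        s_true = float(np.clip(s_true, 0.0, 100.0))
        r = (3.0 * v_true / (4.0 * math.pi)) ** (1.0 / 3.0)
        tspec = TumorSpec(
            semi_axes=(r, r, r),
            vascular_fraction=spec.vascular_fraction,
            sto2_core=s_true,
            sto2_periphery=s_true,
            voxel_spacing=config.scene_voxel_spacing,
            noise_sd=0.02,
        )
        scene = simulate_tumor_scene(
            tspec, fluence=fluence, seed=int(rng.integers(2**31 - 1)), ext=ext
        )
        maps = unmix_pair(
            scene.volumes, ext=ext, noise_floor=config.noise_floor, clamp=config.clamp
        )
        m = roi_statistics(maps, scene.roi_mask)
        rows.append(
            dict(
                animal_id=rec["animal_id"],
                group=int(rec["group"]),
                day=float(day),
                volume_mm3=m.volume_mm3,
                sto2_avg_pct=m.sto2_avg,
                sto2_tot_pct=m.sto2_tot,
                hbt_avg=m.hbt_avg,
                hbt_tot=m.hbt_tot,
                event_day=float(rec["event_day"]),
                censored=bool(rec["censored"]),
            )
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write all stage outputs.

    Returns the report bundle as a dict (also written to
    ``<out_dir>/report.json``).  Any stage failure aborts with a
    stage-tagged error; outputs written so far are preserved.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "patreat_version": __version__,
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }
    report: dict = {"provenance": provenance, "stages": {}}

    def _stage(name):
        logger.info("stage %s starting", name)
        return time.time()

    def _done(name, t0, **counts):
        dt = time.time() - t0
        report["stages"][name] = {"seconds": round(dt, 3), **counts}
        logger.info("stage %s done in %.2fs %s", name, dt, counts)

    try:
        t0 = _stage("simulate")
        cohort = simulate_growth_cohort(config.cohort_spec(), seed=config.seed)
        cohort.table.to_csv(out / "cohort_generated.csv", index=False)
        cohort.truth.to_csv(out / "cohort_truth.csv", index=False)
        _done("simulate", t0, n_rows=len(cohort.table), n_animals=len(cohort.truth))

        if config.use_imaging:
            t0 = _stage("unmix+metrics")
            measured = _image_cohort(cohort, config, seed=config.seed + 1)
            _done("unmix+metrics", t0, n_scenes=len(measured))
        else:
            measured = cohort.table.copy()
        measured.to_csv(out / "cohort_measured.csv", index=False)

        t0 = _stage("growth")
        fits = fit_cohort(measured, preset=config.auc_preset)
        fits.to_csv(out / "growth_fits.csv", index=False)
        tests_vol = per_day_group_tests(measured, "volume_mm3")
        tests_sto2 = per_day_group_tests(measured, "sto2_avg_pct")
        tests_vol.to_csv(out / "tests_volume.csv", index=False)
        tests_sto2.to_csv(out / "tests_sto2_avg.csv", index=False)
        km = {}
        for g, label in ((0, "control"), (1, "treated")):
            sub = cohort.truth[cohort.truth["group"] == g]
            if len(sub):
                est = km_estimate(
                    sub.rename(columns={"event_day": "event_day"})[
                        ["event_day", "censored"]
                    ]
                )
                km[label] = {
                    "median_days": est.median_days if est.median_defined else None,
                    "n": est.n,
                }
        _done("growth", t0, n_converged=int(fits["converged"].sum()))

        t0 = _stage("predict")
        feats = build_feature_table(measured, fits, config.feature_days)
        feats.to_csv(out / "features.csv", index=False)
        corr_vars = [
            "pretreat_volume_mm3", "alpha", "beta", "kappa",
            "auc_early", "auc_treat", "auc_late",
            "dsto2_d7_d10", "dsto2_d10_d14",
        ]
        corr = spearman_matrix(feats, corr_vars)
        corr.rho.to_csv(out / "correlation_rho.csv")
        corr.p.to_csv(out / "correlation_p.csv")

        selected, trace = forward_select(feats, list(PREDICTORS), "beta")
        model = GrowthRateModel(feats, PREDICTORS, "beta")
        reg_rows = []
        results = {
            "full": model.fit("full"),
            "kfold": model.fit("kfold", seed=config.seed, k=config.cv_k),
            "subsample": model.fit(
                "subsample",
                seed=config.seed,
                train_frac=config.cv_train_frac,
                repeats=config.cv_repeats,
            ),
        }
        for name, res in results.items():
            row = {"scheme": name, "r_squared": res.r_squared, "p": res.model_p}
            for pname, c, se in zip(
                res.param_names, res.coefficients, res.std_errors
            ):
                row[pname] = c
                row[f"{pname}_se"] = se
            reg_rows.append(row)
        pd.DataFrame(reg_rows).to_csv(out / "regression_summary.csv", index=False)

        responder = ResponderModel(
            feats, PREDICTORS, percentile=config.responder_percentile
        ).fit()
        pd.DataFrame(
            {
                "threshold": responder.roc.thresholds,
                "fpr": responder.roc.fpr,
                "tpr": responder.roc.tpr,
            }
        ).to_csv(out / "roc_points.csv", index=False)
        if responder.logistic.separation:
            logger.warning("responder logistic model flagged complete separation")
        _done("predict", t0, n_features=len(feats))

        report.update(
            {
                "km_median_survival": km,
                "per_day_significant_volume_days": tests_vol.loc[
                    tests_vol["significant"], "day"
                ].tolist(),
                "per_day_significant_sto2_days": tests_sto2.loc[
                    tests_sto2["significant"], "day"
                ].tolist(),
                "forward_selection": {"selected": selected, "trace": trace},
                "regression": {
                    name: {
                        "coefficients": res.coefficients.tolist(),
                        "std_errors": res.std_errors.tolist(),
                        "r_squared": res.r_squared,
                        "p": res.model_p,
                    }
                    for name, res in results.items()
                },
                "responder": {
                    "threshold_beta": responder.threshold,
                    "n_responders": int(responder.labels.sum()),
                    "separation": bool(responder.logistic.separation),
                    "roc_auc": responder.roc.auc,
                    "roc_auc_se": responder.roc.auc_se,
                    "roc_ci95": list(responder.roc.ci95),
                    "youden_cutoff": responder.cutoff,
                    "sensitivity": responder.confusion.sensitivity,
                    "specificity": responder.confusion.specificity,
                    "ppv": responder.confusion.ppv,
                    "npv": responder.confusion.npv,
                    "hosmer_lemeshow_p": responder.hl_p,
                },
            }
        )
    except Exception as err:
        stage = next(
            (s for s in ("simulate", "unmix+metrics", "growth", "predict")
             if s not in report["stages"]),
            "unknown",
        )
        raise type(err)(f"[stage: {stage}] {err}") from err

    report["total_seconds"] = round(time.time() - t_start, 3)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(_json_safe(report), fh, indent=2)
    return report


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj
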