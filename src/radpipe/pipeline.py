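"""End-to-end orchestration: simulate -> segment -> extract -> select/score -> evaluate."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from radpipe import io as rio
from radpipe.config import RunConfig
from radpipe.features import FeatureConfig, extract_feature_vector, feature_names
from radpipe.outcome_stats import cohort_table_stats, cox_ph, km_logrank, roc_auc_and_cutoff
from radpipe.segmentation import SeedBox, SegmentationConfig, VolumePair, TumorMask, \
    map_mask, segment_volume
from radpipe.svm_scoring import SelectionConfig, cross_validated_scores, refit_scores, \
    sequential_forward_selection
from radpipe.synthetic_cohort import ADC_CUTOFF, simulate_cohort

log = logging.getLogger("radpipe")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def seed_box_from_mask(mask: np.ndarray, margin: int = 3) -> SeedBox:
    """Emulate the operator's initial rectangle from a reference mask."""
    xs, ys, zs = np.nonzero(mask)
    shape = mask.shape
    return SeedBox(
        slice_first=int(zs.min()), slice_last=int(zs.max()),
        rectangle=(
            max(int(xs.min()) - margin, 0), min(int(xs.max()) + 1 + margin, shape[0]),
            max(int(ys.min()) - margin, 0), min(int(ys.max()) + 1 + margin, shape[1]),
        ))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 1.0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(input_dir: Path) -> tuple[list[dict], pd.DataFrame]:
    table = rio.load_covariates(
        input_dir / "covariates.csv",
        required=("patient_id", "followup_time", "event"))
    patients = []
    for pid in table["patient_id"]:
        t1, spacing, aff1 = rio.load_volume(input_dir / "images" / f"{pid}_t1c.nii.gz")
        t2, _, aff2 = rio.load_volume(input_dir / "images" / f"{pid}_t2.nii.gz")
        m, _, affm = rio.load_mask(input_dir / "images" / f"{pid}_mask.nii.gz")
        pair = VolumePair(volume_t1c=t1, volume_t2=t2, spacing=spacing,
                          affine_t1c=aff1, affine_t2=aff2)
        patients.append({
            "patient_id": pid, "pair": pair,
            "truth_mask": TumorMask(mask=m, spacing=spacing, affine=affm)})
    return patients, table


def compute_feature_table(patients: list[dict], covariates: pd.DataFrame,
                          config: RunConfig) -> tuple[pd.DataFrame, list[float]]:
    """Segment (optionally) and extract the 214-feature row per patient."""
    fcfg = FeatureConfig(n_bins=config.n_bins, glcm_distance=config.glcm_distance,
                         mode=config.texture_mode)
    scfg = SegmentationConfig(fuzziness=config.fcm_fuzziness, tol=config.fcm_tol,
                              max_iter=config.fcm_max_iter)
    rows, dices = [], []
    for p in patients:
        pair = p["pair"]
        truth = p["truth_mask"]
        if config.segment:
            box = seed_box_from_mask(truth.mask)
            mask_t1 = segment_volume(pair, box, scfg)
            dices.append(dice(mask_t1.mask, truth.mask))
        else:
            mask_t1 = truth
            dices.append(1.0)
        mask_t2 = map_mask(mask_t1, pair.affine_t1c, pair.affine_t2,
                           pair.volume_t2.shape)
        vec = extract_feature_vector(pair, mask_t1, mask_t2, fcfg)
        rows.append(vec)
    table = pd.DataFrame(rows, index=covariates["patient_id"]).reset_index(
        names="patient_id")
    return table, dices


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    The run directory contains the frozen config, the covariate and
    feature tables, per-patient scores, the selected-feature list, ROC
    and survival tables, and a machine-readable ``summary.json``.  All
    randomness derives from ``config.seed``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed, "n_patients": config.n_patients}

    try:
        t0 = time.perf_counter()
        if config.simulate:
            patients, covariates = simulate_cohort(config.n_patients, seed=config.seed)
        else:
            if not config.input_dir:
                raise StageError("simulate: disabled but no input_dir given")
            patients, covariates = _load_cohort(Path(config.input_dir))
        covariates.to_csv(out / "covariates.csv", index=False)
        log.info("cohort stage done in %.1fs (n=%d, sha256=%s)",
                 time.perf_counter() - t0, len(patients),
                 _sha256(out / "covariates.csv")[:12])
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        log.error("cohort stage failed: %s", exc)
        raise StageError(f"cohort: {exc}") from exc

    try:
        t0 = time.perf_counter()
        if config.extract:
            features, dices = compute_feature_table(patients, covariates, config)
            features.to_csv(out / "features.csv", index=False)
            summary["n_features"] = features.shape[1] - 1
            summary["dice_mean"] = round(float(np.mean(dices)), 4)
            summary["dice_min"] = round(float(np.min(dices)), 4)
            log.info("extract stage done in %.1fs", time.perf_counter() - t0)
        else:
            features = pd.read_csv(Path(config.input_dir) / "features.csv")
            dices = []
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        log.error("extract stage failed: %s", exc)
        raise StageError(f"extract: {exc}") from exc

    names = feature_names()
    X = features[names].to_numpy()
    y = covariates["event"].to_numpy().astype(int)
    if not (config.select or config.evaluate):
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        log.removeHandler(handler)
        handler.close()
        return out

    # keep folds stratifiable on small cohorts
    k_folds = int(min(config.k_folds, np.bincount(y).min()))
    if k_folds < config.k_folds:
        log.info("k_folds clamped to smallest class size (%d)", k_folds)
    if k_folds < 2:
        raise StageError("select: fewer than 2 patients in one outcome class")

    try:
        t0 = time.perf_counter()
        if config.select:
            sel_cfg = SelectionConfig(
                k_folds=k_folds, n_repeats=config.n_repeats,
                max_features=config.max_features,
                min_improvement=config.min_improvement, C=config.C,
                metric=config.objective, seed=config.seed)
            selected, trace, model = sequential_forward_selection(X, y, sel_cfg)
        else:
            selected = list(range(min(config.max_features, X.shape[1])))
            trace = None
        selected_names = [names[j] for j in selected]
        (out / "selected_features.json").write_text(json.dumps({
            "indices": selected, "names": selected_names,
            "objective": trace.objective if trace else None}, indent=2))
        summary["selected_features"] = selected_names
        log.info("select stage done in %.1fs: %s",
                 time.perf_counter() - t0, selected_names)

        if config.scoring == "cv":
            scores = cross_validated_scores(X, y, selected, k_folds=k_folds,
                                            C=config.C, seed=config.seed)
        else:
            scores = refit_scores(X, y, selected, C=config.C)
        pd.DataFrame({"patient_id": covariates["patient_id"],
                      "svm_score": np.round(scores, 6)}).to_csv(
            out / "scores.csv", index=False)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        log.error("select stage failed: %s", exc)
        raise StageError(f"select: {exc}") from exc

    if config.evaluate:
        try:
            t0 = time.perf_counter()
            roc = roc_auc_and_cutoff(scores, y)
            summary["auc"] = round(roc.auc, 4)
            summary["cutoff"] = round(roc.cutoff, 4)
            summary["sensitivity"] = round(roc.sensitivity, 4)
            summary["specificity"] = round(roc.specificity, 4)

            cov = pd.DataFrame({
                "bone_invasion": covariates["bone_invasion"].astype(int),
                "low_adc": (covariates["adc_value"] < ADC_CUTOFF).astype(int),
                "high_score": (scores > roc.cutoff).astype(int),
                "str_resection": (covariates["resection_extent"] == "STR").astype(int),
            })
            constant = [c for c in cov.columns if cov[c].nunique() < 2]
            if constant:
                log.warning("dropping constant covariate(s) from Cox: %s", constant)
                cov = cov.drop(columns=constant)
            times = covariates["followup_time"].to_numpy()
            if not cov.empty:
                surv = cox_ph(cov, times, y, gate_p=config.gate_p, penalizer=0.1)
                surv.cox_table.to_csv(out / "cox.csv", index=False)

            km = km_logrank(times, y, (scores > roc.cutoff).astype(int))
            summary["logrank_stat"] = round(km.logrank_stat, 4)
            summary["logrank_p"] = round(km.logrank_p, 6)

            comp = cohort_table_stats(
                covariates.assign(svm_score=scores),
                group_col="event",
                categorical=("sex", "resection_extent", "bone_invasion"),
                continuous=("age", "adc_value", "svm_score"))
            comp.to_csv(out / "group_comparisons.csv", index=False)
            summary["event_fraction"] = round(float(y.mean()), 4)
            log.info("evaluate stage done in %.1fs (AUC=%.3f)",
                     time.perf_counter() - t0, roc.auc)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            log.error("evaluate stage failed: %s", exc)
            raise StageError(f"evaluate: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.removeHandler(handler)
    handler.close()
    return out
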