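"""End-to-end pipelines: laboratory model build and field-trial evaluation.

``run_lab_pipeline`` mirrors the laboratory protocol — simulate flight
recordings across the assay temperatures, clean them, extract spectrogram
features, undersample to a balanced dataset, set aside a stratified test
set, train the gradient-boosting classifier with fourfold CV, evaluate it,
then fit the Gaussian target-detection gate (projector, density, threshold
calibrated on a labeled target/non-target stream standing in for earlier
field campaigns).

``run_field_pipeline`` streams simulated field recordings through the gate
and, for TARGET calls, the genus × sex classifier; accumulates per-cycle
sensor counts; joins them with the simulated manual counts; and runs the
full count-based evaluation (per-cycle BA, summaries, Pearson correlation,
regression in both orientations, diel activity profiles).

Every run writes a manifest (seed, config hash, library versions) so the
outputs are re-derivable bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field as dc_field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import classify, detect, features, fieldeval, simulate
from .types import TARGET_CLASSES, ClassLabel, FieldScenario, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSettings",
    "FeatureSettings",
    "ClassifierSettings",
    "DetectionSettings",
    "PipelineConfig",
    "LabPipelineResult",
    "FieldPipelineResult",
    "run_lab_pipeline",
    "run_field_pipeline",
    "load_config",
    "make_manifest",
]


@dataclass(frozen=True)
class SimulationSettings:
    total_flights: int = 15208
    invalid_fraction: float = 0.075
    noise_sd: float = 0.02
    duration: float = simulate.DEFAULT_DURATION
    sample_rate: float = simulate.DEFAULT_SAMPLE_RATE
    calibration_per_group: int = 500  # target/non-target events for threshold tuning


@dataclass(frozen=True)
class FeatureSettings:
    window_length: int = 256
    overlap: float = 0.5
    max_freq: float = 2000.0

    def spectrogram_config(self) -> features.SpectrogramConfig:
        return features.SpectrogramConfig(
            window_length=self.window_length,
            overlap=self.overlap,
            max_freq=self.max_freq,
        )


@dataclass(frozen=True)
class ClassifierSettings:
    n_test: int = 1000
    n_folds: int = 4
    grid: tuple = classify.DEFAULT_GRID


@dataclass(frozen=True)
class DetectionSettings:
    n_components: int = 8
    ridge: Optional[float] = None
    threshold: Optional[float] = None  # None -> calibrate


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    simulation: SimulationSettings = dc_field(default_factory=SimulationSettings)
    features: FeatureSettings = dc_field(default_factory=FeatureSettings)
    classifier: ClassifierSettings = dc_field(default_factory=ClassifierSettings)
    detection: DetectionSettings = dc_field(default_factory=DetectionSettings)
    outdir: Optional[str] = None


_SECTION_TYPES = {
    "simulation": SimulationSettings,
    "features": FeatureSettings,
    "classifier": ClassifierSettings,
    "detection": DetectionSettings,
}


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Read a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            known = cls.__dataclass_fields__.keys()
            unknown = set(value) - set(known)
            if unknown:
                raise ValueError(f"unknown keys in [{key}]: {sorted(unknown)}")
            kwargs[key] = cls(**value)
        elif key in ("seed", "outdir"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config section: {key}")
    return PipelineConfig(**kwargs)


def make_manifest(config: PipelineConfig, seed: int) -> dict:
    import sklearn
    import xgboost

    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": json.loads(blob),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
    }


def _distribute_flights(total: int) -> dict[tuple[ClassLabel, float], int]:
    """Spread a flight budget as evenly as possible over the 14 assay cells."""
    cells = [
        (label, temp)
        for label in TARGET_CLASSES
        for temp in simulate.LAB_TEMPERATURES[label]
    ]
    base, extra = divmod(total, len(cells))
    return {cell: base + (1 if i < extra else 0) for i, cell in enumerate(cells)}


@dataclass
class LabPipelineResult:
    report: classify.ClassifierReport
    model: classify.TrainedModel
    projector: detect.FeatureProjector
    density: detect.DensityModel
    threshold: detect.DetectionThreshold
    n_recorded: int
    n_valid: int
    n_balanced: int
    n_test: int
    cleaning_confusion: dict[str, int]
    manifest: dict


def run_lab_pipeline(
    config: PipelineConfig,
    seed: Optional[int] = None,
    params: Optional[Mapping[ClassLabel, object]] = None,
) -> LabPipelineResult:
    """Simulate, clean, featurize, balance, split, train, evaluate, fit gate."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_sim, rng_bal, rng_split, rng_cal = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    sim = config.simulation
    spec_cfg = config.features.spectrogram_config()

    logger.info("simulating %d laboratory flights", sim.total_flights)
    recordings = simulate.simulate_lab_dataset(
        _distribute_flights(sim.total_flights),
        invalid_fraction=sim.invalid_fraction,
        rng_seed=rng_sim,
        params=params,
        duration=sim.duration,
        sample_rate=sim.sample_rate,
        noise_sd=sim.noise_sd,
    )

    verdicts = [features.clean_recording(r) for r in recordings]
    valid = [r for r, v in zip(recordings, verdicts) if v.valid]
    cleaning_confusion = {
        "kept_truly_valid": sum(
            v.valid and r.validity.value == "VALID"
            for r, v in zip(recordings, verdicts)
        ),
        "kept_truly_invalid": sum(
            v.valid and r.validity.value != "VALID"
            for r, v in zip(recordings, verdicts)
        ),
        "rejected_truly_invalid": sum(
            (not v.valid) and r.validity.value != "VALID"
            for r, v in zip(recordings, verdicts)
        ),
        "rejected_truly_valid": sum(
            (not v.valid) and r.validity.value == "VALID"
            for r, v in zip(recordings, verdicts)
        ),
    }
    logger.info("cleaning kept %d of %d recordings", len(valid), len(recordings))

    table = features.extract_feature_table(valid, spec_cfg)
    X = features.feature_matrix(table)
    data = classify.LabeledDataset(
        features=X,
        labels=table["label"].to_numpy(),
        temperature=table["temperature"].to_numpy(float),
    )

    balanced = classify.balance_by_undersampling(data, rng_bal)
    train, test = classify.split_test_set(balanced, config.classifier.n_test, rng_split)
    model = classify.train_classifier(
        train,
        n_folds=config.classifier.n_folds,
        grid=config.classifier.grid,
        rng_seed=seed % (2**31),
    )
    report = classify.evaluate_classifier(model, test)
    logger.info("test mean BA %.1f%%", report.mean_ba)

    det = config.detection
    projector = detect.FeatureProjector.fit(train.features, det.n_components)
    density = detect.fit_density(projector.transform(train.features), ridge=det.ridge)

    if det.threshold is not None:
        threshold = detect.DetectionThreshold(value=det.threshold)
    else:
        threshold = _calibrate_on_synthetic_stream(
            config, projector, density, rng_cal, params
        )
    logger.info(
        "detection threshold %.3f (calibration BA %s)",
        threshold.value,
        threshold.calibration_ba,
    )

    result = LabPipelineResult(
        report=report,
        model=model,
        projector=projector,
        density=density,
        threshold=threshold,
        n_recorded=len(recordings),
        n_valid=len(valid),
        n_balanced=len(balanced),
        n_test=len(test),
        cleaning_confusion=cleaning_confusion,
        manifest=make_manifest(config, seed),
    )
    if config.outdir:
        _write_lab_artifacts(result, Path(config.outdir))
    return result


def _calibrate_on_synthetic_stream(
    config: PipelineConfig,
    projector: detect.FeatureProjector,
    density: detect.DensityModel,
    rng: np.random.Generator,
    params,
) -> detect.DetectionThreshold:
    """Labeled target/non-target stream standing in for earlier field data."""
    sim = config.simulation
    n = sim.calibration_per_group
    recs: list[Recording] = []
    is_target = []
    for i in range(n):
        label = TARGET_CLASSES[i % 4]
        recs.append(
            simulate.simulate_flight_waveform(
                label,
                temperature=float(rng.uniform(16, 32)),
                params=params,
                duration=sim.duration,
                sample_rate=sim.sample_rate,
                noise_sd=sim.noise_sd,
                rng_seed=rng,
            )
        )
        is_target.append(True)
    for _ in range(n):
        recs.append(
            simulate.simulate_flight_waveform(
                ClassLabel.NON_TARGET,
                temperature=float(rng.uniform(16, 32)),
                params=params,
                duration=sim.duration,
                sample_rate=sim.sample_rate,
                noise_sd=sim.noise_sd,
                rng_seed=rng,
            )
        )
        is_target.append(False)
    table = features.extract_feature_table(recs, config.features.spectrogram_config())
    Z = projector.transform(features.feature_matrix(table))
    return detect.calibrate_threshold(density, Z, np.array(is_target))


def _write_lab_artifacts(result: LabPipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        result.report.confusion,
        index=[c.value for c in TARGET_CLASSES],
        columns=[c.value for c in TARGET_CLASSES],
    ).to_csv(outdir / "lab_confusion.csv")
    with open(outdir / "lab_report.json", "w") as fh:
        json.dump(
            {
                "mean_ba_pct": result.report.mean_ba,
                "per_class_ba_pct": result.report.per_class_ba,
                "n_recorded": result.n_recorded,
                "n_valid": result.n_valid,
                "n_balanced": result.n_balanced,
                "n_test": result.n_test,
                "cv_results": result.model.cv_results,
                "best_params": result.model.best_params,
                "cleaning_confusion": result.cleaning_confusion,
            },
            fh,
            indent=2,
        )
    detect.save_density(
        result.density, outdir / "density", result.threshold, result.projector
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


@dataclass
class FieldPipelineResult:
    cycles: list[fieldeval.CycleCounts]
    detection_table: pd.DataFrame
    detection_summary: Optional[fieldeval.SummaryStats]
    genus_sex_table: pd.DataFrame
    genus_sex_per_class: dict[ClassLabel, fieldeval.SummaryStats]
    genus_sex_pooled: Optional[fieldeval.SummaryStats]
    genus_sex_overall_ba: Optional[float]
    correlation: Optional[fieldeval.CorrelationResult]
    regression_sensor_on_manual: Optional[fieldeval.RegressionResult]
    regression_manual_on_sensor: Optional[fieldeval.RegressionResult]
    activity_profile: pd.DataFrame
    reconciliation: dict[str, int]
    errors: dict[str, str]
    manifest: dict


def run_field_pipeline(
    config: PipelineConfig,
    scenario: FieldScenario,
    model: classify.TrainedModel,
    projector: detect.FeatureProjector,
    density: detect.DensityModel,
    threshold: detect.DetectionThreshold,
    seed: Optional[int] = None,
    params: Optional[Mapping[ClassLabel, object]] = None,
) -> FieldPipelineResult:
    """Stream simulated field recordings through the gate and classifier."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    sim = config.simulation
    spec_cfg = config.features.spectrogram_config()

    stream, truth = simulate.simulate_field_trial(
        scenario,
        rng_seed=rng,
        params=params,
        duration=sim.duration,
        sample_rate=sim.sample_rate,
        noise_sd=sim.noise_sd,
    )
    logger.info("field stream: %d recordings over %d cycles", len(stream), len(truth))

    sensor: dict[str, dict[ClassLabel, int]] = {
        c.cycle_id: {cls: 0 for cls in TARGET_CLASSES} for c in truth
    }
    sensor_total: dict[str, int] = {c.cycle_id: 0 for c in truth}
    recon = {
        "received": len(stream),
        "out_of_cycle": 0,
        "gated_non_target": 0,
        "classified_target": 0,
    }

    starts = [c.start for c in scenario.cycles]
    if stream:
        table = features.extract_feature_table(stream, spec_cfg)
        X = features.feature_matrix(table)
        Z = projector.transform(X)
        is_target_call = np.asarray(detect.classify_target(density, threshold, Z))
        pred_labels = model.predict(X)
    else:
        is_target_call = np.zeros(0, bool)
        pred_labels = np.zeros(0, str)

    for rec, called, pred in zip(stream, is_target_call, pred_labels):
        idx = int(np.searchsorted(np.array(starts), rec.timestamp, side="right")) - 1
        cycle = scenario.cycles[idx] if 0 <= idx < len(scenario.cycles) else None
        if cycle is None or not cycle.contains(rec.timestamp):
            recon["out_of_cycle"] += 1
            continue
        if not called:
            recon["gated_non_target"] += 1
            continue
        recon["classified_target"] += 1
        sensor[cycle.cycle_id][ClassLabel(pred)] += 1
        sensor_total[cycle.cycle_id] += 1

    cycles = []
    for t in truth:
        cycles.append(
            fieldeval.CycleCounts(
                cycle_id=t.cycle_id,
                start=t.start,
                end=t.end,
                manual=dict(t.manual),
                manual_nontarget=t.manual_nontarget,
                sensor=sensor[t.cycle_id],
                sensor_target_total=sensor_total[t.cycle_id],
                excluded=t.excluded,
                exclusion_reason=t.exclusion_reason,
            )
        )

    # degenerate streams (no captures, zero-variance counts) must not crash
    # the pipeline; each failing statistic is reported by stage name instead
    errors: dict[str, str] = {}

    def attempt(stage, fn, default=None):
        try:
            return fn()
        except (ValueError, KeyError) as exc:
            errors[stage] = str(exc)
            logger.warning("%s: %s", stage, exc)
            return default

    det_table, det_summary = pd.DataFrame(), None
    out = attempt("target_detection", lambda: fieldeval.evaluate_target_detection(cycles))
    if out is not None:
        det_table, det_summary = out
    gs_table, gs_per_class, gs_pooled, gs_overall = pd.DataFrame(), {}, None, None
    out = attempt("genus_sex", lambda: fieldeval.evaluate_genus_sex(cycles))
    if out is not None:
        gs_table, gs_per_class, gs_pooled, gs_overall = out
    corr = attempt(
        "correlation",
        lambda: fieldeval.pearson_correlation(det_table["sensor"], det_table["manual"]),
    )
    reg_sm = attempt(
        "regression_sensor_on_manual",
        lambda: fieldeval.linear_regression(det_table["sensor"], det_table["manual"]),
    )
    reg_ms = attempt(
        "regression_manual_on_sensor",
        lambda: fieldeval.linear_regression(det_table["manual"], det_table["sensor"]),
    )

    events = pd.DataFrame(
        {
            "timestamp": [r.timestamp for r in stream],
            "genus": [
                ClassLabel(p).genus if c else None
                for r, c, p in zip(stream, is_target_call, pred_labels)
            ],
        }
    ).dropna()
    profile = fieldeval.compute_activity_profile(
        events, scenario.cycles[0].start, scenario.cycles[-1].end
    )

    result = FieldPipelineResult(
        cycles=cycles,
        detection_table=det_table,
        detection_summary=det_summary,
        genus_sex_table=gs_table,
        genus_sex_per_class=gs_per_class,
        genus_sex_pooled=gs_pooled,
        genus_sex_overall_ba=gs_overall,
        correlation=corr,
        regression_sensor_on_manual=reg_sm,
        regression_manual_on_sensor=reg_ms,
        activity_profile=profile,
        reconciliation=recon,
        errors=errors,
        manifest=make_manifest(config, seed),
    )
    if config.outdir:
        _write_field_artifacts(result, Path(config.outdir))
    return result


def _write_field_artifacts(result: FieldPipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fieldeval.write_cycle_counts(result.cycles, outdir / "cycle_counts.csv")
    result.detection_table.to_csv(outdir / "detection_per_cycle.csv", index=False)
    result.genus_sex_table.to_csv(outdir / "genus_sex_per_cycle.csv", index=False)
    result.activity_profile.to_csv(outdir / "activity_profile.csv", index=False)
    with open(outdir / "field_summary.json", "w") as fh:
        json.dump(
            {
                "target_detection": result.detection_summary.as_dict()
                if result.detection_summary
                else None,
                "genus_sex_per_class": {
                    c.value: s.as_dict()
                    for c, s in result.genus_sex_per_class.items()
                },
                "genus_sex_pooled": result.genus_sex_pooled.as_dict()
                if result.genus_sex_pooled
                else None,
                "genus_sex_overall_ba_pct": result.genus_sex_overall_ba,
                "pearson_r": result.correlation.r if result.correlation else None,
                "pearson_p": result.correlation.p_value if result.correlation else None,
                "regression_sensor_on_manual": asdict(result.regression_sensor_on_manual)
                if result.regression_sensor_on_manual
                else None,
                "regression_manual_on_sensor": asdict(result.regression_manual_on_sensor)
                if result.regression_manual_on_sensor
                else None,
                "reconciliation": result.reconciliation,
                "errors": result.errors,
            },
            fh,
            indent=2,
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
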