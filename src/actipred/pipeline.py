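"""End-to-end orchestration: data -> forecaster -> classifier -> reports.

``run_hap_pipeline`` trains a forecaster on the observed->future epoch pairs
and a classifier on the *measured* future halves only (the classifier is
pre-trained, never sees forecasts), then reports three things on the
held-out split:

* forecast quality (per-activity RMSE / Pearson correlation),
* classification of measured future halves (recognition reference),
* classification of forecasted future halves (activity prediction).

All randomness is keyed off one seed; report files contain no timestamps,
so a rerun with the same config reproduces them byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifier import (
    ClassifierSpec,
    ClassifierTrainConfig,
    build_classifier,
    fit_classifier,
)
from .forecasters import (
    ForecasterSpec,
    TrainConfig,
    build_forecaster,
    fit_forecaster,
    forecast,
)
from .metrics import classification_report, forecast_report
from .serialize import save_model
from .synthetic import SyntheticDatasetConfig, HapDataset, generate_hap_dataset

log = logging.getLogger("actipred")


@dataclass
class PipelineConfig:
    """One object describing a full run; round-trips through YAML."""

    seed: int = 0
    output_dir: str = "hap_run"
    dataset: SyntheticDatasetConfig = field(default_factory=SyntheticDatasetConfig)
    forecaster: ForecasterSpec = field(default_factory=ForecasterSpec)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    forecaster_train: TrainConfig = field(default_factory=TrainConfig)
    classifier_train: ClassifierTrainConfig = field(
        default_factory=ClassifierTrainConfig
    )
    val_frac: float = 0.15
    save_checkpoints: bool = True


def split_validation(pairs, label_names, val_frac: float):
    """Carve the chronologically last ``val_frac`` of each class's training
    pairs into a validation set for best-checkpoint selection."""
    if val_frac <= 0:
        return list(pairs), []
    fit, val = [], []
    for name in label_names:
        cls = [p for p in pairs if p.label == name]
        k = max(1, int(round(val_frac * len(cls)))) if len(cls) > 1 else 0
        fit.extend(cls[: len(cls) - k])
        val.extend(cls[len(cls) - k:])
    return fit, val


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_hap_pipeline(config: PipelineConfig,
                     dataset: HapDataset | None = None) -> dict:
    """Execute the full pipeline and write reports to ``config.output_dir``.

    Returns a dict with keys ``forecast`` (per-activity RMSE/CORR),
    ``classification_measured`` and ``classification_forecast`` (the
    recognition-vs-prediction comparison), plus loss histories.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    seed = config.seed
    stage = "synthesize dataset"
    try:
        if dataset is None:
            dataset = generate_hap_dataset(config.dataset, seed=seed)
        log.info("%s: %d train / %d test pairs (%.1fs)", stage,
                 len(dataset.train), len(dataset.test), time.time() - t0)

        stage = "train forecaster"
        fit_pairs, val_pairs = split_validation(
            dataset.train, dataset.label_names, config.val_frac
        )
        fmodel = build_forecaster(config.forecaster, seed=seed)
        ft_cfg = dataclasses.replace(config.forecaster_train, seed=seed)
        fhist = fit_forecaster(fmodel, fit_pairs, ft_cfg,
                               val_pairs=val_pairs or None)
        log.info("%s: final loss %.5f (%.1fs)", stage, fhist[-1], time.time() - t0)

        stage = "train classifier"
        Xtr, Ytr, ytr = dataset.arrays("train")
        cmodel = build_classifier(config.classifier, seed=seed + 1,
                                  label_names=dataset.label_names)
        ct_cfg = dataclasses.replace(config.classifier_train, seed=seed)
        # trained on measured future halves only, never on forecasts
        chist = fit_classifier(cmodel, Ytr, ytr, ct_cfg)
        log.info("%s: final loss %.5f (%.1fs)", stage, chist[-1], time.time() - t0)

        stage = "forecast test epochs"
        Xte, Yte, yte = dataset.arrays("test")
        fc = forecast(fmodel, Xte)
        fc_clipped = np.clip(fc, -1.0, 1.0)
        f_report = forecast_report(dataset.test, list(fc))
        log.info("%s: mean CORR %.3f, mean RMSE %.3f (%.1fs)", stage,
                 f_report["mean_corr"], f_report["mean_rmse"], time.time() - t0)

        stage = "classify"
        n_cls = len(dataset.label_names)
        pred_meas = np.argmax(cmodel.predict_proba(Yte), axis=-1)
        pred_fc = np.argmax(cmodel.predict_proba(fc_clipped), axis=-1)
        rep_meas = classification_report(yte, pred_meas, n_cls, dataset.label_names)
        rep_fc = classification_report(yte, pred_fc, n_cls, dataset.label_names)
        log.info("%s: measured acc %.3f, forecast acc %.3f (%.1fs)", stage,
                 rep_meas.accuracy, rep_fc.accuracy, time.time() - t0)

        stage = "write artifacts"
        _write_json(out / "forecast_report.json", f_report)
        _write_json(out / "classification_measured.json", rep_meas.to_dict())
        _write_json(out / "classification_forecast.json", rep_fc.to_dict())
        _write_json(out / "loss_history.json",
                    {"forecaster": fhist, "classifier": chist})
        if config.save_checkpoints:
            save_model(fmodel, out / "forecaster.npz")
            save_model(cmodel, out / "classifier.npz")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return {
        "forecast": f_report,
        "classification_measured": rep_meas.to_dict(),
        "classification_forecast": rep_fc.to_dict(),
        "loss_history": {"forecaster": fhist, "classifier": chist},
        "models": {"forecaster": fmodel, "classifier": cmodel},
    }
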