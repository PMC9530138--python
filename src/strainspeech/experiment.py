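"""End-to-end experiment runner: simulate/load -> preprocess -> train ->
cross-validate -> write artifacts.

Artifacts written to the output directory:

* ``report.json`` — fold accuracies, confusion matrix, baseline accuracies,
  all stage seeds, the config echo and its hash, and a timestamp (the only
  non-deterministic field; two runs with the same config are byte-identical
  once it is stripped).
* ``confusion.csv`` — pooled confusion matrix with class-label headers.
* ``model.npz`` — checkpoint of the model trained on the full dataset.
* ``run.log`` — stage-by-stage log including every seed.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (Conv3DWordClassifier, CorrelationWordClassifier,
                       SVMWordClassifier, save_checkpoint)
from .config import RunConfig, config_hash
from .datasets import read_dataset
from .evaluate import EvalReport, cross_validate
from .preprocess import SignalPreprocessor
from .simulate import synth_dataset

__all__ = ["run_experiment", "strip_timestamp"]


def _cnn_factory(cfg: RunConfig):
    m = cfg.model
    return lambda: Conv3DWordClassifier(
        conv_channels=m.conv_channels, fc_sizes=m.fc_sizes,
        axis_order=m.axis_order, learning_rate=m.learning_rate,
        batch_size=m.batch_size, epochs=m.epochs, random_state=cfg.model_seed)


def run_experiment(config: RunConfig, out_dir, *,
                   write_artifacts: bool = True) -> EvalReport:
    """Run the configured pipeline and return the CNN cross-validation report."""
    out = Path(out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    chash = config_hash(config)
    log("config", f"hash={chash} seed={config.seed}")

    if config.dataset_path is not None:
        records, _ = read_dataset(config.dataset_path)
        log("data", f"loaded {len(records)} records from {config.dataset_path}")
    else:
        records = synth_dataset(config.sim)
        log("data", f"simulated {len(records)} records (sim_seed={config.sim_seed})")

    # PreprocessConfig fields map 1:1 onto the transformer's parameters
    pre = SignalPreprocessor(
        savgol_window=config.preprocess.savgol_window,
        savgol_polyorder=config.preprocess.savgol_polyorder,
        normalize_first=config.preprocess.normalize_first,
        out_len=config.preprocess.out_len,
        out_duration=config.preprocess.out_duration,
        in_rate=config.preprocess.in_rate)
    X = pre.fit_transform(records)
    y = np.array([r.class_id for r in records])
    log("preprocess", f"tensors {X.shape}")

    factory = _cnn_factory(config)
    report = cross_validate(factory, X, y, k=config.eval.k,
                            seed=config.eval_seed,
                            config={"model": config.model.to_dict(),
                                    "eval": config.eval.to_dict()})
    log("evaluate", f"cnn mean accuracy {report.mean_accuracy:.2f}% "
                    f"(eval_seed={config.eval_seed})")

    baselines = {}
    if config.eval.run_baselines:
        for name, make in (("svm", lambda: SVMWordClassifier()),
                           ("correlation", lambda: CorrelationWordClassifier())):
            rep = cross_validate(make, X, y, k=config.eval.k, seed=config.eval_seed)
            baselines[name] = rep.mean_accuracy
            log("evaluate", f"{name} mean accuracy {rep.mean_accuracy:.2f}%")

    final_model = factory().fit(X, y)
    classes = [int(c) for c in np.unique(y)]

    if write_artifacts:
        save_checkpoint(final_model, out / "model.npz")
        conf = pd.DataFrame(report.confusion,
                            index=[f"true_{c}" for c in classes],
                            columns=[f"pred_{c}" for c in classes])
        conf.to_csv(out / "confusion.csv")
        doc = {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "config_hash": chash,
            "config": config.to_dict(),
            "seeds": {"global": config.seed, "sim": config.sim_seed,
                      "model": config.model_seed, "eval": config.eval_seed},
            "cnn": report.to_dict(),
            "baselines": baselines,
        }
        (out / "report.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report


def strip_timestamp(report_json: str) -> str:
    """Canonical form of a report document with the timestamp removed."""
    doc = json.loads(report_json)
    doc.pop("timestamp", None)
    return json.dumps(doc, sort_keys=True)
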