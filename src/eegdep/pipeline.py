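"""End-to-end orchestration: cohort -> selection -> comparison -> training -> reports.

``run_pipeline`` executes the four pipeline stages in order on either a
directory of EDF/FIF recordings or a synthetic cohort spec, writing every
artifact (selection report, CV tables, classifier comparison, checkpoints,
evaluation reports, manifest) into a run directory. Reruns with the same
config and seed reproduce the same numbers.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ModelSpec,
    TrainConfig,
    build_model,
    compare_classifiers,
    save_checkpoint,
    train_model,
)
from .evaluate import evaluate_predictions
from .features import feature_table
from .io import Recording, read_recording
from .preprocess import preprocess_recording
from .select import SelectionConfig, SelectionReport, run_selection
from .synth import CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_cohort"]

log = logging.getLogger("eegdep")

DEFAULT_SPEC_KINDS = ("LR", "SVM_RBF", "MLP", "CNN", "LSTM", "CNNGRU")


@dataclass
class PipelineConfig:
    """One input source (files xor synthetic spec) plus stage parameters."""

    synthetic: CohortSpec | None = None
    input_dir: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    compare_train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=30))
    classifier_kinds: tuple[str, ...] = DEFAULT_SPEC_KINDS
    final_kinds: tuple[str, ...] = ("LSTM", "CNNGRU")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("config needs exactly one of synthetic or input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            kwargs["synthetic"] = CohortSpec(**kwargs["synthetic"])
        if "selection" in kwargs:
            kwargs["selection"] = SelectionConfig(**kwargs["selection"])
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if "compare_train" in kwargs:
            kwargs["compare_train"] = TrainConfig(**kwargs["compare_train"])
        for key in ("classifier_kinds", "final_kinds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def load_cohort(config: PipelineConfig) -> list[Recording]:
    if config.synthetic is not None:
        return generate_cohort(config.synthetic)
    paths = sorted(Path(config.input_dir).glob("*.edf")) + sorted(
        Path(config.input_dir).glob("*.fif")
    )
    if not paths:
        raise FileNotFoundError(f"no EDF/FIF files under {config.input_dir}")
    return [read_recording(p) for p in paths]


def _selected_matrix(cohort, selection: SelectionReport, feats):
    X_rows, y_rows = [], []
    for rec in cohort:
        windows = preprocess_recording(rec, selection.span, selection.electrodes)
        table = feature_table(windows, features=feats)
        X_rows.append(table[feats].to_numpy())
        y_rows.append(table["y"].to_numpy())
    return np.vstack(X_rows), np.concatenate(y_rows)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run all four stages; returns the run directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    log.info("stage 1/4: loading cohort")
    cohort = load_cohort(config)
    log.info("cohort: %d subjects, %d channels", len(cohort), len(cohort[0].channel_names))

    log.info("stage 1-2/4: span/region/feature selection")
    selection = run_selection(cohort, config.selection)
    selection.to_json(out / "selection.json")
    for name in ("span_table", "region_table", "combination_table"):
        pd.DataFrame(getattr(selection, name)).T.to_csv(out / f"{name}.csv")
    log.info(
        "selected span=%ss region=%r combination=%s",
        selection.span,
        selection.region,
        selection.combination,
    )

    feats = selection.combination_features
    X, y = _selected_matrix(cohort, selection, feats)

    log.info("stage 2/4: classifier comparison on %d windows", X.shape[0])
    specs = [ModelSpec(kind=k, seed=config.seed) for k in config.classifier_kinds]
    results, pmat = compare_classifiers(
        X, y, specs, k=config.selection.k_folds, seed=config.seed,
        train_config=config.compare_train,
    )
    pd.DataFrame(
        {
            "classifier": [r.unit for r in results],
            "mean_accuracy": [r.mean for r in results],
            "sd": [r.sd for r in results],
        }
    ).to_csv(out / "classifier_comparison.csv", index=False)
    pmat.to_csv(out / "classifier_pvalues.csv")

    log.info("stage 3/4: training final models")
    reports = {}
    for kind in config.final_kinds:
        model = build_model(ModelSpec(kind=kind, seed=config.seed))
        train_model(model, X, y, config.train)
        ckpt = save_checkpoint(model, out / f"{kind.lower()}_checkpoint")
        proba = model.predict_proba(X)[:, list(model.classes_).index(1)]
        report = evaluate_predictions(y, proba)
        report.to_json(out / f"{kind.lower()}_eval.json")
        reports[kind] = report
        log.info("%s: in-sample accuracy %.4f auc %.4f (%s)", kind, report.accuracy, report.auc, ckpt)

    manifest = {
        "package_version": __version__,
        "config": _config_dict(config),
        "elapsed_s": round(time.time() - t_start, 2),
        "n_subjects": len(cohort),
        "selected": {
            "span": selection.span,
            "region": selection.region,
            "combination": selection.combination,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
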