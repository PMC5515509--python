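"""End-to-end orchestration: signal → features → staging → report.

:func:`run_pipeline` chains preprocessing, SEF + MSFE feature extraction,
cross-validated SVM staging and agreement scoring for a single channel,
and (optionally) writes every artefact a rerun needs: the feature table,
the predicted hypnogram, the JSON report, the resolved configuration and
a log of the epoch bookkeeping (generated → amplitude-rejected →
missing-feature → classified).  Runs are deterministic given the seeds in
the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import TASKS, CVConfig, TaskSpec, collapse_labels, cross_validate
from .complexity import FEParams, msfe_feature_vector
from .containers import Hypnogram, Recording
from .errors import InputError
from .metrics import EvalReport
from .preprocess import EpochSet, PreprocessConfig, preprocess_for_classification
from .signal_io import (
    FEATURE_NAMES,
    write_features,
    write_hypnogram,
)
from .spectral import sef_feature_vector
from .synthetic import GeneratorConfig, generate_recording

logger = logging.getLogger("earsleep")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for one pipeline run (YAML round-trippable)."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fe_params: FEParams = field(default_factory=FEParams)
    cv: CVConfig = field(default_factory=CVConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    task: str = "four_class"
    channel: str | None = None  # None: first channel

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise InputError(
                f"unknown task {self.task!r}; expected one of {sorted(TASKS)}"
            )

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {
                    f.name: plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .synthetic import SpindleParams, StageParams

        d = dict(d)
        if "preprocess" in d:
            pp = dict(d["preprocess"])
            for key in ("scoring_band", "classify_band"):
                if key in pp:
                    pp[key] = tuple(pp[key])
            d["preprocess"] = PreprocessConfig(**pp)
        if "fe_params" in d:
            d["fe_params"] = FEParams(**d["fe_params"])
        if "cv" in d:
            d["cv"] = CVConfig(**d["cv"])
        if "generator" in d:
            gen = dict(d["generator"])
            if "stage_params" in gen:
                params = {}
                for stage, sp in gen["stage_params"].items():
                    sp = dict(sp)
                    if sp.get("spindles") is not None:
                        sp["spindles"] = SpindleParams(**sp["spindles"])
                    params[stage] = StageParams(**sp)
                gen["stage_params"] = params
            d["generator"] = GeneratorConfig(**gen)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="ascii") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="ascii") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    """Everything one run produces, plus the epoch bookkeeping."""

    features: pd.DataFrame
    predicted_hypnogram: Hypnogram
    report: EvalReport
    kept_mask: np.ndarray
    n_epochs_total: int
    n_rejected: int
    n_missing_features: int


def extract_features(
    epochset: EpochSet, fe_params: FEParams = FEParams()
) -> pd.DataFrame:
    """30 named features (15 SEF + 15 MSFE) per surviving epoch.

    The frame is indexed by the epoch's original (pre-rejection) index.
    """
    rows = []
    for ep in epochset.epochs:
        row = sef_feature_vector(ep)
        row.update(msfe_feature_vector(ep, fe_params))
        rows.append(row)
    frame = pd.DataFrame(rows, index=epochset.kept_indices, columns=FEATURE_NAMES)
    frame.index.name = "epoch_index"
    return frame


def run_pipeline(
    config: PipelineConfig,
    recording: Recording | None = None,
    hypnogram: Hypnogram | None = None,
    stage_sequence: list[str] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute preprocess → features → classify → evaluate.

    Either pass a ``recording`` + ``hypnogram``, or a ``stage_sequence`` to
    simulate one with the configured generator and ``seed``.  When
    ``out_dir`` is given, the feature TSV, predicted hypnogram, JSON
    report and resolved YAML config are written there.
    """
    if recording is None:
        if stage_sequence is None:
            raise InputError(
                "need a recording + hypnogram, or a stage_sequence to simulate"
            )
        recording, hypnogram = generate_recording(
            stage_sequence, config.generator, seed=seed
        )
    if hypnogram is None:
        raise InputError("a hypnogram of true stages is required")

    channel = config.channel or recording.channel_labels[0]
    signal = recording.channel(channel)
    logger.info(
        "pipeline: channel=%s fs=%g Hz -> %g Hz, band=%s, reject=±%g µV (%s)",
        channel,
        recording.fs,
        config.preprocess.fs_target,
        config.preprocess.classify_band,
        config.preprocess.reject_threshold,
        config.preprocess.reject_stage,
    )

    epochset = preprocess_for_classification(
        signal, recording.fs, config.preprocess
    )
    n_total = epochset.n_total
    if n_total != len(hypnogram):
        raise InputError(
            f"recording yields {n_total} epochs but hypnogram has "
            f"{len(hypnogram)}"
        )
    n_rejected = n_total - len(epochset.epochs)
    logger.info(
        "amplitude rejection: %d of %d epochs removed (%.1f%%)",
        n_rejected,
        n_total,
        100.0 * n_rejected / n_total,
    )

    features = extract_features(epochset, config.fe_params)
    complete = ~features.isna().any(axis=1)
    n_missing = int((~complete).sum())
    if n_missing:
        logger.info("dropping %d epochs with missing features", n_missing)
    features_used = features[complete]

    labels_kept = [hypnogram.labels[i] for i in features_used.index]
    task = TASKS[config.task]
    y = collapse_labels(labels_kept, task)
    predictions, report = cross_validate(features_used, y, task, config.cv)

    # Encode each predicted class by its first member stage so the result
    # is a valid hypnogram; collapsing it under the same task recovers the
    # predicted class sequence exactly (for four_class this is the
    # identity).  Rejected / incomplete epochs stay UNSCORED.
    representative: dict[int, str] = {}
    for stage, cls in task.mapping:
        representative.setdefault(cls, stage)
    predicted_labels = ["UNSCORED"] * n_total
    for idx, pred in zip(features_used.index, predictions):
        predicted_labels[idx] = representative[int(pred)]
    predicted = Hypnogram(
        predicted_labels, epoch_duration=hypnogram.epoch_duration
    )

    table = features.copy()
    table.insert(0, "stage", [hypnogram.labels[i] for i in features.index])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_features(table, out_dir / "features.tsv")
        write_hypnogram(predicted, out_dir / "predicted_hypnogram.txt")
        report.to_json(out_dir / "report.json")
        config.to_yaml(out_dir / "config.yaml")
        bookkeeping = {
            "n_epochs_total": n_total,
            "n_rejected": n_rejected,
            "n_missing_features": n_missing,
            "n_classified": int(len(features_used)),
        }
        with open(out_dir / "bookkeeping.json", "w", encoding="ascii") as fh:
            json.dump(bookkeeping, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        features=table,
        predicted_hypnogram=predicted,
        report=report,
        kept_mask=epochset.kept_mask,
        n_epochs_total=n_total,
        n_rejected=n_rejected,
        n_missing_features=n_missing,
    )
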