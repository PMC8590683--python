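"""Model/Results interface for the full screening pipeline.

:class:`ApneaScreeningModel` is built from labeled training data (one
RRI series, event annotations, and subject record per training subject);
``fit()`` standardizes and segments every record, trains the per-segment
LSTM classifier, computes each training subject's AS ratio, calibrates
the borderline threshold, and returns an :class:`ApneaScreeningResults`
that screens new subjects, evaluates held-out cohorts, and prints a
summary table.

Example
-------
>>> from apneascreen import synthetic, model
>>> spec = synthetic.SyntheticCohortSpec(n_patients=2, n_healthy=2,
...                                      record_duration_s=3600, seed=1)
>>> cohort = synthetic.generate_cohort(spec)
>>> res = model.ApneaScreeningModel(cohort).fit()
>>> print(res.summary())                                # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import preprocessing, screening, sequence_model
from .io import EventAnnotation, RRISeries, SubjectRecord, ValidationError
from .preprocessing import SegmentSet

__all__ = ["ApneaScreeningModel", "ApneaScreeningResults"]

SubjectData = tuple[RRISeries, Sequence[EventAnnotation], SubjectRecord]


def prepare_segments(
    series: RRISeries,
    window_width_s: float,
    events: Sequence[EventAnnotation] | None = None,
    label_overlap_s: float = preprocessing.DEFAULT_LABEL_OVERLAP_S,
) -> SegmentSet:
    """Standardize, segment, and (when events are given) label one record."""
    standardized = preprocessing.standardize_rri(series)
    segset = preprocessing.segment_rri(series, standardized, window_width_s)
    if events is not None:
        segset = preprocessing.label_segments(segset, events, label_overlap_s)
    return segset


class ApneaScreeningModel:
    """Sleep-apnea screening model over a labeled training cohort.

    Parameters
    ----------
    train_data : sequence of (RRISeries, events, SubjectRecord)
        One entry per training subject.  Events provide the expert-style
        per-segment ground truth via the overlap rule.
    config : ModelConfig, optional
        Classifier hyperparameters (defaults: 32 units, 150 epochs, Adam
        lr 0.01, raw-RRI mode).
    window_width_s : float
        Segmentation window (default 60 s, the CVHR period).
    label_overlap_s : float
        Minimum apnea/hypopnea coverage for a segment to be labeled A.
    """

    def __init__(
        self,
        train_data: Sequence[SubjectData],
        config: sequence_model.ModelConfig | None = None,
        window_width_s: float = preprocessing.DEFAULT_WINDOW_WIDTH_S,
        label_overlap_s: float = preprocessing.DEFAULT_LABEL_OVERLAP_S,
    ):
        if not train_data:
            raise ValidationError("training cohort is empty")
        config = config or sequence_model.ModelConfig()
        # raw mode pads to 2 beats/s of window (RRI >= 0.5 s physiologically)
        wanted = int(round(2 * window_width_s))
        if config.mode == "raw_rri" and config.max_beats != wanted:
            config = replace(config, max_beats=wanted)
        self.config = config
        self.window_width_s = float(window_width_s)
        self.label_overlap_s = float(label_overlap_s)
        self.train_data = list(train_data)

    def fit(self) -> "ApneaScreeningResults":
        """Train the classifier and calibrate the screening threshold."""
        segsets = [
            prepare_segments(series, self.window_width_s, events, self.label_overlap_s)
            for series, events, _ in self.train_data
        ]
        subjects = [record for _, _, record in self.train_data]
        X, y = sequence_model.build_training_matrix(segsets, mode=self.config.mode)
        trained = sequence_model.train(X, y, self.config)

        ratios = []
        for segset in segsets:
            preds = sequence_model.predict(trained, segset)
            _, _, ratio = screening.as_ratio(preds, self.window_width_s)
            ratios.append(ratio)
        threshold = screening.select_threshold(list(zip(subjects, ratios)))

        train_table = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "ahi": [s.ahi for s in subjects],
                "group": [s.group for s in subjects],
                "as_ratio": ratios,
                "decision": [screening.classify_subject(r, threshold) for r in ratios],
            }
        )
        return ApneaScreeningResults(self, trained, threshold, train_table)


class ApneaScreeningResults:
    """Fitted pipeline: trained classifier plus calibrated threshold."""

    def __init__(
        self,
        model: ApneaScreeningModel,
        classifier: sequence_model.TrainedModel,
        threshold: float,
        train_table: pd.DataFrame,
    ):
        self.model = model
        self.classifier = classifier
        self.threshold = float(threshold)
        self.train_table = train_table

    @property
    def loss_curve(self) -> list[float]:
        return self.classifier.loss_curve

    def predict_segments(self, series: RRISeries) -> tuple[SegmentSet, list[str]]:
        """Segment a record and return per-segment A/N predictions."""
        segset = prepare_segments(series, self.model.window_width_s)
        return segset, sequence_model.predict(self.classifier, segset)

    def screen_subject(self, series: RRISeries) -> screening.ScreeningResult:
        """Full screening decision for one subject's RRI record."""
        _, preds = self.predict_segments(series)
        return screening.make_result(
            series.subject_id, preds, self.model.window_width_s, self.threshold
        )

    def screen(self, data: Sequence[SubjectData]) -> pd.DataFrame:
        """Screen a cohort; returns one row per subject."""
        rows = []
        for series, _, record in data:
            res = self.screen_subject(series)
            rows.append(
                {
                    "subject_id": res.subject_id,
                    "ahi": record.ahi,
                    "group": record.group,
                    "as_ratio": res.as_ratio,
                    "threshold": res.threshold,
                    "decision": res.decision,
                    "t_a_s": res.t_a,
                    "t_s_s": res.t_s,
                }
            )
        return pd.DataFrame(rows)

    def evaluate(self, data: Sequence[SubjectData], **kwargs) -> dict:
        """Screen a held-out cohort and compute subject-level metrics."""
        pairs = [
            (record, self.screen_subject(series)) for series, _, record in data
        ]
        return screening.evaluate(pairs, **kwargs)

    def summary(self) -> str:
        """Human-readable account of the fit and calibration."""
        cfg = self.model.config
        lines = [
            "Apnea screening model",
            "=" * 58,
            f"mode:            {cfg.mode}",
            f"window width:    {self.model.window_width_s:.0f} s",
            f"LSTM units:      {cfg.hidden_units}   epochs: {cfg.epochs}   "
            f"lr: {cfg.learning_rate}",
            f"segments:        {int(sum(self.classifier.class_counts.values()))} "
            f"(A: {self.classifier.class_counts.get('A', 0)}, "
            f"N: {self.classifier.class_counts.get('N', 0)})",
            f"final BCE loss:  {self.loss_curve[-1]:.4f}",
            f"AS threshold:    {self.threshold:.3f} (borderline-case rule)",
            "-" * 58,
            "training subjects:",
        ]
        tbl = self.train_table.copy()
        tbl["as_ratio"] = tbl["as_ratio"].map(lambda v: f"{v:.3f}")
        tbl["ahi"] = tbl["ahi"].map(lambda v: f"{v:.1f}")
        lines.append(tbl.to_string(index=False))
        return "\n".join(lines)
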