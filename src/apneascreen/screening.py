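"""Subject-level screening from per-segment predictions.

The apnea/sleep (AS) ratio is the fraction of analyzed sleep time whose
segments the classifier labels apnea: ``A = T_a / T_s`` with
``T_a = (# A segments) * w`` and ``T_s = (# segments) * w`` for window
width ``w``.  It is reported as a fraction in [0, 1]; a percent display
is a presentation choice (multiply by 100).  ``T_s`` here is analyzed
ECG time — the windows that survived segmentation — not an EEG-derived
total sleep time, since the pipeline has no EEG channel.

Threshold calibration uses the borderline-case rule: the cutoff is the
AS ratio of the training patient with the smallest AHI among those with
AHI >= 15 (ties on AHI break toward the smaller AS ratio, the more
conservative cutoff).  A subject is flagged as a potential patient with
moderate-to-severe SAS when their AS ratio is >= the threshold — the
boundary is inclusive so the borderline patient classifies as a patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io import SubjectRecord, ValidationError
from .preprocessing import APNEA_LABEL

__all__ = [
    "ScreeningResult",
    "as_ratio",
    "select_threshold",
    "classify_subject",
    "evaluate",
    "POSITIVE_DECISION",
    "NEGATIVE_DECISION",
]

POSITIVE_DECISION = "potential_patient"
NEGATIVE_DECISION = "healthy"


@dataclass(frozen=True)
class ScreeningResult:
    """Per-subject screening outcome."""

    subject_id: str
    as_ratio: float
    threshold: float
    decision: str
    t_a: float  # apnea seconds
    t_s: float  # total analyzed seconds


def as_ratio(
    predictions: Sequence[str], window_width_s: float
) -> tuple[float, float, float]:
    """Return ``(t_a, t_s, ratio)`` from per-segment A/N predictions."""
    if len(predictions) == 0:
        raise ValidationError("cannot compute AS ratio from zero segments")
    n_a = sum(1 for p in predictions if p == APNEA_LABEL)
    t_a = n_a * window_width_s
    t_s = len(predictions) * window_width_s
    return float(t_a), float(t_s), float(t_a / t_s)


def select_threshold(
    train_results: Sequence[tuple[SubjectRecord, float]]
) -> float:
    """Borderline-case threshold from training (subject, AS-ratio) pairs."""
    patients = [(s.ahi, ratio) for s, ratio in train_results if s.is_patient]
    if not patients:
        raise ValidationError(
            "no training subject with AHI >= 15; cannot calibrate threshold"
        )
    return float(min(patients)[1])  # min AHI, ties -> smaller AS ratio


def classify_subject(as_ratio_value: float, threshold: float) -> str:
    """Decision: potential patient iff AS ratio >= threshold (inclusive)."""
    if not (0 <= as_ratio_value <= 1 and 0 <= threshold <= 1):
        raise ValidationError("AS ratio and threshold must lie in [0, 1]")
    return POSITIVE_DECISION if as_ratio_value >= threshold else NEGATIVE_DECISION


def make_result(
    subject_id: str,
    predictions: Sequence[str],
    window_width_s: float,
    threshold: float,
) -> ScreeningResult:
    t_a, t_s, ratio = as_ratio(predictions, window_width_s)
    return ScreeningResult(
        subject_id=subject_id,
        as_ratio=ratio,
        threshold=float(threshold),
        decision=classify_subject(ratio, threshold),
        t_a=t_a,
        t_s=t_s,
    )


def evaluate(
    results: Sequence[tuple[SubjectRecord, ScreeningResult]],
    sleep_parameters: Mapping[str, Mapping[str, float]] | None = None,
) -> dict:
    """Subject-level screening metrics.

    Positive class = AHI >= 15.  Returns sensitivity TP/(TP+FN),
    specificity TN/(TN+FP), ROC AUC with the AS ratio as score, and the
    Welch's t-test p-value comparing patient vs healthy AS ratios.  A
    metric undefined for the supplied groups (single-group input) is
    reported as None.  ``sleep_parameters`` maps parameter name ->
    {subject_id: value}; each yields a Pearson correlation with the AS
    ratio.
    """
    if not results:
        raise ValidationError("no subjects to evaluate")
    truth = np.array([int(s.is_patient) for s, _ in results])
    scores = np.array([r.as_ratio for _, r in results])
    flagged = np.array([int(r.decision == POSITIVE_DECISION) for _, r in results])

    tp = int(np.sum((truth == 1) & (flagged == 1)))
    fn = int(np.sum((truth == 1) & (flagged == 0)))
    tn = int(np.sum((truth == 0) & (flagged == 0)))
    fp = int(np.sum((truth == 0) & (flagged == 1)))

    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    both_groups = 0 < truth.sum() < truth.size
    auc = float(roc_auc_score(truth, scores)) if both_groups else None

    p_value = None
    if both_groups and truth.sum() >= 2 and (truth == 0).sum() >= 2:
        p_value = float(
            stats.ttest_ind(scores[truth == 1], scores[truth == 0], equal_var=False).pvalue
        )

    metrics = {
        "n_subjects": int(truth.size),
        "n_patients": int(truth.sum()),
        "n_healthy": int(truth.size - truth.sum()),
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "auc": auc,
        "welch_t_p_value": p_value,
        "mean_as_ratio_patients": float(scores[truth == 1].mean()) if truth.sum() else None,
        "mean_as_ratio_healthy": float(scores[truth == 0].mean()) if (truth == 0).sum() else None,
    }

    if sleep_parameters:
        corr = {}
        by_id = {s.subject_id: r.as_ratio for s, r in results}
        for name, values in sleep_parameters.items():
            common = [sid for sid in by_id if sid in values]
            if len(common) >= 3:
                a = np.array([by_id[sid] for sid in common])
                b = np.array([values[sid] for sid in common])
                corr[name] = float(stats.pearsonr(a, b).statistic)
            else:
                corr[name] = None
        metrics["as_ratio_correlations"] = corr
    return metrics
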