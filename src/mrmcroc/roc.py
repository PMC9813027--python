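"""Empirical ROC curves and trapezoidal AUC for reader-study ratings.

Two score types are supported per reading mode:

``pom``
    The probability-of-malignancy scale completed over all breasts.  BI-RADS
    1–2 carry no POM by protocol, so they are mapped below every POM value
    while preserving their mutual order (1 -> -2, 2 -> -1); BI-RADS >= 3
    contributes the recorded POM (0–100).  Any strictly order-preserving
    encoding yields the same empirical ROC; this one is the reference.

``birads``
    The forced five-point BI-RADS score itself (ordinal 1–5), giving an ROC
    with at most four interior operating points.

Positivity is "score >= threshold" (higher = more suspicious).  Ties receive
half credit — the trapezoidal area equals the tie-corrected Mann–Whitney
pair statistic (#{pos>neg} + 0.5 #{pos=neg}) / (n_pos n_neg).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .datamodel import IntegrityError, RatingRecord, StudyDataset

__all__ = [
    "pom_score",
    "birads_score",
    "score_record",
    "ScoreVector",
    "RocResult",
    "empirical_roc",
    "mode_score_frame",
    "reader_auc_table",
    "roc_points_frame",
]

#: reference encoding of the POM-less BI-RADS categories
POM_BIRADS1 = -2.0
POM_BIRADS2 = -1.0


def pom_score(record: RatingRecord, distinguish_birads12: bool = True) -> float:
    """POM-completed score for one rating.

    With ``distinguish_birads12=False`` both POM-less categories collapse to
    a single rank below 0 (sensitivity-analysis variant).
    """
    if record.bi_rads <= 2:
        if not distinguish_birads12:
            return POM_BIRADS2
        return POM_BIRADS1 if record.bi_rads == 1 else POM_BIRADS2
    if record.pom is None:  # unreachable for validated records
        raise IntegrityError(
            f"case {record.case_id}: BI-RADS {record.bi_rads} without POM")
    return float(record.pom)


def birads_score(record: RatingRecord) -> float:
    """The forced BI-RADS category as an ordinal score (1–5)."""
    return float(record.bi_rads)


def score_record(record: RatingRecord, score_type: str, **kwargs) -> float:
    if score_type == "pom":
        return pom_score(record, **kwargs)
    if score_type == "birads":
        return birads_score(record)
    raise ValueError(f"unknown score_type {score_type!r}")


@dataclass
class ScoreVector:
    """Scores and binary truth labels (1 = malignant) for one reader x mode."""

    case_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    score_type: str = "pom"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.case_ids) != len(self.scores) or len(self.scores) != len(self.labels):
            raise ValueError("case_ids, scores and labels must have equal length")


@dataclass
class RocResult:
    """Empirical ROC operating points and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def operating_points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def empirical_roc(sv: ScoreVector) -> RocResult:
    """Empirical ROC over all distinct score thresholds, plus (0,0) and (1,1).

    Raises ``ValueError`` on single-class input; bootstrap callers treat that
    as a degenerate resample.
    """
    n_pos = int(sv.labels.sum())
    n_neg = int(len(sv.labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    fpr, tpr, thr = roc_curve(sv.labels, sv.scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
                     n_pos=n_pos, n_neg=n_neg)


def mode_score_frame(ds: StudyDataset, mode: str, score_type: str = "pom",
                     **score_kwargs) -> tuple[pd.DataFrame, np.ndarray]:
    """Readers x cases score matrix for one mode, plus aligned labels.

    Returns a DataFrame indexed by reader_id with case_id columns (column
    order = truth-table order) and the 0/1 label vector in the same order.
    Incomplete mode data raises :class:`IntegrityError`.
    """
    case_order = ds.case_ids
    truth = ds.truth_by_id()
    recs = ds.ratings_for(mode)
    if not recs:
        raise IntegrityError(f"no ratings for mode {mode!r}")
    rows = [(r.reader_id, r.case_id, score_record(r, score_type, **score_kwargs))
            for r in recs]
    frame = pd.DataFrame(rows, columns=["reader_id", "case_id", "score"])
    wide = frame.pivot(index="reader_id", columns="case_id", values="score")
    missing_cases = [c for c in case_order if c not in wide.columns]
    if missing_cases or wide.isna().any().any():
        raise IntegrityError(
            f"mode {mode!r} is incomplete; run validate_completeness")
    wide = wide[case_order]
    labels = np.array([int(truth[c].is_positive) for c in case_order])
    return wide, labels


def reader_auc_table(ds: StudyDataset, mode: str, score_type: str = "pom",
                     **score_kwargs) -> tuple[dict[str, float], float]:
    """Per-reader empirical AUCs for one mode and their unweighted mean.

    Full precision is kept; rounding happens only in the reporting layer.
    """
    wide, labels = mode_score_frame(ds, mode, score_type, **score_kwargs)
    aucs: dict[str, float] = {}
    for reader_id, row in wide.iterrows():
        sv = ScoreVector(case_ids=list(wide.columns), scores=row.to_numpy(),
                         labels=labels, score_type=score_type)
        aucs[str(reader_id)] = empirical_roc(sv).auc
    mean = float(np.mean(list(aucs.values())))
    return aucs, mean


def roc_points_frame(result: RocResult) -> pd.DataFrame:
    """Operating points as a (fpr, tpr, threshold) table for curve export."""
    return pd.DataFrame({"fpr": result.fpr, "tpr": result.tpr,
                         "threshold": result.thresholds})
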