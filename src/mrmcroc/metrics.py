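"""Sensitivity and specificity at the BI-RADS 4–5 positivity rule.

The study dichotomizes the forced BI-RADS assessment into positive (4–5)
versus negative (1–3).  Sensitivity is computed over malignant breasts and
specificity over non-malignant breasts (biopsy-proven benign plus
normal-negative), with counts pooled over readers — pooling and
reader-averaging coincide when every reader rates every case, but pooled
counts are the reference definition here.

Strata:

* ``overall`` and the two density strata use every breast of the stratum;
* the two finding-type strata are lesion strata: ``soft_tissue`` is
  {mass, mass_calc, focal_asymmetry} and ``calcification`` is the
  calcification lesions.  Their specificity denominator is the *benign
  lesions* of the stratum only — finding type is a lesion attribute, so
  normal-negative breasts are excluded.  ``distortion`` lesions are exposed
  as a descriptive stratum but belong to neither named group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .datamodel import CaseTruth, ConfigError, RatingRecord, StudyDataset
from .bootstrap import (BootstrapSpec, BootstrapResult, bootstrap_p,
                        percentile_ci, proportion_statistic, two_way_bootstrap)

__all__ = [
    "POSITIVITY_THRESHOLD",
    "SOFT_TISSUE_FINDINGS",
    "STRATA",
    "classify",
    "BinaryPerf",
    "stratum_masks",
    "perf_by_stratum",
    "BinaryComparison",
    "compare_binary",
]

POSITIVITY_THRESHOLD = 4
SOFT_TISSUE_FINDINGS = frozenset({"mass", "mass_calc", "focal_asymmetry"})


def classify(record: RatingRecord) -> str:
    """Dichotomized assessment: ``positive`` iff BI-RADS >= 4."""
    return "positive" if record.bi_rads >= POSITIVITY_THRESHOLD else "negative"


def _in_soft_tissue(t: CaseTruth) -> bool:
    return t.finding_type in SOFT_TISSUE_FINDINGS


#: stratum name -> (case filter, include normal-negative breasts in specificity?)
STRATA: dict[str, tuple[Callable[[CaseTruth], bool], bool]] = {
    "overall": (lambda t: True, True),
    "non_dense": (lambda t: t.density == "non_dense", True),
    "dense": (lambda t: t.density == "dense", True),
    "soft_tissue": (_in_soft_tissue, False),
    "calcification": (lambda t: t.finding_type == "calcification", False),
    "distortion": (lambda t: t.finding_type == "distortion", False),
}

StratumRule = Union[str, Callable[[CaseTruth], bool]]


def _resolve_stratum(rule: StratumRule) -> tuple[Callable[[CaseTruth], bool], bool, str]:
    if callable(rule):
        return rule, True, getattr(rule, "__name__", "custom")
    try:
        f, with_normals = STRATA[rule]
    except KeyError:
        raise ConfigError(f"unknown stratum {rule!r}; known: {sorted(STRATA)}")
    return f, with_normals, rule


@dataclass
class BinaryPerf:
    """Pooled-over-readers confusion counts and rates for one mode x stratum.

    ``sensitivity``/``specificity`` are ``None`` when the corresponding
    denominator is empty (flagged, never silent NaN).
    """

    stratum: str
    mode: str
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    def to_dict(self) -> dict:
        return {"stratum": self.stratum, "mode": self.mode,
                "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def stratum_masks(ds: StudyDataset, rule: StratumRule
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(malignant-member, negative-member) boolean masks in truth-table order."""
    f, with_normals, _ = _resolve_stratum(rule)
    pos = np.zeros(ds.n_cases, dtype=bool)
    neg = np.zeros(ds.n_cases, dtype=bool)
    for i, t in enumerate(ds.truths):
        if not f(t):
            continue
        if t.is_positive:
            pos[i] = True
        elif with_normals or t.truth == "benign_biopsy":
            neg[i] = True
    return pos, neg


def perf_by_stratum(ds: StudyDataset, mode: str, stratum: StratumRule = "overall"
                    ) -> BinaryPerf:
    """Pooled sensitivity/specificity for one reading mode in one stratum."""
    _, _, name = _resolve_stratum(stratum)
    pos_mask, neg_mask = stratum_masks(ds, stratum)
    by_case = {c: i for i, c in enumerate(ds.case_ids)}
    tp = fn = tn = fp = 0
    for r in ds.ratings_for(mode):
        i = by_case.get(r.case_id)
        if i is None:
            continue
        called = r.bi_rads >= POSITIVITY_THRESHOLD
        if pos_mask[i]:
            tp, fn = tp + called, fn + (not called)
        elif neg_mask[i]:
            fp, tn = fp + called, tn + (not called)
    return BinaryPerf(stratum=name, mode=mode, tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass
class BinaryComparison:
    """Paired mode contrast of a pooled proportion (sensitivity/specificity)."""

    mode_a: str
    mode_b: str
    metric: str
    stratum: str
    value_a: float
    value_b: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float
    n_effective_resamples: int
    n_degenerate_skipped: int
    seed: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "mode_a", "mode_b", "metric", "stratum", "value_a", "value_b",
            "difference", "ci_low", "ci_high", "p_value", "alpha",
            "n_effective_resamples", "n_degenerate_skipped", "seed")}


def compare_binary(ds: StudyDataset, mode_a: str, mode_b: str,
                   metric: str = "sensitivity",
                   stratum: StratumRule = "overall",
                   spec: Optional[BootstrapSpec] = None) -> BinaryComparison:
    """Two-way bootstrap contrast of sensitivity or specificity.

    Resampling is over all patients (the study design); the statistic is the
    proportion within the stratum members present in each resample.
    """
    spec = spec or BootstrapSpec()
    if metric not in ("sensitivity", "specificity"):
        raise ConfigError("metric must be 'sensitivity' or 'specificity'")
    _, _, name = _resolve_stratum(stratum)
    pos_mask, neg_mask = stratum_masks(ds, stratum)
    mask = pos_mask if metric == "sensitivity" else neg_mask
    stat = proportion_statistic(threshold=POSITIVITY_THRESHOLD,
                                positive=(metric == "sensitivity"))
    boot: BootstrapResult = two_way_bootstrap(
        ds, mode_a, mode_b, "birads", spec, statistic=stat,
        extra_case_data={"relevant": mask})
    perf_a = perf_by_stratum(ds, mode_a, stratum)
    perf_b = perf_by_stratum(ds, mode_b, stratum)
    va = getattr(perf_a, metric)
    vb = getattr(perf_b, metric)
    if va is None or vb is None:
        raise ConfigError(f"{metric} undefined in stratum {name!r}")
    lo, hi = percentile_ci(boot.diffs, spec.alpha)
    return BinaryComparison(
        mode_a=mode_a, mode_b=mode_b, metric=metric, stratum=name,
        value_a=va, value_b=vb, difference=vb - va,
        ci_low=lo, ci_high=hi, p_value=bootstrap_p(boot.diffs),
        alpha=spec.alpha, n_effective_resamples=int(boot.diffs.size),
        n_degenerate_skipped=boot.n_degenerate_skipped, seed=spec.seed)
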