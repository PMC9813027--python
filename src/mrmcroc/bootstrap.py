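"""Random-reader random-case inference by a two-way clustered bootstrap.

The reader-averaged statistic (empirical AUC by default) is compared between
two paired reading modes.  Both readers and cases are treated as random
samples:

* cases are resampled with replacement in patient clusters — a drawn patient
  contributes both breasts with all their ratings, preserving the
  within-patient correlation the random-case model exists for;
* reader identities are resampled with replacement, nested within each case
  resample (n_case_resamples x n_reader_resamples total draws);
* the statistic is evaluated for both modes on the *same* resampled cases
  and readers, and the difference (mode_b - mode_a) recorded.

Reader-component correction.  The case bootstrap already regenerates each
reader's case-level noise, so re-adding the raw between-reader spread of the
per-reader differences through naive reader draws double-counts that noise
and over-disperses the bootstrap distribution (the classic bias of the naive
two-way bootstrap that components-of-variance bootstraps correct).  By
default the reader draws are therefore rescaled so that they contribute the
*genuine* reader-heterogeneity variance: the observed between-reader spread
minus its case-noise expectation, the latter estimated from the covariance
of the per-reader differences across case resamples.  The uncorrected
scheme remains available via ``reader_correction="naive"``.

Confidence intervals are percentile (nearest-rank order statistics of the
bootstrap differences); the two-sided P value is the +1-corrected percentile
form ``p = 2 min((#{d<=0}+1)/(B+1), (#{d>=0}+1)/(B+1))`` capped at 1, which
can never return exactly zero.

Determinism: one master seed; each case-resample iteration draws from its own
spawned substream, and the reader-draw matrix from a dedicated substream, so
results do not depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .datamodel import ConfigError, StudyDataset
from . import roc as _roc

__all__ = [
    "BootstrapSpec",
    "BootstrapResult",
    "DegenerateResampleError",
    "auc_statistic",
    "proportion_statistic",
    "resample_two_way",
    "two_way_bootstrap",
    "percentile_ci",
    "bootstrap_p",
    "MrmcComparison",
    "compare_modes",
]


class DegenerateResampleError(RuntimeError):
    """A case resample could not be redrawn into a defined statistic."""


@dataclass(frozen=True)
class BootstrapSpec:
    """Resampling plan for the two-way bootstrap.

    Defaults follow the study's 1000 case resamples x 100 reader resamples
    (100,000 total) with patient-cluster case resampling at alpha 0.05.
    """

    n_case_resamples: int = 1000
    n_reader_resamples: int = 100
    cluster_key: str = "patient"  # or "breast" for unclustered sensitivity runs
    seed: int = 0
    alpha: float = 0.05
    max_redraws: int = 100
    reader_correction: str = "noise_adjusted"  # or "naive"

    def __post_init__(self) -> None:
        if self.n_case_resamples < 1 or self.n_reader_resamples < 1:
            raise ConfigError("resample counts must be positive")
        if self.cluster_key not in ("patient", "breast"):
            raise ConfigError("cluster_key must be 'patient' or 'breast'")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.reader_correction not in ("noise_adjusted", "naive"):
            raise ConfigError(
                "reader_correction must be 'noise_adjusted' or 'naive'")

    @property
    def total_resamples(self) -> int:
        return self.n_case_resamples * self.n_reader_resamples


@dataclass
class BootstrapResult:
    """Bootstrap distribution of the reader-averaged paired difference."""

    diffs: np.ndarray                 # flat, n_case x n_reader entries
    per_reader_diffs: np.ndarray      # (n_case_resamples, n_readers)
    n_degenerate_skipped: int
    spec: BootstrapSpec
    #: scale applied to the reader-draw deviations (1.0 under "naive")
    reader_scale: float = 1.0
    #: estimated genuine between-reader variance of the paired difference
    reader_het_variance: float = 0.0


def auc_statistic(scores: np.ndarray, data: Mapping[str, np.ndarray]) -> float:
    """Tie-corrected Mann–Whitney AUC via midranks; NaN if single-class.

    Algebraically identical to the trapezoidal area of the empirical ROC
    (asserted against :func:`mrmcroc.roc.empirical_roc` in the test suite).
    """
    labels = data["label"]
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(scores)
    rank_sum = float(ranks[labels.astype(bool)].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def proportion_statistic(threshold: int = 4, positive: bool = True,
                         mask_key: str = "relevant") -> Callable:
    """Per-reader proportion statistic over a case subset.

    ``positive=True`` gives the call-rate at BI-RADS >= ``threshold`` over
    the masked cases (sensitivity when the mask selects malignant breasts);
    ``positive=False`` gives the below-threshold rate (specificity when the
    mask selects non-malignant breasts).  NaN when the mask is empty in the
    resample.
    """

    def stat(scores: np.ndarray, data: Mapping[str, np.ndarray]) -> float:
        mask = data[mask_key].astype(bool)
        if not mask.any():
            return math.nan
        called = scores[mask] >= threshold
        frac = float(called.mean())
        return frac if positive else 1.0 - frac
    return stat


def _cluster_members(cluster_ids: Sequence) -> list[np.ndarray]:
    ids = np.asarray(cluster_ids)
    order = {}
    for i, c in enumerate(ids):
        order.setdefault(c, []).append(i)
    return [np.asarray(v, dtype=np.intp) for v in order.values()]


def resample_two_way(scores_a: np.ndarray, scores_b: np.ndarray,
                     case_data: Mapping[str, np.ndarray],
                     cluster_ids: Sequence, spec: BootstrapSpec,
                     stat_fn: Callable = auc_statistic) -> BootstrapResult:
    """Low-level engine on aligned arrays.

    ``scores_a``/``scores_b``: (n_readers, n_cases) matrices with identical
    reader and case ordering.  ``case_data``: per-case arrays (must include
    whatever ``stat_fn`` reads, e.g. ``label``); each is subset with the same
    resample indices.  ``cluster_ids``: per-case resampling-cluster key.

    A case resample on which the statistic is undefined for any reader/mode
    is redrawn from the same substream (up to ``spec.max_redraws`` times,
    counted in ``n_degenerate_skipped``), then raises
    :class:`DegenerateResampleError`.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score matrices must share shape")
    n_readers, n_cases = scores_a.shape
    if len(cluster_ids) != n_cases:
        raise ValueError("cluster_ids length must equal n_cases")

    members = _cluster_members(cluster_ids)
    n_clusters = len(members)
    sizes = {m.size for m in members}
    uniform = len(sizes) == 1
    if uniform:
        member_mat = np.vstack(members)  # (n_clusters, cluster_size)

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_case_resamples + 1)
    per_reader = np.empty((spec.n_case_resamples, n_readers))
    skipped = 0
    for b in range(spec.n_case_resamples):
        rng = np.random.default_rng(children[b])
        for _attempt in range(spec.max_redraws + 1):
            drawn = rng.integers(0, n_clusters, size=n_clusters)
            if uniform:
                idx = member_mat[drawn].ravel()
            else:
                idx = np.concatenate([members[c] for c in drawn])
            data_b = {k: np.asarray(v)[idx] for k, v in case_data.items()}
            va = np.array([stat_fn(scores_a[r, idx], data_b)
                           for r in range(n_readers)])
            vb = np.array([stat_fn(scores_b[r, idx], data_b)
                           for r in range(n_readers)])
            if not (np.isnan(va).any() or np.isnan(vb).any()):
                break
            skipped += 1
        else:
            raise DegenerateResampleError(
                f"case resample {b}: statistic undefined after "
                f"{spec.max_redraws} redraws")
        per_reader[b] = vb - va

    case_means = per_reader.mean(axis=1)                  # (B,)
    centered = per_reader - case_means[:, None]           # (B, R)

    scale, sigma2_a = 1.0, 0.0
    if spec.reader_correction == "noise_adjusted" and n_readers > 1:
        # Genuine reader heterogeneity = observed between-reader spread of
        # the full-data per-reader differences, minus its case-noise
        # expectation (mean variance minus mean covariance of the per-reader
        # differences across case resamples).
        all_idx = np.arange(n_cases)
        data_full = {k: np.asarray(v) for k, v in case_data.items()}
        obs = np.array([stat_fn(scores_b[r, all_idx], data_full)
                        - stat_fn(scores_a[r, all_idx], data_full)
                        for r in range(n_readers)])
        if np.isnan(obs).any():
            raise DegenerateResampleError("statistic undefined on full data")
        s2_obs = float(np.var(obs, ddof=1))
        cov = np.cov(per_reader, rowvar=False)
        v_bar = float(np.mean(np.diag(cov)))
        c_bar = float((cov.sum() - np.trace(cov))
                      / (n_readers * (n_readers - 1)))
        sigma2_a = max(0.0, s2_obs - (v_bar - c_bar))
        # a draw of R readers adds variance scale^2 * E_b[mean_j centered^2]/R;
        # match that to sigma2_a / R (the variance a fresh reader panel adds)
        spread = float(np.mean(centered ** 2))
        scale = math.sqrt(sigma2_a / spread) if spread > 0 else 0.0

    reader_rng = np.random.default_rng(children[-1])
    draws = reader_rng.integers(
        0, n_readers,
        size=(spec.n_case_resamples, spec.n_reader_resamples, n_readers))
    dev = np.take_along_axis(
        centered[:, None, :].repeat(spec.n_reader_resamples, axis=1),
        draws, axis=2).mean(axis=2)                       # (B, K)
    diffs = (case_means[:, None] + scale * dev).ravel()
    return BootstrapResult(diffs=diffs, per_reader_diffs=per_reader,
                           n_degenerate_skipped=skipped, spec=spec,
                           reader_scale=scale, reader_het_variance=sigma2_a)


def _patient_ids(ds: StudyDataset) -> list[str]:
    truth = ds.truth_by_id()
    return [truth[c].patient_id for c in ds.case_ids]


def two_way_bootstrap(ds: StudyDataset, mode_a: str, mode_b: str,
                      score_type: str, spec: BootstrapSpec,
                      statistic: Callable = auc_statistic,
                      extra_case_data: Optional[Mapping[str, np.ndarray]] = None,
                      ) -> BootstrapResult:
    """Dataset-level two-way bootstrap of ``statistic(mode_b) - statistic(mode_a)``."""
    wide_a, labels = _roc.mode_score_frame(ds, mode_a, score_type)
    wide_b, labels_b = _roc.mode_score_frame(ds, mode_b, score_type)
    if list(wide_a.index) != list(wide_b.index):
        raise ConfigError("modes rated by different reader sets")
    assert np.array_equal(labels, labels_b)
    case_data = {"label": labels}
    if extra_case_data:
        case_data.update({k: np.asarray(v) for k, v in extra_case_data.items()})
    if spec.cluster_key == "patient":
        clusters: Sequence = _patient_ids(ds)
    else:
        clusters = ds.case_ids
    return resample_two_way(wide_a.to_numpy(), wide_b.to_numpy(), case_data,
                            clusters, spec, statistic)


def percentile_ci(boot_diffs: Sequence[float], alpha: float = 0.05
                  ) -> tuple[float, float]:
    """Nearest-rank percentile interval.

    With B sorted values, the q-quantile is the ``ceil(qB)``-th order
    statistic (clamped to [1, B]); the interval is the alpha/2 and
    1 - alpha/2 quantiles.
    """
    x = np.sort(np.asarray(boot_diffs, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty bootstrap distribution")

    def rank(q: float) -> int:
        return min(n, max(1, math.ceil(q * n)))

    return float(x[rank(alpha / 2.0) - 1]), float(x[rank(1.0 - alpha / 2.0) - 1])


def bootstrap_p(boot_diffs: Sequence[float]) -> float:
    """Two-sided +1-corrected percentile P value for H0: difference = 0."""
    d = np.asarray(boot_diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty bootstrap distribution")
    b = d.size
    lo = (np.count_nonzero(d <= 0.0) + 1) / (b + 1)
    hi = (np.count_nonzero(d >= 0.0) + 1) / (b + 1)
    return min(1.0, 2.0 * min(lo, hi))


@dataclass
class MrmcComparison:
    """Paired modality contrast with bootstrap percentile inference."""

    mode_a: str
    mode_b: str
    score_type: str
    per_reader_auc_a: dict[str, float]
    per_reader_auc_b: dict[str, float]
    mean_auc_a: float
    mean_auc_b: float
    difference: float          # mean_b - mean_a
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float
    n_effective_resamples: int
    n_degenerate_skipped: int
    seed: int
    boot_diffs: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "mode_a": self.mode_a,
            "mode_b": self.mode_b,
            "score_type": self.score_type,
            "per_reader_auc_a": dict(self.per_reader_auc_a),
            "per_reader_auc_b": dict(self.per_reader_auc_b),
            "mean_auc_a": self.mean_auc_a,
            "mean_auc_b": self.mean_auc_b,
            "difference": self.difference,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "n_effective_resamples": self.n_effective_resamples,
            "n_degenerate_skipped": self.n_degenerate_skipped,
            "seed": self.seed,
        }


def compare_modes(ds: StudyDataset, mode_a: str, mode_b: str,
                  score_type: str = "pom",
                  spec: Optional[BootstrapSpec] = None) -> MrmcComparison:
    """Observed reader-averaged AUC contrast plus two-way bootstrap CI and P."""
    spec = spec or BootstrapSpec()
    auc_a, mean_a = _roc.reader_auc_table(ds, mode_a, score_type)
    auc_b, mean_b = _roc.reader_auc_table(ds, mode_b, score_type)
    boot = two_way_bootstrap(ds, mode_a, mode_b, score_type, spec)
    lo, hi = percentile_ci(boot.diffs, spec.alpha)
    return MrmcComparison(
        mode_a=mode_a, mode_b=mode_b, score_type=score_type,
        per_reader_auc_a=auc_a, per_reader_auc_b=auc_b,
        mean_auc_a=mean_a, mean_auc_b=mean_b,
        difference=mean_b - mean_a,
        ci_low=lo, ci_high=hi,
        p_value=bootstrap_p(boot.diffs),
        alpha=spec.alpha,
        n_effective_resamples=int(boot.diffs.size),
        n_degenerate_skipped=boot.n_degenerate_skipped,
        seed=spec.seed,
        boot_diffs=boot.diffs,
    )
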