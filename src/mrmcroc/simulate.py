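"""Synthetic reader-study generator with a Roe–Metz-style latent-score model.

Each rating arises from a latent suspicion score

    x = mu_class,mode + r_j + c_k + rc_jk + eps_jkm

with reader effect ``r_j ~ N(0, var_reader)``, case effect ``c_k`` (variance
``var_case``, correlated ``rho_patient`` between the two breasts of one
patient), reader-by-case interaction ``rc_jk ~ N(0, var_interaction)`` and
residual ``eps ~ N(0, var_resid)``.  The reader and case effects — and the
interaction — are shared across the four reading modes, so a mode contrast
is paired through the latent structure exactly as repeated readings of the
same breasts by the same readers are in the study design.

Class means: normal-negative breasts sit at 0, biopsy-proven benign lesions
at a small positive ``benign_shift`` (benign lesions drew enough suspicion
to be biopsied), malignant breasts at a per-mode ``mu`` calibrated so the
population AUC of the *emitted* score equals the configured per-mode target.

The forced BI-RADS score is the latent score cut at four ordered cutpoints;
the POM (emitted only for BI-RADS >= 3, as in the elicitation protocol) is a
rounded monotone logistic map of the latent score, hence rank-consistent
with it.  Because BI-RADS 1–2 breasts re-enter the POM-completed ROC as two
tied ranks, the calibration inverts the AUC of that censored score (by
numerical integration over the class mixture and the reader effect) rather
than the latent-scale binormal identity; the closed form
``mu = sqrt(2 v) * Phi^-1(AUC)`` applies — and is used — when nothing is
censored and no benign shift is present.

Composition (case counts, finding-type margins, density margins) is exact by
construction, not merely in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, ndtr, ndtri

from .datamodel import (MODE_SESSION, MODES, CaseTruth, ConfigError,
                        RatingRecord, StudyDataset)

__all__ = [
    "DEFAULT_FINDING_MARGINS",
    "DEFAULT_TARGET_AUC",
    "SimConfig",
    "calibrate_mu",
    "population_observed_auc",
    "mode_mu",
    "generate_truth",
    "generate_ratings",
    "generate_study",
]

#: finding type -> (malignant count, benign count); study case-mix margins
DEFAULT_FINDING_MARGINS: Mapping[str, tuple[int, int]] = {
    "mass": (49, 34),
    "mass_calc": (15, 1),
    "focal_asymmetry": (2, 3),
    "distortion": (4, 6),
    "calcification": (14, 39),
}

#: reader-averaged POM AUC targets per reading mode (study operating levels)
DEFAULT_TARGET_AUC: Mapping[str, float] = {
    "DM": 0.871,
    "AICAD_SM": 0.902,
    "DM_DBT": 0.895,
    "AICAD_SM_DBT": 0.909,
}

_HISTOLOGY_MALIGNANT: Mapping[str, int] = {
    "invasive_ductal_carcinoma": 71,
    "dcis": 8,
    "invasive_lobular_carcinoma": 3,
    "tubular_carcinoma": 1,
    "invasive_micropapillary_carcinoma": 1,
}

#: plausible lesion-size (mm) log-normal location/scale and clip range per type
_SIZE_MODEL: Mapping[str, tuple[float, float, int, int]] = {
    "mass": (math.log(19.0), 0.35, 6, 42),
    "mass_calc": (math.log(20.0), 0.35, 6, 45),
    "focal_asymmetry": (math.log(15.0), 0.30, 8, 40),
    "distortion": (math.log(12.0), 0.30, 6, 30),
    "calcification": (math.log(20.0), 0.45, 8, 60),
}


def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if total == 0 or w.sum() == 0:
        return [0] * len(w)
    quotas = w / w.sum() * total
    counts = np.floor(quotas).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


@dataclass(frozen=True)
class SimConfig:
    """Study-design and latent-model parameters for the generator.

    Defaults reproduce the study conditions: 194 patients x 2 breasts = 388
    breasts (84 cancers / 83 biopsy-proven benign / 221 normal-negative),
    206 non-dense breasts, 4 readers, the 4 sequential reading modes, and
    per-mode AUC targets at the study's reader-averaged POM values.
    """

    n_patients: int = 194
    n_normal: int = 221
    finding_margins: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_FINDING_MARGINS))
    n_non_dense: int = 206
    n_readers: int = 4
    modes: tuple[str, ...] = MODES
    target_auc: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_AUC))
    #: latent variance components (residual fixed at 1 sets the scale)
    var_reader: float = 0.0225
    var_case: float = 0.6
    var_interaction: float = 0.2
    var_resid: float = 1.0
    rho_patient: float = 0.3
    benign_shift: float = 0.3
    #: BI-RADS cutpoints on the latent scale; score = 1 + #cutpoints <= x
    cutpoints: tuple[float, float, float, float] = (0.5, 1.3, 2.1, 3.2)
    pom_center: float = 3.0
    pom_scale: float = 1.2
    #: optional direct latent shifts per mode, bypassing AUC calibration
    mu_override: Optional[Mapping[str, float]] = None
    #: optional (mode, finding_type) -> latent increment for lesion breasts
    mode_finding_shift: Mapping[tuple[str, str], float] = field(
        default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_readers < 1:
            raise ConfigError("n_patients and n_readers must be positive")
        for m in self.modes:
            if m not in MODES:
                raise ConfigError(f"unknown mode {m!r}")
        if self.n_malignant + self.n_benign + self.n_normal != self.n_breasts:
            raise ConfigError(
                f"composition {self.n_malignant}/{self.n_benign}/"
                f"{self.n_normal} does not fill {self.n_breasts} breasts "
                f"({self.n_patients} patients x 2)")
        if not 0 <= self.n_non_dense <= self.n_breasts:
            raise ConfigError("n_non_dense out of range")
        if self.mu_override is None:
            for m in self.modes:
                t = self.target_auc.get(m)
                if t is None:
                    raise ConfigError(f"no target AUC for mode {m!r}")
                if not 0.5 <= t < 1.0:
                    raise ConfigError(f"target AUC for {m!r} must be in [0.5, 1)")
        if not 0.0 <= self.rho_patient < 1.0:
            raise ConfigError("rho_patient must be in [0, 1)")
        if min(self.var_reader, self.var_case, self.var_interaction) < 0 \
                or self.var_resid <= 0:
            raise ConfigError("variance components must be non-negative, "
                              "residual positive")
        if list(self.cutpoints) != sorted(self.cutpoints) or \
                len(set(self.cutpoints)) != 4:
            raise ConfigError("cutpoints must be 4 strictly increasing values")

    # -- derived counts ----------------------------------------------------
    @property
    def n_breasts(self) -> int:
        return 2 * self.n_patients

    @property
    def n_malignant(self) -> int:
        return sum(m for m, _ in self.finding_margins.values())

    @property
    def n_benign(self) -> int:
        return sum(b for _, b in self.finding_margins.values())

    @property
    def var_within(self) -> float:
        """Within-class, within-reader latent variance."""
        return self.var_case + self.var_interaction + self.var_resid

    @classmethod
    def with_composition(cls, n_malignant: int, n_benign: int, n_normal: int,
                         n_patients: int, **overrides) -> "SimConfig":
        """Scaled study: finding/density margins apportioned from the defaults."""
        mal = _largest_remainder(
            [m for m, _ in DEFAULT_FINDING_MARGINS.values()], n_malignant)
        ben = _largest_remainder(
            [b for _, b in DEFAULT_FINDING_MARGINS.values()], n_benign)
        margins = {k: (mal[i], ben[i])
                   for i, k in enumerate(DEFAULT_FINDING_MARGINS)}
        n_breasts = 2 * n_patients
        overrides.setdefault("n_non_dense", round(206 / 388 * n_breasts))
        return cls(n_patients=n_patients, n_normal=n_normal,
                   finding_margins=margins, **overrides)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_normal": self.n_normal,
            "finding_margins": {k: list(v)
                                for k, v in self.finding_margins.items()},
            "n_non_dense": self.n_non_dense,
            "n_readers": self.n_readers,
            "modes": list(self.modes),
            "target_auc": dict(self.target_auc),
            "var_reader": self.var_reader,
            "var_case": self.var_case,
            "var_interaction": self.var_interaction,
            "var_resid": self.var_resid,
            "rho_patient": self.rho_patient,
            "benign_shift": self.benign_shift,
            "cutpoints": list(self.cutpoints),
            "pom_center": self.pom_center,
            "pom_scale": self.pom_scale,
            "mu_override": dict(self.mu_override) if self.mu_override else None,
            "mode_finding_shift": {f"{m}:{ft}": v for (m, ft), v
                                   in self.mode_finding_shift.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "finding_margins" in d:
            d["finding_margins"] = {k: tuple(v)
                                    for k, v in d["finding_margins"].items()}
        if "modes" in d:
            d["modes"] = tuple(d["modes"])
        if "cutpoints" in d:
            d["cutpoints"] = tuple(d["cutpoints"])
        if d.get("mode_finding_shift"):
            d["mode_finding_shift"] = {
                tuple(k.split(":", 1)): v
                for k, v in d["mode_finding_shift"].items()}
        return cls(**d)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# calibration: latent shift <-> population AUC of the emitted score
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(80)
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(21)


def _pair_auc_censored(a: float, b: float, s: float,
                       c1: float, c2: float) -> float:
    """P(S_X > S_Y) + 0.5 P(S_X = S_Y) for X~N(a,s^2) vs Y~N(b,s^2).

    The emitted score S is the identity above ``c2`` and collapses
    (-inf, c1] and (c1, c2] to two tied ranks below every continuous value.
    """
    px1 = ndtr((c1 - a) / s)
    px2 = ndtr((c2 - a) / s) - px1
    py1 = ndtr((c1 - b) / s)
    py2 = ndtr((c2 - b) / s) - py1
    hi = max(a, b) + 8.0 * s
    cont = 0.0
    if hi > c2:
        y = 0.5 * (hi - c2) * (_GL_NODES + 1.0) + c2
        w = 0.5 * (hi - c2) * _GL_WEIGHTS
        f_y = np.exp(-0.5 * ((y - b) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        cont = float(np.sum(w * f_y * (1.0 - ndtr((y - a) / s))))
    return (cont
            + (1.0 - px1 - px2) * (py1 + py2)   # X continuous, Y censored
            + px2 * py1                         # X in band 2, Y in band 1
            + 0.5 * (px1 * py1 + px2 * py2))    # tied bands


def population_observed_auc(mu: float, *, var_case: float = 0.0,
                            var_interaction: float = 0.0,
                            var_resid: float = 1.0, var_reader: float = 0.0,
                            benign_shift: float = 0.0,
                            benign_weight: float = 0.0,
                            cutpoints: Optional[Sequence[float]] = None
                            ) -> float:
    """Population AUC of the emitted score for malignant shift ``mu``.

    The non-diseased class is the (normal, benign) mixture with benign
    weight ``benign_weight`` and mean ``benign_shift``; ``cutpoints`` (the
    first two BI-RADS cutpoints) switch on the censoring of BI-RADS 1–2
    into tied ranks.  The expectation over the reader effect is taken by
    Gauss–Hermite quadrature (the effect shifts a reader's scores and
    cutpoints jointly, so it matters only under censoring).
    """
    v = var_case + var_interaction + var_resid
    s = math.sqrt(v)
    w = benign_weight
    if cutpoints is None:
        return ((1 - w) * ndtr(mu / math.sqrt(2 * v))
                + w * ndtr((mu - benign_shift) / math.sqrt(2 * v)))
    c1, c2 = float(cutpoints[0]), float(cutpoints[1])

    def auc_given_reader(r: float) -> float:
        a = mu + r
        out = (1 - w) * _pair_auc_censored(a, r, s, c1, c2)
        if w > 0:
            out += w * _pair_auc_censored(a, benign_shift + r, s, c1, c2)
        return out

    if var_reader <= 0:
        return auc_given_reader(0.0)
    sd_r = math.sqrt(var_reader)
    rs = math.sqrt(2.0) * sd_r * _GH_NODES
    vals = np.array([auc_given_reader(r) for r in rs])
    return float(np.sum(_GH_WEIGHTS * vals) / math.sqrt(math.pi))


def calibrate_mu(target_auc: float, *, var_case: float = 0.0,
                 var_interaction: float = 0.0, var_resid: float = 1.0,
                 var_reader: float = 0.0, benign_shift: float = 0.0,
                 benign_weight: float = 0.0,
                 cutpoints: Optional[Sequence[float]] = None) -> float:
    """Latent malignant shift whose population emitted-score AUC is ``target_auc``.

    Without censoring and without a benign shift this is the binormal closed
    form ``mu = sqrt(2 v) * Phi^-1(target)``; otherwise the censored-mixture
    AUC is inverted numerically (it is strictly increasing in ``mu``).
    """
    if not 0.5 <= target_auc < 1.0:
        raise ConfigError("target_auc must be in [0.5, 1)")
    v = var_case + var_interaction + var_resid
    if v <= 0:
        raise ConfigError("total within-class variance must be positive")
    if cutpoints is None and (benign_weight == 0.0 or benign_shift == 0.0):
        return math.sqrt(2.0 * v) * float(ndtri(target_auc))

    def f(m: float) -> float:
        return population_observed_auc(
            m, var_case=var_case, var_interaction=var_interaction,
            var_resid=var_resid, var_reader=var_reader,
            benign_shift=benign_shift, benign_weight=benign_weight,
            cutpoints=cutpoints) - target_auc

    lo = -2.0 * math.sqrt(v)
    hi = 6.0 * math.sqrt(2.0 * v) + abs(benign_shift) + 1.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def mode_mu(cfg: SimConfig) -> dict[str, float]:
    """Per-mode calibrated latent malignant shifts for a configuration."""
    if cfg.mu_override is not None:
        return {m: float(cfg.mu_override[m]) for m in cfg.modes}
    n_neg = cfg.n_benign + cfg.n_normal
    w = cfg.n_benign / n_neg if n_neg else 0.0
    return {m: calibrate_mu(
        cfg.target_auc[m], var_case=cfg.var_case,
        var_interaction=cfg.var_interaction, var_resid=cfg.var_resid,
        var_reader=cfg.var_reader, benign_shift=cfg.benign_shift,
        benign_weight=w, cutpoints=cfg.cutpoints[:2]) for m in cfg.modes}


# ---------------------------------------------------------------------------
# truth and rating generation
# ---------------------------------------------------------------------------

def _rng_children(cfg: SimConfig) -> tuple[np.random.Generator, np.random.Generator]:
    truth_ss, rating_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    return np.random.default_rng(truth_ss), np.random.default_rng(rating_ss)


def generate_truth(cfg: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> list[CaseTruth]:
    """Case-truth table with exactly the configured margins.

    Truth classes and finding types are randomly placed across breasts;
    density is assigned at the patient level (both breasts alike) as far as
    the margin allows, with at most one split patient when ``n_non_dense``
    is odd.
    """
    if rng is None:
        rng = _rng_children(cfg)[0]

    n = cfg.n_breasts
    patient_ids = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    cases = [(pid, side) for pid in patient_ids for side in ("left", "right")]

    truth_labels = (["malignant"] * cfg.n_malignant
                    + ["benign_biopsy"] * cfg.n_benign
                    + ["normal_negative"] * cfg.n_normal)
    truth_labels = [truth_labels[i] for i in rng.permutation(n)]

    def _shuffled(pool: list[str]) -> list[str]:
        return [pool[i] for i in rng.permutation(len(pool))]

    mal_findings = _shuffled(
        [ft for ft, (m, _) in cfg.finding_margins.items() for _ in range(m)])
    ben_findings = _shuffled(
        [ft for ft, (_, b) in cfg.finding_margins.items() for _ in range(b)])
    mal_hist = _shuffled(
        [h for h, c in zip(_HISTOLOGY_MALIGNANT,
                           _largest_remainder(
                               list(_HISTOLOGY_MALIGNANT.values()),
                               cfg.n_malignant))
         for _ in range(c)])

    # patient-level density assignment
    dens_order = rng.permutation(cfg.n_patients)
    density_by_patient: dict[str, tuple[str, str]] = {}
    full, odd = divmod(cfg.n_non_dense, 2)
    for rank, pi in enumerate(dens_order):
        if rank < full:
            pair = ("non_dense", "non_dense")
        elif rank == full and odd:
            pair = ("non_dense", "dense")
        else:
            pair = ("dense", "dense")
        density_by_patient[patient_ids[pi]] = pair

    truths: list[CaseTruth] = []
    for i, (pid, side) in enumerate(cases):
        truth = truth_labels[i]
        if truth == "malignant":
            ft, hist = mal_findings.pop(), mal_hist.pop()
        elif truth == "benign_biopsy":
            ft = ben_findings.pop()
            hist = ("fibroadenoma" if ft in ("mass", "mass_calc")
                    else "fibrocystic_change")
        else:
            ft, hist = "none", None
        size = None
        if ft != "none":
            loc, sc, lo, hi = _SIZE_MODEL[ft]
            size = float(int(np.clip(round(rng.lognormal(loc, sc)), lo, hi)))
        truths.append(CaseTruth(
            case_id=f"{pid}_{'L' if side == 'left' else 'R'}",
            patient_id=pid, side=side, truth=truth,
            density=density_by_patient[pid][0 if side == "left" else 1],
            finding_type=ft, lesion_size_mm=size, histology=hist))
    return truths


def generate_ratings(truths: Sequence[CaseTruth], cfg: SimConfig,
                     rng: Optional[np.random.Generator] = None,
                     return_latent: bool = False):
    """Ratings for every (breast, reader, mode) from the latent-score model.

    Returns the record list, or ``(records, latent)`` with the
    (n_readers, n_cases, n_modes) latent array when ``return_latent`` is set
    (used by rank-consistency checks).
    """
    if rng is None:
        rng = _rng_children(cfg)[1]
    mu = mode_mu(cfg)
    n, n_r, n_m = len(truths), cfg.n_readers, len(cfg.modes)

    class_mean = np.zeros((n, n_m))
    for i, t in enumerate(truths):
        for j, m in enumerate(cfg.modes):
            base = mu[m] if t.truth == "malignant" else (
                cfg.benign_shift if t.truth == "benign_biopsy" else 0.0)
            base += cfg.mode_finding_shift.get((m, t.finding_type), 0.0)
            class_mean[i, j] = base

    patients = list(dict.fromkeys(t.patient_id for t in truths))
    p_index = {p: k for k, p in enumerate(patients)}
    p_eff = rng.standard_normal(len(patients))
    u = rng.standard_normal(n)
    rho = cfg.rho_patient
    c_eff = math.sqrt(cfg.var_case) * (
        math.sqrt(rho) * np.array([p_eff[p_index[t.patient_id]] for t in truths])
        + math.sqrt(1.0 - rho) * u)
    r_eff = math.sqrt(cfg.var_reader) * rng.standard_normal(n_r)
    rc = math.sqrt(cfg.var_interaction) * rng.standard_normal((n_r, n))
    eps = math.sqrt(cfg.var_resid) * rng.standard_normal((n_r, n, n_m))

    x = (class_mean[None, :, :] + r_eff[:, None, None]
         + c_eff[None, :, None] + rc[:, :, None] + eps)

    birads = np.ones(x.shape, dtype=int)
    for c in cfg.cutpoints:
        birads += (x >= c)
    pom = np.clip(np.rint(100.0 * expit((x - cfg.pom_center) / cfg.pom_scale)),
                  0, 100).astype(int)

    records: list[RatingRecord] = []
    for r in range(n_r):
        reader_id = f"R{r + 1}"
        for j, m in enumerate(cfg.modes):
            sess = MODE_SESSION[m]
            for i, t in enumerate(truths):
                b = int(birads[r, i, j])
                records.append(RatingRecord(
                    case_id=t.case_id, reader_id=reader_id, mode=m,
                    session=sess, bi_rads=b,
                    pom=int(pom[r, i, j]) if b >= 3 else None))
    if return_latent:
        return records, x
    return records


def generate_study(cfg: Optional[SimConfig] = None,
                   seed: Optional[int] = None) -> StudyDataset:
    """Complete synthetic study dataset (truths + ratings + provenance)."""
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = cfg.with_seed(seed)
    t_rng, r_rng = _rng_children(cfg)
    truths = generate_truth(cfg, t_rng)
    ratings = generate_ratings(truths, cfg, r_rng)
    return StudyDataset(
        truths=truths, ratings=ratings,
        metadata={"provenance": "synthetic", "seed": cfg.seed,
                  "n_readers": cfg.n_readers, "n_modes": len(cfg.modes),
                  "modes": list(cfg.modes), "config": cfg.to_dict()})
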