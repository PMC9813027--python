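"""Core data structures for multireader multicase (MRMC) breast reader studies.

The study design modelled here: every breast (the analysis unit) is read by
every reader under every reading mode.  Reading happens in two sessions of two
sequential modes each — session 1 is digital mammography alone (``DM``)
followed by DM plus tomosynthesis (``DM_DBT``); session 2 is the AI-CAD
enhanced synthesized mammogram alone (``AICAD_SM``) followed by
``AICAD_SM_DBT``.  Each rating is a forced five-point BI-RADS score; a
probability-of-malignancy (POM, 0–100) is elicited only when BI-RADS >= 3.

Breasts come in pairs: two breasts per patient, and the patient is the
clustering unit for case resampling (ratings of the two breasts of one
patient are correlated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "TRUTH_CLASSES",
    "DENSITIES",
    "FINDING_TYPES",
    "MODES",
    "SIDES",
    "MODE_SESSION",
    "StudyDataError",
    "SchemaError",
    "IntegrityError",
    "ConfigError",
    "CaseTruth",
    "RatingRecord",
    "StudyDataset",
]

TRUTH_CLASSES = ("malignant", "benign_biopsy", "normal_negative")
DENSITIES = ("non_dense", "dense")
FINDING_TYPES = ("mass", "mass_calc", "focal_asymmetry", "distortion",
                 "calcification", "none")
SIDES = ("left", "right")
MODES = ("DM", "AICAD_SM", "DM_DBT", "AICAD_SM_DBT")
#: session 1 = DM-based reading, session 2 = synthesized-mammogram reading
MODE_SESSION: Mapping[str, int] = {
    "DM": 1, "DM_DBT": 1, "AICAD_SM": 2, "AICAD_SM_DBT": 2,
}


class StudyDataError(Exception):
    """Base class for all study-data errors."""


class SchemaError(StudyDataError):
    """A field failed to parse or violated its enumeration/range."""


class IntegrityError(StudyDataError):
    """Records are individually well-formed but mutually inconsistent."""


class ConfigError(StudyDataError):
    """Invalid simulation or analysis configuration."""


def normalize_category(value: str, allowed: Sequence[str], fieldname: str) -> str:
    """Map a case-insensitive categorical value to its canonical form.

    Canonical forms are lower-snake (``malignant``) except for reading-mode
    identifiers, which are upper-snake acronyms (``AICAD_SM``).
    """
    v = str(value).strip()
    for a in allowed:
        if v.lower() == a.lower():
            return a
    raise SchemaError(
        f"unknown value {value!r} for field {fieldname!r}; "
        f"expected one of {list(allowed)}"
    )


@dataclass(frozen=True)
class CaseTruth:
    """Reference standard for one breast.

    ``truth`` is three-valued (malignant / biopsy-proven benign / negative on
    one-year follow-up); for ROC and specificity purposes the positive class
    is ``malignant`` and both other classes are negatives (see
    :attr:`is_positive`).
    """

    case_id: str
    patient_id: str
    side: str
    truth: str
    density: str
    finding_type: str = "none"
    lesion_size_mm: Optional[float] = None
    histology: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "side",
                           normalize_category(self.side, SIDES, "side"))
        object.__setattr__(self, "truth",
                           normalize_category(self.truth, TRUTH_CLASSES, "truth"))
        object.__setattr__(self, "density",
                           normalize_category(self.density, DENSITIES, "density"))
        object.__setattr__(
            self, "finding_type",
            normalize_category(self.finding_type, FINDING_TYPES, "finding_type"))
        if self.truth == "normal_negative" and self.finding_type != "none":
            raise IntegrityError(
                f"case {self.case_id}: normal_negative breasts carry no "
                f"finding (got {self.finding_type!r})")
        if self.lesion_size_mm is not None:
            if self.finding_type == "none":
                raise IntegrityError(
                    f"case {self.case_id}: lesion size given without a finding")
            if not self.lesion_size_mm > 0:
                raise SchemaError(
                    f"case {self.case_id}: lesion_size_mm must be positive")

    @property
    def is_positive(self) -> bool:
        """True for the diseased (malignant) class."""
        return self.truth == "malignant"


@dataclass(frozen=True)
class RatingRecord:
    """One reader's assessment of one breast under one reading mode.

    The elicitation protocol ties POM to BI-RADS: scores 1–2 carry no POM
    (the reader saw nothing to quantify), scores 3–5 require one.  Absence is
    encoded as ``None`` — never 0, which is a legal POM value.
    """

    case_id: str
    reader_id: str
    mode: str
    session: int
    bi_rads: int
    pom: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode",
                           normalize_category(self.mode, MODES, "mode"))
        object.__setattr__(self, "session", int(self.session))
        object.__setattr__(self, "bi_rads", int(self.bi_rads))
        if not 1 <= self.bi_rads <= 5:
            raise SchemaError(
                f"case {self.case_id}: bi_rads must be 1..5, got {self.bi_rads}")
        if MODE_SESSION[self.mode] != self.session:
            raise IntegrityError(
                f"case {self.case_id}: mode {self.mode} belongs to session "
                f"{MODE_SESSION[self.mode]}, got session {self.session}")
        if self.pom is not None:
            object.__setattr__(self, "pom", int(self.pom))
            if not 0 <= self.pom <= 100:
                raise SchemaError(
                    f"case {self.case_id}: pom must be 0..100, got {self.pom}")
            if self.bi_rads <= 2:
                raise IntegrityError(
                    f"case {self.case_id}: BI-RADS {self.bi_rads} must not "
                    f"carry a POM")
        elif self.bi_rads >= 3:
            raise IntegrityError(
                f"case {self.case_id}: BI-RADS {self.bi_rads} requires a POM")


@dataclass
class StudyDataset:
    """A complete (or partial) reader study: truths, ratings, provenance."""

    truths: list[CaseTruth]
    ratings: list[RatingRecord]
    metadata: dict = field(default_factory=dict)

    @property
    def case_ids(self) -> list[str]:
        return [t.case_id for t in self.truths]

    @property
    def reader_ids(self) -> list[str]:
        return sorted({r.reader_id for r in self.ratings})

    @property
    def modes(self) -> list[str]:
        present = {r.mode for r in self.ratings}
        return [m for m in MODES if m in present]

    @property
    def n_cases(self) -> int:
        return len(self.truths)

    def truth_by_id(self) -> dict[str, CaseTruth]:
        return {t.case_id: t for t in self.truths}

    def ratings_for(self, mode: str) -> list[RatingRecord]:
        return [r for r in self.ratings if r.mode == mode]

    def subset_modes(self, modes: Iterable[str]) -> "StudyDataset":
        keep = set(modes)
        return StudyDataset(
            truths=list(self.truths),
            ratings=[r for r in self.ratings if r.mode in keep],
            metadata=dict(self.metadata),
        )
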