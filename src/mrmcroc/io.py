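"""CSV input/output and dataset completeness validation.

Two fixed schemas (UTF-8, comma-separated, mandatory header):

``truth.csv``
    case_id, patient_id, side, truth, density, finding_type,
    lesion_size_mm, histology

``ratings.csv``
    case_id, reader_id, mode, session, bi_rads, pom

Categorical values are accepted case-insensitively and written in canonical
form.  An absent POM is an empty field; ``0`` always means an elicited POM
of zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .datamodel import (MODE_SESSION, MODES, CaseTruth, IntegrityError,
                        RatingRecord, SchemaError, StudyDataset)

__all__ = [
    "TRUTH_COLUMNS",
    "RATING_COLUMNS",
    "read_truth",
    "read_ratings",
    "write_truth",
    "write_ratings",
    "read_dataset",
    "write_dataset",
    "ValidationReport",
    "validate_completeness",
]

TRUTH_COLUMNS = ("case_id", "patient_id", "side", "truth", "density",
                 "finding_type", "lesion_size_mm", "histology")
RATING_COLUMNS = ("case_id", "reader_id", "mode", "session", "bi_rads", "pom")


def _load_frame(path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_truth(path) -> list[CaseTruth]:
    """Parse a truth table; raises :class:`SchemaError` naming row and field."""
    df = _load_frame(path, TRUTH_COLUMNS)
    truths: list[CaseTruth] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            size = row.lesion_size_mm.strip()
            hist = row.histology.strip()
            rec = CaseTruth(
                case_id=row.case_id.strip(),
                patient_id=row.patient_id.strip(),
                side=row.side,
                truth=row.truth,
                density=row.density,
                finding_type=row.finding_type,
                lesion_size_mm=float(size) if size else None,
                histology=hist or None,
            )
        except (SchemaError, IntegrityError, ValueError) as exc:
            raise SchemaError(f"{path} line {i}: {exc}") from exc
        if rec.case_id in seen:
            raise IntegrityError(f"{path} line {i}: duplicate case_id "
                                 f"{rec.case_id!r}")
        seen.add(rec.case_id)
        truths.append(rec)
    return truths


def read_ratings(path, on_protocol_violation: str = "warn") -> list[RatingRecord]:
    """Parse a ratings table.

    A POM attached to BI-RADS 1–2 violates the elicitation protocol but is
    recoverable: with ``on_protocol_violation="warn"`` (default) the POM is
    dropped with a warning; ``"raise"`` rejects the file.  A missing POM for
    BI-RADS >= 3 is never recoverable.
    """
    if on_protocol_violation not in ("warn", "raise"):
        raise ValueError("on_protocol_violation must be 'warn' or 'raise'")
    df = _load_frame(path, RATING_COLUMNS)
    out: list[RatingRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            bi_rads = int(row.bi_rads)
            pom_raw = row.pom.strip()
            pom: Optional[int] = int(pom_raw) if pom_raw else None
            if pom is not None and bi_rads <= 2:
                msg = (f"{path} line {i}: BI-RADS {bi_rads} with POM {pom} "
                       f"violates the elicitation protocol")
                if on_protocol_violation == "raise":
                    raise IntegrityError(msg)
                warnings.warn(msg + "; POM dropped", UserWarning, stacklevel=2)
                pom = None
            out.append(RatingRecord(
                case_id=row.case_id.strip(),
                reader_id=row.reader_id.strip(),
                mode=row.mode,
                session=int(row.session),
                bi_rads=bi_rads,
                pom=pom,
            ))
        except (SchemaError, ValueError) as exc:
            raise SchemaError(f"{path} line {i}: {exc}") from exc
        except IntegrityError as exc:
            raise IntegrityError(f"{path} line {i}: {exc}") from exc
    return out


def write_truth(truths: Sequence[CaseTruth], path) -> None:
    rows = [{
        "case_id": t.case_id, "patient_id": t.patient_id, "side": t.side,
        "truth": t.truth, "density": t.density, "finding_type": t.finding_type,
        "lesion_size_mm": "" if t.lesion_size_mm is None else t.lesion_size_mm,
        "histology": t.histology or "",
    } for t in truths]
    pd.DataFrame(rows, columns=list(TRUTH_COLUMNS)).to_csv(path, index=False)


def write_ratings(ratings: Sequence[RatingRecord], path) -> None:
    rows = [{
        "case_id": r.case_id, "reader_id": r.reader_id, "mode": r.mode,
        "session": r.session, "bi_rads": r.bi_rads,
        "pom": "" if r.pom is None else r.pom,
    } for r in ratings]
    pd.DataFrame(rows, columns=list(RATING_COLUMNS)).to_csv(path, index=False)


def read_dataset(truth_path, ratings_path, **kwargs) -> StudyDataset:
    return StudyDataset(truths=read_truth(truth_path),
                        ratings=read_ratings(ratings_path, **kwargs),
                        metadata={"provenance": "file",
                                  "truth_path": str(truth_path),
                                  "ratings_path": str(ratings_path)})


def write_dataset(ds: StudyDataset, out_dir, metadata: bool = True) -> dict:
    """Write ``truth.csv`` + ``ratings.csv`` (+ ``metadata.json``); returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"truth": out / "truth.csv", "ratings": out / "ratings.csv"}
    write_truth(ds.truths, paths["truth"])
    write_ratings(ds.ratings, paths["ratings"])
    if metadata:
        paths["metadata"] = out / "metadata.json"
        paths["metadata"].write_text(
            json.dumps(ds.metadata, indent=2, sort_keys=True, default=str))
    return {k: str(v) for k, v in paths.items()}


@dataclass
class ValidationReport:
    """Completeness audit of a study dataset.

    ``session_report_count`` counts (case, reader, session) reports for which
    every rating of the session is present — the unit the study logistics
    track (one report per case per reader per session, each carrying the 2D
    rating and the +DBT rating).
    """

    n_cases: int
    n_readers: int
    modes: list[str]
    n_ratings: int
    missing: list[tuple[str, str, str]] = field(default_factory=list)
    duplicates: list[tuple[str, str, str]] = field(default_factory=list)
    orphans: list[tuple[str, str, str]] = field(default_factory=list)
    session_report_count: int = 0

    @property
    def expected_ratings(self) -> int:
        return self.n_cases * self.n_readers * len(self.modes)

    @property
    def is_complete(self) -> bool:
        return not (self.missing or self.duplicates or self.orphans)

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_readers": self.n_readers,
            "modes": list(self.modes),
            "n_ratings": self.n_ratings,
            "expected_ratings": self.expected_ratings,
            "n_missing": len(self.missing),
            "missing": [list(t) for t in self.missing],
            "n_duplicates": len(self.duplicates),
            "duplicates": [list(t) for t in self.duplicates],
            "n_orphans": len(self.orphans),
            "orphans": [list(t) for t in self.orphans],
            "session_report_count": self.session_report_count,
            "is_complete": self.is_complete,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def validate_completeness(ds: StudyDataset,
                          readers: Optional[Sequence[str]] = None,
                          modes: Optional[Sequence[str]] = None) -> ValidationReport:
    """Audit a dataset against the full cases x readers x modes grid.

    The expected reader and mode sets default to those observed in the
    ratings; pass them explicitly to detect an entirely missing reader/mode.
    """
    readers = sorted(readers) if readers is not None else ds.reader_ids
    modes = list(modes) if modes is not None else ds.modes
    case_set = set(ds.case_ids)

    seen: dict[tuple[str, str, str], int] = {}
    orphans: list[tuple[str, str, str]] = []
    for r in ds.ratings:
        key = (r.case_id, r.reader_id, r.mode)
        seen[key] = seen.get(key, 0) + 1
        if r.case_id not in case_set:
            orphans.append(key)

    duplicates = sorted(k for k, n in seen.items() if n > 1)
    missing = sorted(
        (c, rd, m)
        for c in case_set for rd in readers for m in modes
        if (c, rd, m) not in seen
    )

    # one session report per (case, reader, session) with all its modes rated
    by_session: dict[int, list[str]] = {}
    for m in modes:
        by_session.setdefault(MODE_SESSION[m], []).append(m)
    n_reports = 0
    for c in case_set:
        for rd in readers:
            for sess, ms in by_session.items():
                if all((c, rd, m) in seen for m in ms):
                    n_reports += 1

    return ValidationReport(
        n_cases=len(case_set),
        n_readers=len(readers),
        modes=modes,
        n_ratings=len(ds.ratings),
        missing=missing,
        duplicates=duplicates,
        orphans=sorted(set(orphans)),
        session_report_count=n_reports,
    )
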