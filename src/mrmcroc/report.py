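"""Study-shaped report tables and derived arithmetic.

All numbers are carried at full precision internally; rounding (half-up)
happens exactly once, at serialization: AUCs to 3 decimals, percentages to
1 decimal, dose ratio to 1 decimal and dose fraction to whole percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import ConfigError, StudyDataset
from .bootstrap import MrmcComparison
from .metrics import BinaryPerf, perf_by_stratum
from . import roc as _roc

__all__ = [
    "round_half_up",
    "build_table1",
    "serialize_table1",
    "build_table2",
    "serialize_table2",
    "mean_birads_per_lesion",
    "build_table3",
    "derived_dose_metrics",
    "StudyReport",
]

SCORE_TYPES = ("pom", "birads")
DEFAULT_STRATA = ("overall", "non_dense", "dense", "soft_tissue",
                  "calcification")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up on the shortest repr of ``x`` (never banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def build_table1(ds: StudyDataset, modes: Optional[Sequence[str]] = None,
                 score_types: Sequence[str] = SCORE_TYPES) -> pd.DataFrame:
    """Per-reader AUCs plus the reader-averaged mean row, full precision.

    Rows: reader ids then ``mean``; columns: (score_type, mode) MultiIndex.
    The mean row is re-verified against the unweighted mean of the
    per-reader cells before the frame is returned.
    """
    modes = list(modes) if modes is not None else ds.modes
    readers = ds.reader_ids
    cols: dict[tuple[str, str], list[float]] = {}
    for st in score_types:
        for m in modes:
            aucs, mean = _roc.reader_auc_table(ds, m, st)
            col = [aucs[r] for r in readers] + [mean]
            if not np.isclose(mean, np.mean(col[:-1])):
                raise AssertionError("mean row inconsistent with per-reader cells")
            cols[(st, m)] = col
    frame = pd.DataFrame(cols, index=readers + ["mean"])
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["score_type", "mode"])
    return frame


def serialize_table1(table: pd.DataFrame, path=None) -> pd.DataFrame:
    out = table.map(lambda v: round_half_up(v, 3))
    if path is not None:
        out.to_csv(path)
    return out


def build_table2(ds: StudyDataset, modes: Optional[Sequence[str]] = None,
                 strata: Sequence[str] = DEFAULT_STRATA) -> pd.DataFrame:
    """Sensitivity/specificity grid: (stratum, metric) rows x mode columns.

    Values are proportions in [0, 1] (or NaN when undefined); percent
    formatting belongs to :func:`serialize_table2`.
    """
    modes = list(modes) if modes is not None else ds.modes
    rows = []
    index = []
    for stratum in strata:
        perfs: dict[str, BinaryPerf] = {
            m: perf_by_stratum(ds, m, stratum) for m in modes}
        for metric in ("sensitivity", "specificity"):
            index.append((stratum, metric))
            rows.append([getattr(perfs[m], metric) for m in modes])
    frame = pd.DataFrame(rows, columns=modes,
                         index=pd.MultiIndex.from_tuples(
                             index, names=["stratum", "metric"]))
    return frame.astype(float)


def serialize_table2(table: pd.DataFrame, path=None) -> pd.DataFrame:
    out = table.map(lambda v: v if pd.isna(v) else round_half_up(100.0 * v, 1))
    if path is not None:
        out.to_csv(path)
    return out


def mean_birads_per_lesion(ds: StudyDataset, mode: str,
                           finding_type: str = "calcification",
                           truth: str = "malignant") -> pd.Series:
    """Across-reader mean forced BI-RADS per lesion breast, for one mode."""
    wanted = {t.case_id for t in ds.truths
              if t.finding_type == finding_type and t.truth == truth}
    scores: dict[str, list[int]] = {c: [] for c in wanted}
    for r in ds.ratings_for(mode):
        if r.case_id in wanted:
            scores[r.case_id].append(r.bi_rads)
    if any(not v for v in scores.values()):
        raise ConfigError(f"mode {mode!r} has unrated lesions in the filter")
    return pd.Series({c: float(np.mean(v)) for c, v in sorted(scores.items())},
                     name=f"mean_birads_{mode}")


def build_table3(ds: StudyDataset, mode_a: str = "DM",
                 mode_b: str = "AICAD_SM",
                 finding_type: str = "calcification") -> pd.DataFrame:
    """Per-lesion mean BI-RADS contrast for malignant lesions of one type.

    One row per lesion: lesion size plus the across-reader mean score under
    each mode.  (The reference-standard schema carries no calcification
    morphology/distribution descriptors, so those columns of the printed
    analog are not reproduced.)
    """
    a = mean_birads_per_lesion(ds, mode_a, finding_type)
    b = mean_birads_per_lesion(ds, mode_b, finding_type)
    truth = ds.truth_by_id()
    frame = pd.DataFrame({
        "lesion_size_mm": [truth[c].lesion_size_mm for c in a.index],
        a.name: a.values, b.name: b.values,
    }, index=pd.Index(a.index, name="case_id"))
    return frame.sort_values("lesion_size_mm")


def derived_dose_metrics(dm_dose: float, dbt_dose: float) -> dict[str, float]:
    """Mean-glandular-dose arithmetic for the combined examination.

    ``combined`` = DM + DBT dose; ``ratio_combined_to_dm`` = combined / DM;
    ``sm_dbt_fraction`` = DM / combined — the share of the combined dose
    saved by replacing DM with the (dose-free) synthesized mammogram.
    """
    if dm_dose <= 0 or dbt_dose <= 0:
        raise ConfigError("doses must be positive")
    combined = dm_dose + dbt_dose
    return {"combined": combined,
            "ratio_combined_to_dm": combined / dm_dose,
            "sm_dbt_fraction": dm_dose / combined}


@dataclass
class StudyReport:
    """Bundle of all study outputs, serializable to a directory."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    comparisons: list[MrmcComparison] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_dataset(cls, ds: StudyDataset,
                     comparisons: Optional[list[MrmcComparison]] = None,
                     table3_modes: tuple[str, str] = ("DM", "AICAD_SM"),
                     ) -> "StudyReport":
        from . import __version__
        return cls(
            table1=build_table1(ds),
            table2=build_table2(ds),
            table3=build_table3(ds, *table3_modes),
            comparisons=comparisons or [],
            provenance={"dataset": dict(ds.metadata),
                        "software": f"mrmcroc {__version__}"})

    def write(self, out_dir) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        serialize_table1(self.table1, out / "table1_auc.csv")
        paths["table1"] = str(out / "table1_auc.csv")
        serialize_table2(self.table2, out / "table2_sens_spec.csv")
        paths["table2"] = str(out / "table2_sens_spec.csv")
        t3 = self.table3.copy()
        for c in t3.columns:
            if c.startswith("mean_birads"):
                t3[c] = t3[c].map(lambda v: round_half_up(v, 2))
        t3.to_csv(out / "table3_calcifications.csv")
        paths["table3"] = str(out / "table3_calcifications.csv")
        comp = [c.to_dict() for c in self.comparisons]
        (out / "comparisons.json").write_text(
            json.dumps({"comparisons": comp, "provenance": self.provenance},
                       indent=2, sort_keys=True, default=str))
        paths["comparisons"] = str(out / "comparisons.json")
        (out / "report.txt").write_text(self.render_text())
        paths["text"] = str(out / "report.txt")
        return paths

    def render_text(self) -> str:
        lines = ["Reader-study report", "===================", "",
                 "Table 1 — per-reader and mean AUC", ""]
        lines.append(serialize_table1(self.table1).to_string())
        lines += ["", "Table 2 — sensitivity/specificity (%) by stratum", ""]
        lines.append(serialize_table2(self.table2).to_string())
        lines += ["", "Table 3 — malignant calcification lesions, "
                      "mean BI-RADS per mode", ""]
        lines.append(self.table3.to_string())
        if self.comparisons:
            lines += ["", "Modality comparisons", ""]
            for c in self.comparisons:
                lines.append(
                    f"  {c.mode_a} vs {c.mode_b} [{c.score_type}]: "
                    f"diff {c.difference:+.3f} "
                    f"(CI {c.ci_low:.3f} to {c.ci_high:.3f}, "
                    f"P = {c.p_value:.4g}, B = {c.n_effective_resamples}, "
                    f"degenerate skipped = {c.n_degenerate_skipped})")
        return "\n".join(lines) + "\n"
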