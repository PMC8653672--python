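"""Survey screening against validated cut-offs and compliance summary."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, ConcStatus, inverse_signal
from .panel import PanelConfig
from .stats import POSITIVE, classify

#: columns of the screening table produced by :func:`screen_samples`
SCREENING_COLUMNS = [
    "sample_id",
    "analyte",
    "rlu",
    "cutoff",
    "call",
    "est_conc",
    "conc_status",
]


def screen_samples(
    records: pd.DataFrame,
    cutoffs: Mapping[str, float],
    models: Optional[Mapping[str, CalibrationModel]] = None,
    dilution_factor: float = 2.0,
) -> pd.DataFrame:
    """Classify survey records against per-analyte cut-offs.

    A record screens positive when its RLU is strictly below the analyte's
    cut-off. When a calibration model is supplied, the concentration is
    back-calculated from the curve and multiplied by ``dilution_factor``
    (the sample was diluted before the assay); signals at or below the
    curve background are censored (``est_conc`` NaN, status "saturated"),
    signals at or above the zero plateau report 0 µg/kg.
    """
    required = {"sample_id", "analyte", "rlu"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"sample table lacks columns: {sorted(missing_cols)}")
    present = set(records["analyte"].unique())
    uncovered = present - set(cutoffs)
    if uncovered:
        raise ValueError(f"no cut-off for analyte(s): {sorted(uncovered)}")

    rows = []
    for rec in records.itertuples(index=False):
        cutoff = float(cutoffs[rec.analyte])
        call = classify(rec.rlu, cutoff)
        est, status = math.nan, None
        if models is not None and rec.analyte in models:
            estimate = inverse_signal(float(rec.rlu), models[rec.analyte])
            status = estimate.status.value
            est = (
                estimate.value * dilution_factor
                if estimate.status is not ConcStatus.SATURATED
                else math.nan
            )
        rows.append(
            (rec.sample_id, rec.analyte, float(rec.rlu), cutoff, call, est, status)
        )
    return pd.DataFrame(rows, columns=SCREENING_COLUMNS)


@dataclass(frozen=True)
class AnalyteOccurrence:
    cutoff: float
    n_positive: int
    pct_positive: float


@dataclass(frozen=True)
class SampleCompliance:
    positive_for: tuple[str, ...]
    compliant: bool  # screen-negative for every analyte
    sulphonamide_sum: Optional[float]  # µg/kg, when concentrations available
    sulphonamide_sum_compliant: Optional[bool]


@dataclass
class SurveyReport:
    """Per-analyte occurrence and per-sample MRL-compliance summary.

    Compliance is a screening-level statement: a sample is compliant when
    it screens negative for every analyte. The sulphonamide concentration
    sum (over the 13 group members, against the 100 µg/kg group MRL) is a
    separate, optional concentration-level check, reported only when
    back-calculated concentrations are available and uncensored.
    """

    n_samples: int
    per_analyte: dict[str, AnalyteOccurrence]
    per_sample: dict[str, SampleCompliance]
    manifest: Optional[dict] = field(default=None)

    @property
    def n_compliant(self) -> int:
        return sum(s.compliant for s in self.per_sample.values())

    @property
    def pct_compliant(self) -> float:
        return 100.0 * self.n_compliant / self.n_samples

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "per_analyte": {
                n: {
                    "cutoff": a.cutoff,
                    "n_positive": a.n_positive,
                    "pct_positive": a.pct_positive,
                }
                for n, a in self.per_analyte.items()
            },
            "per_sample": {
                sid: {
                    "positive_for": list(s.positive_for),
                    "compliant": s.compliant,
                    "sulphonamide_sum": s.sulphonamide_sum,
                    "sulphonamide_sum_compliant": s.sulphonamide_sum_compliant,
                }
                for sid, s in self.per_sample.items()
            },
            "summary": {
                "n_compliant": self.n_compliant,
                "pct_compliant": self.pct_compliant,
            },
            "manifest": self.manifest,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def survey_summary(
    screening: pd.DataFrame,
    panel: PanelConfig,
    manifest: dict | None = None,
) -> SurveyReport:
    """Aggregate a screening table into occurrence and compliance counts."""
    if screening.empty:
        raise ValueError("screening table is empty")
    sample_ids = list(dict.fromkeys(screening["sample_id"]))
    n_samples = len(sample_ids)

    per_analyte: dict[str, AnalyteOccurrence] = {}
    for name in panel.names:
        sub = screening[screening["analyte"] == name]
        if sub.empty:
            continue
        n_pos = int((sub["call"] == POSITIVE).sum())
        per_analyte[name] = AnalyteOccurrence(
            cutoff=float(sub["cutoff"].iloc[0]),
            n_positive=n_pos,
            pct_positive=100.0 * n_pos / n_samples,
        )

    members = set(panel.sulphonamide_members)
    per_sample: dict[str, SampleCompliance] = {}
    for sid in sample_ids:
        sub = screening[screening["sample_id"] == sid]
        positive_for = tuple(sub.loc[sub["call"] == POSITIVE, "analyte"])
        sulph = sub[sub["analyte"].isin(members)]
        s_sum: Optional[float] = None
        s_ok: Optional[bool] = None
        if len(sulph) and sulph["conc_status"].notna().all():
            if (sulph["conc_status"] == ConcStatus.SATURATED.value).any():
                s_sum, s_ok = None, None  # censored member: sum unknowable
            else:
                s_sum = float(sulph["est_conc"].sum())
                s_ok = s_sum <= panel.sulphonamide_sum_mrl
        per_sample[sid] = SampleCompliance(
            positive_for=positive_for,
            compliant=len(positive_for) == 0,
            sulphonamide_sum=s_sum,
            sulphonamide_sum_compliant=s_ok,
        )
    return SurveyReport(
        n_samples=n_samples,
        per_analyte=per_analyte,
        per_sample=per_sample,
        manifest=manifest,
    )


def _trunc2(pct: float) -> str:
    """Percentages truncated (not rounded) to 2 decimals, as survey tables print them."""
    return f"{math.floor(pct * 100) / 100:g}"


def render_survey_table(report: SurveyReport) -> str:
    """Occurrence table: cut-off, positive count and percentage per analyte."""
    names = list(report.per_analyte)
    w = 9

    def row(label: str, cells: list[str]) -> str:
        return f"{label:<26}" + "".join(f"{c:>{w}}" for c in cells)

    lines = [
        row("", names),
        row("Number of samples", [str(report.n_samples)] * len(names)),
        row("Cut-off", [f"{report.per_analyte[n].cutoff:.2f}" for n in names]),
        row("Number of positives", [str(report.per_analyte[n].n_positive) for n in names]),
        row("% positive", [_trunc2(report.per_analyte[n].pct_positive) for n in names]),
    ]
    lines.append(
        f"\nCompliant samples: {report.n_compliant}/{report.n_samples} "
        f"({_trunc2(report.pct_compliant)}%)"
    )
    return "\n".join(lines)
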