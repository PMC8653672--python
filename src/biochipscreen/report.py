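"""Validation report container, JSON serialization and table rendering."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .stats import CcBetaDecision, CutoffResult, ErrorCounts


@dataclass(frozen=True)
class AnalyteValidation:
    """Everything the validation stage derives for one analyte."""

    cutoff: CutoffResult
    errors: dict[str, ErrorCounts]  # keyed by rule, "T" and "Fm"
    ccbeta: CcBetaDecision


@dataclass
class ValidationReport:
    """Panel-wide validation outcome.

    ``all_valid`` - every analyte satisfied T > Fm; ``all_validated`` -
    every analyte additionally met the false-compliant allowance, so its
    CCbeta equals its spike level.
    """

    cutoff_rule: str
    analytes: dict[str, AnalyteValidation]
    manifest: Optional[dict] = field(default=None)

    @property
    def all_valid(self) -> bool:
        return all(a.cutoff.valid for a in self.analytes.values())

    @property
    def all_validated(self) -> bool:
        return all(a.ccbeta.decision == "validated" for a in self.analytes.values())

    @property
    def analytes_below_mrl(self) -> int:
        return sum(bool(a.ccbeta.below_mrl) for a in self.analytes.values())

    @property
    def chosen_cutoffs(self) -> dict[str, float]:
        """Per-analyte decision boundary under the report's cut-off rule."""
        return {n: a.cutoff.chosen_cutoff for n, a in self.analytes.items()}

    def to_dict(self) -> dict:
        return {
            "cutoff_rule": self.cutoff_rule,
            "analytes": {
                name: {
                    "cutoff": {
                        "analyte": a.cutoff.analyte,
                        "blank_mean": a.cutoff.blank_mean,
                        "blank_sd": a.cutoff.blank_sd,
                        "spiked_mean": a.cutoff.spiked_mean,
                        "spiked_sd": a.cutoff.spiked_sd,
                        "t_value": a.cutoff.t_value,
                        "fm_value": a.cutoff.fm_value,
                        "valid": a.cutoff.valid,
                        "cutoff_rule": a.cutoff.cutoff_rule,
                        "chosen_cutoff": a.cutoff.chosen_cutoff,
                    },
                    "errors": {
                        rule: {
                            "analyte": e.analyte,
                            "cutoff_rule": e.cutoff_rule,
                            "cutoff": e.cutoff,
                            "n_blank": e.n_blank,
                            "n_spiked": e.n_spiked,
                            "false_positive": e.false_positive,
                            "false_negative": e.false_negative,
                            "fp_rate": e.fp_rate,
                            "fn_rate": e.fn_rate,
                        }
                        for rule, e in a.errors.items()
                    },
                    "ccbeta": {
                        "analyte": a.ccbeta.analyte,
                        "spike_level": a.ccbeta.spike_level,
                        "false_negative": a.ccbeta.false_negative,
                        "decision": a.ccbeta.decision,
                        "cc_beta": a.ccbeta.cc_beta,
                        "below_mrl": a.ccbeta.below_mrl,
                    },
                }
                for name, a in self.analytes.items()
            },
            "summary": {
                "all_valid": self.all_valid,
                "all_validated": self.all_validated,
                "analytes_below_mrl": self.analytes_below_mrl,
            },
            "manifest": self.manifest,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        analytes = {}
        for name, a in d["analytes"].items():
            c = a["cutoff"]
            cutoff = CutoffResult(
                analyte=c["analyte"],
                blank_mean=c["blank_mean"],
                blank_sd=c["blank_sd"],
                spiked_mean=c["spiked_mean"],
                spiked_sd=c["spiked_sd"],
                t_value=c["t_value"],
                fm_value=c["fm_value"],
                valid=c["valid"],
                cutoff_rule=c["cutoff_rule"],
            )
            errors = {
                rule: ErrorCounts(
                    analyte=e["analyte"],
                    cutoff_rule=e["cutoff_rule"],
                    cutoff=e["cutoff"],
                    n_blank=e["n_blank"],
                    n_spiked=e["n_spiked"],
                    false_positive=e["false_positive"],
                    false_negative=e["false_negative"],
                )
                for rule, e in a["errors"].items()
            }
            cb = a["ccbeta"]
            ccbeta = CcBetaDecision(
                analyte=cb["analyte"],
                spike_level=cb["spike_level"],
                false_negative=cb["false_negative"],
                decision=cb["decision"],
                cc_beta=cb["cc_beta"],
                below_mrl=cb["below_mrl"],
            )
            analytes[name] = AnalyteValidation(cutoff, errors, ccbeta)
        return cls(
            cutoff_rule=d["cutoff_rule"],
            analytes=analytes,
            manifest=d.get("manifest"),
        )

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls.from_dict(json.loads(text))


def _row(label: str, cells: list[str], width: int = 9) -> str:
    return f"{label:<28}" + "".join(f"{c:>{width}}" for c in cells)


def render_cutoff_table(report: ValidationReport) -> str:
    """Summary table under the Fm cut-off: T, Fm, validity, error rates."""
    names = list(report.analytes)
    rows = [
        _row("", names),
        _row("T value (RLU)", [f"{report.analytes[n].cutoff.t_value:.2f}" for n in names]),
        _row("Fm value (RLU)", [f"{report.analytes[n].cutoff.fm_value:.2f}" for n in names]),
        _row("T > Fm", ["Yes" if report.analytes[n].cutoff.valid else "No" for n in names]),
        _row("Number of FP", [str(report.analytes[n].errors["Fm"].false_positive) for n in names]),
        _row("FP rate (%)", [f"{report.analytes[n].errors['Fm'].fp_rate:g}" for n in names]),
        _row("Number of FN", [str(report.analytes[n].errors["Fm"].false_negative) for n in names]),
        _row("FN rate (%)", [f"{report.analytes[n].errors['Fm'].fn_rate:g}" for n in names]),
    ]
    return "\n".join(rows)


def render_ccbeta_table(report: ValidationReport) -> str:
    """Detection-capability table: spike level and assigned CCbeta."""
    names = list(report.analytes)
    rows = [
        _row("", names),
        _row("Spike level (ug/kg)", [f"{report.analytes[n].ccbeta.spike_level:g}" for n in names]),
        _row(
            "CCbeta (ug/kg)",
            [
                f"{report.analytes[n].ccbeta.cc_beta:g}"
                if report.analytes[n].ccbeta.cc_beta is not None
                else "escalate"
                for n in names
            ],
        ),
    ]
    return "\n".join(rows)


def render_error_table(report: ValidationReport) -> str:
    """False positives/negatives under both candidate cut-off rules."""
    names = list(report.analytes)
    rows = [
        _row("", names),
        _row("T value (RLU)", [f"{report.analytes[n].cutoff.t_value:.2f}" for n in names]),
        _row("  FP (cut-off = T)", [str(report.analytes[n].errors["T"].false_positive) for n in names]),
        _row("  FN (cut-off = T)", [str(report.analytes[n].errors["T"].false_negative) for n in names]),
        _row("Fm value (RLU)", [f"{report.analytes[n].cutoff.fm_value:.2f}" for n in names]),
        _row("  FP (cut-off = Fm)", [str(report.analytes[n].errors["Fm"].false_positive) for n in names]),
        _row("  FN (cut-off = Fm)", [str(report.analytes[n].errors["Fm"].false_negative) for n in names]),
    ]
    return "\n".join(rows)


def render_validation_tables(report: ValidationReport) -> str:
    return (
        "Cut-off summary (Fm rule)\n"
        + render_cutoff_table(report)
        + "\n\nDetection capability CCbeta\n"
        + render_ccbeta_table(report)
        + "\n\nErrors under either cut-off rule\n"
        + render_error_table(report)
    )
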