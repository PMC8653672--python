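"""Cut-off statistics for screening-method validation.

A screening method is validated per analyte from 20 blank and 20 spiked
control samples. Two candidate decision boundaries are computed on the
RLU scale:

    T  = mean(blank RLU)  - t_factor  * SD(blank RLU)      (threshold)
    Fm = mean(spiked RLU) + fm_factor * SD(spiked RLU)     (cut-off factor)

The signal is competitive (lower RLU = more analyte), so a sample screens
*positive* when its RLU falls strictly below the chosen boundary. The
validation level is usable only when T > Fm; the detection capability
CCbeta equals the spike level when at most ``max_false_compliant`` of the
spiked controls screen negative, otherwise the spike level must be
escalated and the study repeated.

SDs use the n-1 (sample) denominator, standard for small-n validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .panel import AnalyteSpec, ValidationConfig

POSITIVE = "positive"
NEGATIVE = "negative"


class InsufficientDataError(ValueError):
    """A cohort is too small for the requested statistic."""


def _as_rlu_array(values: Sequence[float], minimum: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < minimum:
        raise InsufficientDataError(
            f"{what}: need at least {minimum} values, got {arr.size}"
        )
    return arr


def threshold_T(blank_rlus: Sequence[float], t_factor: float = 1.6,
                ddof: int = 1) -> float:
    """Blank-based threshold: mean - t_factor * SD (n-1 denominator)."""
    arr = _as_rlu_array(blank_rlus, 2, "threshold_T")
    return float(arr.mean() - t_factor * arr.std(ddof=ddof))


def cutoff_Fm(spiked_rlus: Sequence[float], fm_factor: float = 1.64,
              ddof: int = 1) -> float:
    """Spiked-based cut-off factor: mean + fm_factor * SD (n-1 denominator)."""
    arr = _as_rlu_array(spiked_rlus, 2, "cutoff_Fm")
    return float(arr.mean() + fm_factor * arr.std(ddof=ddof))


def classify(rlu, cutoff: float):
    """Screening call: positive iff RLU strictly below the cut-off.

    An RLU exactly at the cut-off is a presumptive negative (the boundary
    must be deterministic even though ties are vanishingly likely with
    continuous signals). Accepts scalars or arrays.
    """
    arr = np.asarray(rlu, dtype=float)
    calls = np.where(arr < cutoff, POSITIVE, NEGATIVE)
    return str(calls) if arr.ndim == 0 else calls


@dataclass(frozen=True)
class CutoffResult:
    """Per-analyte cut-off statistics and the T > Fm validity check."""

    analyte: str
    blank_mean: float
    blank_sd: float
    spiked_mean: float
    spiked_sd: float
    t_value: float
    fm_value: float
    valid: bool
    cutoff_rule: str  # "T" or "Fm"

    @property
    def chosen_cutoff(self) -> float:
        return self.t_value if self.cutoff_rule == "T" else self.fm_value


def compute_cutoffs(
    analyte: str,
    blank_rlus: Sequence[float],
    spiked_rlus: Sequence[float],
    config: ValidationConfig,
    cutoff_rule: str = "Fm",
) -> CutoffResult:
    """Both boundaries plus summary statistics for one analyte."""
    if cutoff_rule not in ("T", "Fm"):
        raise ValueError(f"cutoff_rule must be 'T' or 'Fm', got {cutoff_rule!r}")
    blanks = _as_rlu_array(blank_rlus, 2, f"{analyte} blanks")
    spiked = _as_rlu_array(spiked_rlus, 2, f"{analyte} spiked")
    t = threshold_T(blanks, config.t_factor)
    fm = cutoff_Fm(spiked, config.fm_factor)
    return CutoffResult(
        analyte=analyte,
        blank_mean=float(blanks.mean()),
        blank_sd=float(blanks.std(ddof=1)),
        spiked_mean=float(spiked.mean()),
        spiked_sd=float(spiked.std(ddof=1)),
        t_value=t,
        fm_value=fm,
        valid=t > fm,
        cutoff_rule=cutoff_rule,
    )


@dataclass(frozen=True)
class ErrorCounts:
    """False-positive / false-negative bookkeeping under one cut-off rule.

    A *false positive* is a blank control screening positive (RLU below the
    cut-off); a *false negative* (false compliant) is a spiked control
    screening negative (RLU at or above the cut-off).
    """

    analyte: str
    cutoff_rule: str
    cutoff: float
    n_blank: int
    n_spiked: int
    false_positive: int
    false_negative: int

    @property
    def fp_rate(self) -> float:
        """False-positive percentage of the blank cohort."""
        return 100.0 * self.false_positive / self.n_blank

    @property
    def fn_rate(self) -> float:
        """False-negative percentage of the spiked cohort."""
        return 100.0 * self.false_negative / self.n_spiked


def count_errors(
    blank_rlus: Sequence[float],
    spiked_rlus: Sequence[float],
    cutoff: float,
    rule_label: str,
    analyte: str = "",
) -> ErrorCounts:
    """Tally screening errors of both control cohorts against a cut-off."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    blanks = _as_rlu_array(blank_rlus, 1, f"{analyte} blanks")
    spiked = _as_rlu_array(spiked_rlus, 1, f"{analyte} spiked")
    fp = int(np.count_nonzero(blanks < cutoff))
    fn = int(np.count_nonzero(spiked >= cutoff))
    return ErrorCounts(
        analyte=analyte,
        cutoff_rule=rule_label,
        cutoff=float(cutoff),
        n_blank=blanks.size,
        n_spiked=spiked.size,
        false_positive=fp,
        false_negative=fn,
    )


@dataclass(frozen=True)
class CcBetaDecision:
    """Detection-capability decision for one analyte at its spike level.

    ``validated`` means the false-compliant allowance was met, so CCbeta
    equals the spike level; ``escalate`` means the spike level must be
    raised and the validation repeated with fresh data.
    """

    analyte: str
    spike_level: float
    false_negative: int
    decision: str  # "validated" or "escalate"
    cc_beta: Optional[float]
    below_mrl: Optional[bool]


def decide_ccbeta(
    errors: ErrorCounts, spec: AnalyteSpec, config: ValidationConfig
) -> CcBetaDecision:
    """Apply the one-or-none false-compliant rule to assign CCbeta.

    ``errors`` must be the counts under the Fm rule (the decision boundary
    used for positivity). For regulated analytes CCbeta is compared to the
    MRL; for prohibited substances, to the screening target.
    """
    if errors.analyte and errors.analyte != spec.name:
        raise ValueError(
            f"error counts are for {errors.analyte!r}, spec is {spec.name!r}"
        )
    if errors.cutoff_rule != "Fm":
        raise ValueError("CCbeta is decided under the Fm cut-off rule")
    if errors.false_negative <= config.max_false_compliant:
        cc = spec.spike_level
        return CcBetaDecision(
            analyte=spec.name,
            spike_level=spec.spike_level,
            false_negative=errors.false_negative,
            decision="validated",
            cc_beta=cc,
            below_mrl=cc <= spec.action_limit,
        )
    return CcBetaDecision(
        analyte=spec.name,
        spike_level=spec.spike_level,
        false_negative=errors.false_negative,
        decision="escalate",
        cc_beta=None,
        below_mrl=None,
    )
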