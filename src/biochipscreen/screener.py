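"""Cut-off screening as a scikit-learn estimator, plus the panel wrapper.

:class:`CutoffScreener` is the fit/predict core: fitting on labelled blank
and spiked control signals computes the two candidate decision boundaries
(threshold T from blanks, cut-off factor Fm from spiked controls);
prediction classifies signals as screen positive (RLU strictly below the
chosen boundary) or presumptive negative. :func:`validate_panel` runs one
screener per analyte over a tidy sample table and assembles the full
validation report.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .panel import PanelConfig, ValidationConfig
from .report import AnalyteValidation, ValidationReport
from .stats import (
    NEGATIVE,
    POSITIVE,
    compute_cutoffs,
    count_errors,
    decide_ccbeta,
)

BLANK, SPIKED = "blank", "spiked"


class CutoffScreener(BaseEstimator):
    """Screening classifier with a control-derived RLU decision boundary.

    Parameters
    ----------
    cutoff_rule : {"Fm", "T"}, default "Fm"
        Which boundary classifies samples. Fm (spiked mean + ``fm_factor``
        SD) targets a 5% false-compliant rate; T (blank mean - ``t_factor``
        SD) is more sensitive but raises the false-positive rate.
    t_factor, fm_factor : float
        SD multipliers of the two boundaries.
    ddof : int, default 1
        Delta degrees of freedom of the SDs (1 = sample SD).

    Attributes (after fit)
    ----------------------
    blank_mean_, blank_sd_, spiked_mean_, spiked_sd_ : float
    t_value_, fm_value_ : float
        The two candidate boundaries in RLU.
    valid_ : bool
        Whether T > Fm, i.e. whether the validation level is usable.
    cutoff_ : float
        The boundary selected by ``cutoff_rule``.
    """

    def __init__(self, cutoff_rule: str = "Fm", t_factor: float = 1.6,
                 fm_factor: float = 1.64, ddof: int = 1):
        self.cutoff_rule = cutoff_rule
        self.t_factor = t_factor
        self.fm_factor = fm_factor
        self.ddof = ddof

    def _check_params(self) -> None:
        if self.cutoff_rule not in ("T", "Fm"):
            raise ValueError("cutoff_rule must be 'T' or 'Fm'")
        for name in ("t_factor", "fm_factor"):
            v = getattr(self, name)
            if not (isinstance(v, numbers.Real) and v > 0):
                raise ValueError(f"{name} must be a positive number")

    def fit(self, X, y) -> "CutoffScreener":
        """Compute both boundaries from labelled control signals.

        X is a column of RLU values; y labels each row ``"blank"`` or
        ``"spiked"`` (0/1 are accepted as aliases, 0 = blank).
        """
        self._check_params()
        X = check_array(X, ensure_2d=False, dtype=float)
        if X.ndim == 2 and X.shape[1] != 1:
            raise ValueError("X must be a single column of RLU values")
        rlu = X.ravel()
        y = np.asarray(y)
        if y.shape[0] != rlu.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if y.dtype.kind in "iub":
            labels = np.where(y == 0, BLANK, SPIKED).astype(object)
        else:
            labels = y.astype(object)
        bad = set(labels) - {BLANK, SPIKED}
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(map(str, bad))}")
        blanks = rlu[labels == BLANK]
        spiked = rlu[labels == SPIKED]
        cfg = ValidationConfig(
            n_blank=max(2, blanks.size),
            n_spiked=max(2, spiked.size),
            t_factor=self.t_factor,
            fm_factor=self.fm_factor,
        )
        res = compute_cutoffs("", blanks, spiked, cfg, self.cutoff_rule)
        self.blank_mean_ = res.blank_mean
        self.blank_sd_ = res.blank_sd
        self.spiked_mean_ = res.spiked_mean
        self.spiked_sd_ = res.spiked_sd
        self.t_value_ = res.t_value
        self.fm_value_ = res.fm_value
        self.valid_ = res.valid
        self.cutoff_ = res.chosen_cutoff
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed margin above the cut-off (negative = screen positive)."""
        check_is_fitted(self, "cutoff_")
        X = check_array(X, ensure_2d=False, dtype=float)
        return X.ravel() - self.cutoff_

    def predict(self, X) -> np.ndarray:
        """Screening calls: ``"positive"`` iff RLU strictly below cut-off."""
        margin = self.decision_function(X)
        return np.where(margin < 0, POSITIVE, NEGATIVE)


def _split_cohorts(records: pd.DataFrame, analyte: str) -> tuple[np.ndarray, np.ndarray]:
    sub = records[records["analyte"] == analyte]
    blanks = sub.loc[sub["cohort"] == BLANK, "rlu"].to_numpy(dtype=float)
    spiked = sub.loc[sub["cohort"] == SPIKED, "rlu"].to_numpy(dtype=float)
    if blanks.size < 2 or spiked.size < 2:
        raise ValueError(
            f"analyte {analyte!r}: validation needs >=2 blank and >=2 spiked "
            f"records (got {blanks.size} blank, {spiked.size} spiked)"
        )
    return blanks, spiked


def validate_panel(
    records: pd.DataFrame,
    panel: PanelConfig,
    cutoff_rule: str = "Fm",
    manifest: dict | None = None,
) -> ValidationReport:
    """Run the cut-off validation for every panel analyte.

    ``records`` is a tidy sample table (columns ``analyte``, ``cohort``,
    ``rlu``) containing blank and spiked cohorts for each analyte. Returns
    the per-analyte cut-off statistics, error counts under both rules and
    the CCbeta decision (always taken under the Fm rule).
    """
    required = {"analyte", "cohort", "rlu"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"sample table lacks columns: {sorted(missing_cols)}")
    cfg = panel.validation
    out: dict[str, AnalyteValidation] = {}
    for spec in panel.analytes:
        blanks, spiked = _split_cohorts(records, spec.name)
        screener = CutoffScreener(
            cutoff_rule=cutoff_rule, t_factor=cfg.t_factor, fm_factor=cfg.fm_factor
        ).fit(
            np.concatenate([blanks, spiked]),
            np.array([BLANK] * blanks.size + [SPIKED] * spiked.size, dtype=object),
        )
        cutoff = compute_cutoffs(spec.name, blanks, spiked, cfg, cutoff_rule)
        errors = {
            rule: count_errors(blanks, spiked, value, rule, spec.name)
            for rule, value in (("T", screener.t_value_), ("Fm", screener.fm_value_))
        }
        ccbeta = decide_ccbeta(errors["Fm"], spec, cfg)
        out[spec.name] = AnalyteValidation(cutoff=cutoff, errors=errors, ccbeta=ccbeta)
    return ValidationReport(cutoff_rule=cutoff_rule, analytes=out, manifest=manifest)
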