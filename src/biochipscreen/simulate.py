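"""Seeded synthetic RLU cohort generators.

Emulates the data layout of a biochip cut-off validation study: the same
physical milk samples are measured for every analyte on one biochip, so
each sample carries a shared matrix factor that moves all of its analyte
signals together, on top of per-measurement noise and a small additive
detector floor.

Both multiplicative components are left-skewed and bounded above: the
chemiluminescent yield of a test region is ceiling-limited (losses -
matrix interference, incomplete binding, washing - can only subtract
light), and gross outlier runs are excluded by QC-gated reanalysis. The
heavy lower / light upper tail this produces is what a competitive-assay
validation data set shows: blanks occasionally dip below the blank-based
threshold T, while spiked signals almost never exceed the spiked-based
cut-off Fm by more than the one-or-none allowance.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .calibration import CalibrationModel, signal_at
from .panel import PanelConfig

MILK_TYPES = ("skimmed", "semi", "full_fat")

#: column order of every sample table emitted by this module
SAMPLE_COLUMNS = [
    "sample_id",
    "analyte",
    "rlu",
    "cohort",
    "true_conc",
    "milk_type",
    "seed_meta",
]


class NoiseModel(BaseModel):
    """Signal-noise structure of the simulated assay.

    ``sample_cv`` is the coefficient of variation of the per-sample matrix
    factor (shared by all analytes of one sample); ``meas_cv`` that of the
    independent per-measurement factor. Both factors are drawn from a
    reflected lognormal with upper cap ``1 + skew_cap*cv`` and lower clip
    ``1 - lower_clip*cv`` (left-skewed, bounded). ``floor_sd`` is the SD of
    additive Gaussian detector noise in RLU. ``matrix_shift`` scales the
    signal per milk type (defaults 1.0: fat content does not affect the
    assay).
    """

    model_config = ConfigDict(frozen=True)

    sample_cv: float = Field(default=0.08, ge=0)
    meas_cv: float = Field(default=0.06, ge=0)
    skew_cap: float = Field(default=0.6, gt=0)
    lower_clip: float = Field(default=3.0, gt=0)
    floor_sd: float = Field(default=5.0, ge=0)
    matrix_shift: dict[str, float] = Field(
        default_factory=lambda: {t: 1.0 for t in MILK_TYPES}
    )

    @model_validator(mode="after")
    def _check(self) -> "NoiseModel":
        if any(v <= 0 for v in self.matrix_shift.values()):
            raise ValueError("matrix_shift factors must be positive")
        return self

    @property
    def total_cv(self) -> float:
        """Combined multiplicative CV of both noise factors."""
        return float(np.hypot(self.sample_cv, self.meas_cv))

    def scaled(self, factor: float) -> "NoiseModel":
        """Copy with both multiplicative CVs scaled by ``factor``."""
        return self.model_copy(
            update={
                "sample_cv": self.sample_cv * factor,
                "meas_cv": self.meas_cv * factor,
            }
        )

    def draw_factors(self, rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
        """Draw ``size`` bounded left-skewed multiplicative factors, mean ~1."""
        if cv == 0:
            return np.ones(size)
        k = self.skew_cap * cv
        s2 = np.log1p(1.0 / self.skew_cap**2)
        mu = np.log(k) - s2 / 2.0
        m = (1.0 + k) - rng.lognormal(mu, np.sqrt(s2), size)
        return np.clip(m, 1.0 - self.lower_clip * cv, None)


def _require_models(
    panel: PanelConfig, models: Mapping[str, CalibrationModel]
) -> None:
    missing = [n for n in panel.names if n not in models]
    if missing:
        raise ValueError(f"no calibration model for analyte(s): {missing}")


def _measure(
    conc: np.ndarray,
    model: CalibrationModel,
    shift: np.ndarray,
    sample_factor: np.ndarray,
    meas_factor: np.ndarray,
    floor: np.ndarray,
    dilution_factor: float,
) -> np.ndarray:
    """Noisy RLU of samples at true (undiluted) concentrations ``conc``."""
    clean = signal_at(conc / dilution_factor, model)
    return np.clip(clean * shift * sample_factor * meas_factor + floor, 0.0, None)


def generate_validation_cohort(
    panel: PanelConfig,
    models: Mapping[str, CalibrationModel],
    noise: NoiseModel,
    seed: int,
) -> pd.DataFrame:
    """Blank and spiked validation cohorts for every panel analyte.

    Emits ``n_blank`` blank records (true concentration 0) and ``n_spiked``
    records spiked at the analyte's spike level, for each analyte, as one
    tidy table (one row per sample x analyte measurement). Milk types cycle
    through skimmed/semi/full-fat across samples.
    """
    _require_models(panel, models)
    rng = np.random.default_rng(seed)
    cfg = panel.validation
    nb, ns = cfg.n_blank, cfg.n_spiked
    meta = f"validation:seed={seed}"

    blank_ids = [f"VB{i + 1:02d}" for i in range(nb)]
    spike_ids = [f"VS{i + 1:02d}" for i in range(ns)]
    blank_milk = [MILK_TYPES[i % 3] for i in range(nb)]
    spike_milk = [MILK_TYPES[i % 3] for i in range(ns)]
    blank_shift = np.array([noise.matrix_shift.get(t, 1.0) for t in blank_milk])
    spike_shift = np.array([noise.matrix_shift.get(t, 1.0) for t in spike_milk])

    # shared per-sample matrix factors, one per physical milk sample
    m_blank = noise.draw_factors(rng, noise.sample_cv, nb)
    m_spiked = noise.draw_factors(rng, noise.sample_cv, ns)

    frames = []
    for name in panel.names:
        model = models[name]
        spike = panel[name].spike_level
        for ids, milk, shift, m, conc in (
            (blank_ids, blank_milk, blank_shift, m_blank, np.zeros(nb)),
            (spike_ids, spike_milk, spike_shift, m_spiked, np.full(ns, spike)),
        ):
            meas = noise.draw_factors(rng, noise.meas_cv, len(ids))
            floor = rng.normal(0.0, noise.floor_sd, len(ids)) if noise.floor_sd else np.zeros(len(ids))
            rlu = _measure(conc, model, shift, m, meas, floor, cfg.dilution_factor)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": ids,
                        "analyte": name,
                        "rlu": rlu,
                        "cohort": "blank" if conc[0] == 0 else "spiked",
                        "true_conc": conc,
                        "milk_type": milk,
                        "seed_meta": meta,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[SAMPLE_COLUMNS]


def generate_survey_cohort(
    panel: PanelConfig,
    models: Mapping[str, CalibrationModel],
    noise: NoiseModel,
    n_samples: int,
    prevalence: Union[float, Mapping[str, float]] = 0.0,
    conc_distribution: Optional[Mapping[str, Callable[[np.random.Generator], float]]] = None,
    milk_mix: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    forced_contamination: Optional[Mapping[str, Mapping[int, float]]] = None,
) -> pd.DataFrame:
    """A survey cohort: ``n_samples`` milks each measured for every analyte.

    Each sample is independently contaminated with analyte ``a`` with
    probability ``prevalence[a]``; contaminated concentrations come from
    ``conc_distribution[a]`` (default: uniform between the spike level and
    twice the spike level, inside every analyte's calibration range).
    ``forced_contamination`` deterministically overrides specific samples,
    e.g. ``{"SMTZ": {11: 25.0}}`` contaminates sample index 11 with
    25 µg/kg SMTZ regardless of prevalence draws.

    ``milk_mix`` gives milk-type proportions (default 15/53 skimmed,
    17/53 semi, 21/53 full-fat, the survey's composition).
    """
    _require_models(panel, models)
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")

    if milk_mix is None:
        milk_mix = {"skimmed": 15 / 53, "semi": 17 / 53, "full_fat": 21 / 53}
    probs = np.array([milk_mix.get(t, 0.0) for t in MILK_TYPES], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("milk_mix proportions must be nonnegative and sum to 1")

    if isinstance(prevalence, Mapping):
        prev = {n: float(prevalence.get(n, 0.0)) for n in panel.names}
    else:
        prev = {n: float(prevalence) for n in panel.names}
    if any(not 0.0 <= p <= 1.0 for p in prev.values()):
        raise ValueError("prevalence must lie in [0, 1]")

    forced = forced_contamination or {}
    unknown = set(forced) - set(panel.names)
    if unknown:
        raise ValueError(f"forced_contamination names unknown analytes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    meta = f"survey:seed={seed}"
    width = max(2, len(str(n_samples)))
    ids = [f"M{i + 1:0{width}d}" for i in range(n_samples)]

    milk = [MILK_TYPES[i] for i in rng.choice(3, size=n_samples, p=probs)]
    shift = np.array([noise.matrix_shift.get(t, 1.0) for t in milk])
    m_sample = noise.draw_factors(rng, noise.sample_cv, n_samples)

    frames = []
    for name in panel.names:
        model = models[name]
        spike = panel[name].spike_level
        contaminated = rng.random(n_samples) < prev[name]
        conc = np.zeros(n_samples)
        draw = (
            conc_distribution[name]
            if conc_distribution and name in conc_distribution
            else (lambda r, s=spike: r.uniform(s, 2.0 * s))
        )
        for i in np.nonzero(contaminated)[0]:
            conc[i] = draw(rng)
        for i, c in forced.get(name, {}).items():
            if not 0 <= i < n_samples:
                raise ValueError(f"forced_contamination index {i} out of range")
            conc[i] = float(c)
        meas = noise.draw_factors(rng, noise.meas_cv, n_samples)
        floor = rng.normal(0.0, noise.floor_sd, n_samples) if noise.floor_sd else np.zeros(n_samples)
        rlu = _measure(conc, model, shift, m_sample, meas, floor,
                       panel.validation.dilution_factor)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "analyte": name,
                    "rlu": rlu,
                    "cohort": "survey",
                    "true_conc": conc,
                    "milk_type": milk,
                    "seed_meta": meta,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[SAMPLE_COLUMNS]
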