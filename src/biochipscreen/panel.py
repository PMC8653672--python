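"""Analyte panel configuration.

The default panel is the 15-analyte antimicrobial array for milk: 13
sulphonamides (whose residues count jointly toward a 100 µg/kg group MRL),
trimethoprim (own MRL, 50 µg/kg) and dapsone (prohibited substance, no MRL).
Each analyte carries its regulatory limit, the spike level used to build
positive validation controls (at or below half the regulatory limit), the
kit's calibration range (already expressed on the undiluted-sample scale,
i.e. accounting for the 1:1 wash-buffer dilution) and the manufacturer's
limit of detection.
"""

from __future__ import annotations

import importlib.resources
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class PanelConfigError(ValueError):
    """Raised when a panel document violates the configuration schema."""


class AnalyteSpec(BaseModel):
    """Regulatory and assay constants for a single analyte.

    Concentrations are in µg/kg (ppb) on the undiluted-sample scale.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    full_name: str = ""
    mrl: Optional[float] = None
    prohibited: bool = False
    spike_level: float = Field(gt=0)
    calib_min: float = Field(ge=0)
    calib_max: float
    lod: float = Field(gt=0)
    screening_target: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "AnalyteSpec":
        if self.calib_max <= self.calib_min:
            raise ValueError(f"{self.name}: calib_max must exceed calib_min")
        if not (self.lod < self.spike_level <= self.calib_max):
            raise ValueError(
                f"{self.name}: require lod < spike_level <= calib_max "
                f"(got lod={self.lod}, spike={self.spike_level}, "
                f"calib_max={self.calib_max})"
            )
        if self.prohibited:
            if self.mrl is not None:
                raise ValueError(f"{self.name}: prohibited substances have no MRL")
            if self.screening_target is None:
                raise ValueError(
                    f"{self.name}: prohibited substances need a screening_target"
                )
        else:
            if self.mrl is None:
                raise ValueError(f"{self.name}: non-prohibited analytes need an MRL")
            if self.spike_level > self.mrl:
                raise ValueError(
                    f"{self.name}: spike_level {self.spike_level} exceeds "
                    f"MRL {self.mrl}"
                )
        return self

    @property
    def action_limit(self) -> float:
        """MRL for regulated analytes, screening target for prohibited ones."""
        return self.screening_target if self.prohibited else self.mrl  # type: ignore[return-value]


class ValidationConfig(BaseModel):
    """Design constants of the cut-off validation study.

    ``t_factor`` and ``fm_factor`` are the SD multipliers of the blank-based
    threshold T and the spiked-based cut-off factor Fm; 1.64 is the one-sided
    5% normal quantile used for a target false-compliant rate beta = 0.05.
    ``dilution_factor`` is the sample dilution ahead of the assay (1:1 with
    wash buffer, i.e. 2).
    """

    model_config = ConfigDict(frozen=True)

    n_blank: int = Field(default=20, ge=2)
    n_spiked: int = Field(default=20, ge=2)
    t_factor: float = Field(default=1.6, gt=0)
    fm_factor: float = Field(default=1.64, gt=0)
    max_false_compliant: int = Field(default=1, ge=0)
    beta: float = Field(default=0.05, gt=0, lt=1)
    dilution_factor: float = Field(default=2.0, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "ValidationConfig":
        if self.max_false_compliant >= self.n_spiked:
            raise ValueError("max_false_compliant must be below n_spiked")
        return self


class PanelConfig(BaseModel):
    """An ordered analyte panel plus validation design constants."""

    model_config = ConfigDict(frozen=True)

    analytes: tuple[AnalyteSpec, ...]
    validation: ValidationConfig = ValidationConfig()
    sulphonamide_members: tuple[str, ...] = ()
    sulphonamide_sum_mrl: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "PanelConfig":
        names = [a.name for a in self.analytes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate analyte names: {sorted(dupes)}")
        unknown = set(self.sulphonamide_members) - set(names)
        if unknown:
            raise ValueError(
                f"sulphonamide_members not in panel: {sorted(unknown)}"
            )
        return self

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    def __getitem__(self, name: str) -> AnalyteSpec:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    def serialize(self) -> str:
        """Render the panel as a YAML document (round-trips via load_panel)."""
        return yaml.safe_dump(
            self.model_dump(mode="json"), sort_keys=False, default_flow_style=False
        )


def load_panel(document: str) -> PanelConfig:
    """Parse a YAML/JSON panel document into a validated :class:`PanelConfig`.

    Unspecified fields take their defaults. Raises :class:`PanelConfigError`
    naming the offending field on any schema or invariant violation.
    """
    try:
        raw = yaml.safe_load(document)
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise PanelConfigError(f"panel document is not valid YAML/JSON: {exc}")
    if not isinstance(raw, dict):
        raise PanelConfigError("panel document must be a mapping")
    try:
        return PanelConfig.model_validate(raw)
    except Exception as exc:
        raise PanelConfigError(str(exc)) from exc


def default_panel() -> PanelConfig:
    """The packaged 15-analyte milk panel (13 sulphonamides, DAP, TMPM)."""
    text = (
        importlib.resources.files("biochipscreen")
        .joinpath("data/default_panel.yaml")
        .read_text()
    )
    return load_panel(text)
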