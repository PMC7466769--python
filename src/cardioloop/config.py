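"""Configuration schema and loader.

One YAML document describes one experiment: every model parameter carries a
``base_value``, a ``units`` string and a ``multiplier`` (sweeps adjust only
multipliers, keeping proportional changes well-defined).  Unknown keys are
rejected so typos fail loudly.  The shipped ``data/default_config.yaml``
holds the calibrated base parameterization that produces the package's
reference baseline run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .half_sarcomere import SarcomereParams
from .hemodynamics import CirculationParams
from .membrane_ep import EpParams

__all__ = [
    "Param", "ConfigDocument", "load_and_validate_config", "save_config",
    "PARAM_GROUPS", "SWEEPABLE_PARAMS", "DEFAULT_MULTIPLIERS",
]

_KNOWN_UNITS = {
    "", "dimensionless", "x published",
    "mM^-1 s^-1", "s^-1", "s^-1 nm^-1", "s^-1 nm^-4",
    "N m^-1", "nm", "m^-2", "N m^-2", "m^2 N^-1",
    "liters", "L", "L mmHg^-1", "mmHg s L^-1",
    "Hz", "ms", "pA pF^-1",
}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Param(_Strict):
    """A model parameter: published/calibrated base value times a
    strictly positive multiplier."""

    base_value: float
    units: str = ""
    multiplier: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _check_units(self):
        if self.units not in _KNOWN_UNITS:
            raise ValueError(f"unknown units string {self.units!r}")
        return self

    @property
    def effective(self) -> float:
        return self.base_value * self.multiplier


def _p(v: float, units: str = "") -> Param:
    return Param(base_value=v, units=units)


class ElectrophysiologyBlock(_Strict):
    """Adjustable ionic-model parameters, as factors on published values."""

    Ca_Vleak: Param = _p(1.0, "x published")
    Ca_Vmaxup: Param = _p(1.0, "x published")
    g_CaL: Param = _p(1.0, "x published")
    g_to: Param = _p(1.0, "x published")
    g_Kr: Param = _p(1.0, "x published")
    g_Ks: Param = _p(1.0, "x published")


class SarcomereBlock(_Strict):
    k_on: Param = _p(SarcomereParams.k_on, "mM^-1 s^-1")
    k_off: Param = _p(SarcomereParams.k_off, "s^-1")
    k_coop: Param = _p(SarcomereParams.k_coop, "dimensionless")
    k_1: Param = _p(SarcomereParams.k_1, "s^-1")
    k_2: Param = _p(SarcomereParams.k_2, "s^-1")
    k_3: Param = _p(SarcomereParams.k_3, "s^-1 nm^-1")
    k_4_0: Param = _p(SarcomereParams.k_4_0, "s^-1")
    k_4_1: Param = _p(SarcomereParams.k_4_1, "s^-1 nm^-4")
    k_cb: Param = _p(SarcomereParams.k_cb, "N m^-1")
    x_ps: Param = _p(SarcomereParams.x_ps, "nm")
    N_0: Param = _p(SarcomereParams.N_0, "m^-2")
    sigma: Param = _p(SarcomereParams.sigma, "N m^-2")
    L: Param = _p(SarcomereParams.L, "nm")
    L_slack: Param = _p(SarcomereParams.L_slack, "nm")
    k_force: Param = _p(SarcomereParams.k_force, "m^2 N^-1")
    n_overlap: Param = _p(SarcomereParams.n_overlap, "dimensionless")
    w_ascending: Param = _p(SarcomereParams.w_ascending, "nm")
    hsl_full_overlap: Param = _p(SarcomereParams.hsl_full_overlap, "nm")
    hsl_desc_start: Param = _p(SarcomereParams.hsl_desc_start, "nm")
    hsl_desc_end: Param = _p(SarcomereParams.hsl_desc_end, "nm")
    hsl_zero_overlap: Param = _p(SarcomereParams.hsl_zero_overlap, "nm")


class VentricleBlock(_Strict):
    V_slack: Param = _p(0.1, "L")
    W_volume: Param = _p(0.1, "L")
    V_residual: Param = _p(0.008, "L")


class CirculationBlock(_Strict):
    C_aorta: Param = _p(1.35e-3, "L mmHg^-1")
    C_arteries: Param = _p(9.0e-4, "L mmHg^-1")
    C_arterioles: Param = _p(1.5e-3, "L mmHg^-1")
    C_capillaries: Param = _p(5.0e-3, "L mmHg^-1")
    C_veins: Param = _p(0.45, "L mmHg^-1")
    R_aortic_valve: Param = _p(15.0, "mmHg s L^-1")
    R_arteries: Param = _p(25.0, "mmHg s L^-1")
    R_arterioles: Param = _p(1100.0, "mmHg s L^-1")
    R_capillaries: Param = _p(350.0, "mmHg s L^-1")
    R_veins: Param = _p(80.0, "mmHg s L^-1")
    R_venous_return: Param = _p(30.0, "mmHg s L^-1")
    V_total: Param = _p(5.0, "L")


class ProtocolBlock(_Strict):
    n_beats: int = Field(default=17, ge=1)
    rate_hz: float = Field(default=1.0, gt=0.0)
    stim_amplitude: float = -52.0      # pA/pF (negative = depolarizing)
    stim_duration_ms: float = Field(default=3.0, gt=0.0)
    initial_fill_fraction: float = Field(default=1.5, gt=0.0)
    withdrawal_fraction: float = Field(default=0.6, ge=0.0, lt=1.0)
    withdrawal_start_beat: int = Field(default=10, ge=1)
    withdrawal_end_beat: int = Field(default=15, ge=1)

    @model_validator(mode="after")
    def _check_window(self):
        if self.withdrawal_fraction > 0.0:
            if not (self.withdrawal_start_beat < self.withdrawal_end_beat
                    <= self.n_beats):
                raise ValueError("withdrawal window must lie within the beats")
        return self


class NumericsBlock(_Strict):
    dt_ms: float = Field(default=1.0, gt=0.0)
    hemo_substeps: int = Field(default=8, ge=1)
    sarcomere_substeps: int = Field(default=1, ge=1)
    ep_prepace_beats: int = Field(default=1000, ge=1)
    strain_x_min: float = -10.0
    strain_x_max: float = 10.0
    strain_dx: float = Field(default=0.5, gt=0.0)


class OutputBlock(_Strict):
    directory: str = "out"
    cadence_ms: float = Field(default=1.0, gt=0.0)


class SweepsBlock(_Strict):
    parameters: list[str] = Field(default_factory=lambda: list(SWEEPABLE_PARAMS))
    multipliers: list[float] = Field(
        default_factory=lambda: list(DEFAULT_MULTIPLIERS))


# the swept parameters, clustered by model level
PARAM_GROUPS = {
    "sarcomeric": ["k_1", "k_2", "k_3", "k_4_0", "k_cb", "k_force", "k_on",
                   "k_off", "k_coop", "sigma", "L", "L_slack"],
    "electrophysiological": ["Ca_Vleak", "Ca_Vmaxup", "g_CaL", "g_to",
                             "g_Kr", "g_Ks"],
    "circulatory": ["V_slack", "W_volume", "C_veins", "C_aorta",
                    "R_arterioles", "V_total"],
}
SWEEPABLE_PARAMS = tuple(n for names in PARAM_GROUPS.values() for n in names)

# 9 log-spaced multipliers spanning 0.1-10x, including the base value
DEFAULT_MULTIPLIERS = (0.1, 0.178, 0.316, 0.562, 1.0, 1.78, 3.16, 5.62, 10.0)


class ConfigDocument(_Strict):
    """Versioned experiment description (see module docstring)."""

    version: int = 1
    electrophysiology: ElectrophysiologyBlock = ElectrophysiologyBlock()
    sarcomere: SarcomereBlock = SarcomereBlock()
    ventricle: VentricleBlock = VentricleBlock()
    circulation: CirculationBlock = CirculationBlock()
    protocol: ProtocolBlock = ProtocolBlock()
    numerics: NumericsBlock = NumericsBlock()
    output: OutputBlock = OutputBlock()
    sweeps: SweepsBlock = SweepsBlock()

    # ---- effective model parameter objects -------------------------------
    def ep_params(self) -> EpParams:
        b = self.electrophysiology
        return EpParams(**{n: getattr(b, n).effective
                           for n in ("Ca_Vleak", "Ca_Vmaxup", "g_CaL",
                                     "g_to", "g_Kr", "g_Ks")})

    def sarcomere_params(self) -> SarcomereParams:
        b = self.sarcomere
        kw = {n: getattr(b, n).effective for n in type(b).model_fields}
        kw.update(x_min=self.numerics.strain_x_min,
                  x_max=self.numerics.strain_x_max,
                  dx=self.numerics.strain_dx)
        return SarcomereParams(**kw)

    def circulation_params(self) -> CirculationParams:
        b = self.circulation
        C = {n[2:]: getattr(b, "C_" + n[2:]).effective
             for n in ("C_aorta", "C_arteries", "C_arterioles",
                       "C_capillaries", "C_veins")}
        R = {n[2:]: getattr(b, "R_" + n[2:]).effective
             for n in ("R_aortic_valve", "R_arteries", "R_arterioles",
                       "R_capillaries", "R_veins", "R_venous_return")}
        return CirculationParams(C=C, R=R, V_total=b.V_total.effective)

    # ---- parameter addressing for sweeps ---------------------------------
    def _locate(self, name: str):
        for block_name in ("electrophysiology", "sarcomere", "ventricle",
                           "circulation"):
            block = getattr(self, block_name)
            if name in type(block).model_fields:
                return block
        raise KeyError(f"unknown model parameter {name!r}")

    def get_multiplier(self, name: str) -> float:
        return getattr(self._locate(name), name).multiplier

    def with_multiplier(self, name: str, multiplier: float) -> "ConfigDocument":
        """A deep copy with one parameter's multiplier replaced."""
        new = self.model_copy(deep=True)
        param = getattr(new._locate(name), name)
        param.multiplier = multiplier
        return new

    def group_of(self, name: str) -> str:
        for group, names in PARAM_GROUPS.items():
            if name in names:
                return group
        return "other"

    # ---- serialization ---------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "default_config.yaml"


def load_and_validate_config(path: Optional[str] = None) -> ConfigDocument:
    """Load a YAML experiment file (the shipped default when ``path`` is
    None) and validate it against the schema."""
    p = Path(path) if path is not None else default_config_path()
    with open(p) as fh:
        raw = yaml.safe_load(fh) or {}
    return ConfigDocument.model_validate(raw)


def save_config(config: ConfigDocument, path: str) -> None:
    Path(path).write_text(config.to_yaml())
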