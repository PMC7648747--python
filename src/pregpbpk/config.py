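"""Model configuration: drug parameters, reference physiology, gestational curves.

All configuration is validated with pydantic and shipped as YAML files under
``pregpbpk/data``. The internal unit system is µg / L / h; doses at the user
interface are in mg and converted on entry to the simulator.
"""
from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

CYP_ENZYMES = ("CYP3A4", "CYP2B6", "CYP2C9", "CYP2C19", "CYP2D6")
COMPARTMENTS = ("plasma", "gut", "liver", "richly_perfused", "slowly_perfused")
FLOW_COMPARTMENTS = ("gut", "liver_arterial", "richly_perfused", "slowly_perfused")


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


class CYPKinetics(BaseModel):
    """In vitro kinetics for one recombinant CYP enzyme."""

    vmax_pmol_min_pmol: float = Field(gt=0)
    isef: float = Field(gt=0)
    abundance_pmol_mg: float = Field(gt=0)
    gestational_scaling: bool = False


class AbsorptionParams(BaseModel):
    ka_max_per_h: float = Field(gt=0)
    tau_a_h: float = Field(gt=0)


class EnterohepaticParams(BaseModel):
    cl_bile_L_h: float = Field(ge=0)
    k_empty_per_h: float = Field(gt=0)


class CalibrationParams(BaseModel):
    """Constants fitted once against the nonpregnant calibration profile."""

    clint_scalar: float = Field(gt=0)
    kp_adjustment: dict[str, float]

    @field_validator("kp_adjustment")
    @classmethod
    def _positive_factors(cls, v: dict[str, float]) -> dict[str, float]:
        for key, val in v.items():
            if val <= 0:
                raise ValueError(f"kp_adjustment[{key}] must be > 0, got {val}")
        return v


class DrugParams(BaseModel):
    """Physicochemical and binding constants plus per-CYP in vitro kinetics."""

    name: str
    molecular_weight_g_mol: float = Field(gt=0)
    logp: float
    pka: float
    fu0: float = Field(gt=0, lt=1, description="fraction unbound in nonpregnant plasma")
    fu_mic: float = Field(gt=0, le=1, description="fraction unbound in microsomal incubation")
    blood_plasma_ratio: float = Field(gt=0)
    tablet_strengths_mg: list[float]
    substrate_conc_um: float = Field(gt=0)
    cyp_kinetics: dict[str, CYPKinetics]
    absorption: AbsorptionParams
    enterohepatic: EnterohepaticParams
    calibration: CalibrationParams

    @field_validator("tablet_strengths_mg")
    @classmethod
    def _strengths_sorted_positive(cls, v: list[float]) -> list[float]:
        if not v or any(s <= 0 for s in v):
            raise ValueError("tablet_strengths_mg must be non-empty and strictly positive")
        if sorted(v) != v:
            raise ValueError("tablet_strengths_mg must be sorted ascending")
        return v

    @field_validator("cyp_kinetics")
    @classmethod
    def _known_enzymes(cls, v: dict[str, CYPKinetics]) -> dict[str, CYPKinetics]:
        unknown = set(v) - set(CYP_ENZYMES)
        if unknown:
            raise ValueError(f"unknown CYP enzymes: {sorted(unknown)}")
        return v


class Physiology(BaseModel):
    """Nonpregnant reference anatomy: volumes and flows as fractions."""

    body_weight_kg: float = Field(gt=0)
    cardiac_output_L_h: float = Field(gt=0)
    liver_mass_g: float = Field(gt=0)
    mppgl_mg_g: float = Field(gt=0)
    fractional_volumes: dict[str, float]
    fractional_flows: dict[str, float]

    @model_validator(mode="after")
    def _check_fractions(self) -> "Physiology":
        missing = set(COMPARTMENTS) - set(self.fractional_volumes)
        if missing:
            raise ValueError(f"fractional_volumes missing compartments: {sorted(missing)}")
        missing = set(FLOW_COMPARTMENTS) - set(self.fractional_flows)
        if missing:
            raise ValueError(f"fractional_flows missing compartments: {sorted(missing)}")
        for key, val in {**self.fractional_volumes, **self.fractional_flows}.items():
            if val <= 0:
                raise ValueError(f"fraction {key} must be > 0, got {val}")
        vol_sum = sum(self.fractional_volumes.values())
        if vol_sum > 1.0 + 1e-9:
            raise ValueError(f"fractional volumes sum to {vol_sum:.4f} > 1")
        flow_sum = sum(self.fractional_flows.values())
        if abs(flow_sum - 1.0) > 1e-9:
            raise ValueError(f"fractional flows must sum to 1, got {flow_sum:.6f}")
        return self


class GestPoly(BaseModel):
    """Polynomial in gestational age (weeks): offset + sum(c_i * GA^i)."""

    form: Literal["polynomial"] = "polynomial"
    offset: float
    coeffs: list[float]

    def __call__(self, ga: float) -> float:
        value = self.offset
        power = 1.0
        for c in self.coeffs:
            power *= ga
            value += c * power
        return value


class GestEmax(BaseModel):
    """Saturating activity multiplier: 1 + emax * GA^h / (ga50^h + GA^h)."""

    form: Literal["emax"]
    emax: float = Field(gt=0)
    ga50: float = Field(gt=0)
    hill: float = Field(gt=0)

    def __call__(self, ga: float) -> float:
        if ga == 0:
            return 1.0
        x = (ga / self.ga50) ** self.hill
        return 1.0 + self.emax * x / (1.0 + x)


GestCurve = Union[GestPoly, GestEmax]


class GestationalCoefficients(BaseModel):
    """Gestational-age curves for physiology, binding and CYP activity.

    Every curve evaluates to its nonpregnant reference at GA = 0
    (multiplier 1 for ratios, 0 for gains).
    """

    body_weight_gain_kg: GestPoly
    plasma_volume_ratio: GestPoly
    cardiac_output_ratio: GestPoly
    placental_fetal_volume_L: GestPoly
    fat_gain_kg: GestPoly
    albumin_ratio: GestPoly
    cyp_activity: dict[str, GestCurve]

    @model_validator(mode="after")
    def _reference_at_ga0(self) -> "GestationalCoefficients":
        for name, expected in (
            ("body_weight_gain_kg", 0.0),
            ("placental_fetal_volume_L", 0.0),
            ("fat_gain_kg", 0.0),
            ("plasma_volume_ratio", 1.0),
            ("cardiac_output_ratio", 1.0),
            ("albumin_ratio", 1.0),
        ):
            curve = getattr(self, name)
            if curve(0.0) != expected:
                raise ValueError(f"{name} must evaluate to {expected} at GA=0")
        for enzyme, curve in self.cyp_activity.items():
            if curve(0.0) != 1.0:
                raise ValueError(f"cyp_activity[{enzyme}] must be 1 at GA=0")
        return self

    def cyp_multiplier(self, enzyme: str, ga: float) -> float:
        """Activity multiplier for an enzyme; 1 when no gestational data exist."""
        curve = self.cyp_activity.get(enzyme)
        return 1.0 if curve is None else curve(ga)


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("pregpbpk").joinpath("data", filename)))


def _load_yaml(path: Path) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return payload


def _validate(model: type[BaseModel], payload: dict, path: Path):
    try:
        return model.model_validate(payload)
    except ValidationError as err:
        keys = ", ".join(".".join(str(loc) for loc in e["loc"]) for e in err.errors())
        raise ConfigError(f"{path}: invalid {model.__name__} (offending keys: {keys})\n{err}") from err


def load_drug_params(path: str | Path | None = None) -> DrugParams:
    path = _data_path("drug_sertraline.yaml") if path is None else Path(path)
    return _validate(DrugParams, _load_yaml(path), path)


def load_physiology(path: str | Path | None = None) -> Physiology:
    path = _data_path("physiology_icrp_female.yaml") if path is None else Path(path)
    return _validate(Physiology, _load_yaml(path), path)


def load_gestational_coefficients(path: str | Path | None = None) -> GestationalCoefficients:
    path = _data_path("gestation_coefficients.yaml") if path is None else Path(path)
    return _validate(GestationalCoefficients, _load_yaml(path), path)


def load_config(
    drug: str | Path | None = None,
    physiology: str | Path | None = None,
    gestation: str | Path | None = None,
) -> tuple[DrugParams, Physiology, GestationalCoefficients]:
    """Load (drug, physiology, gestational coefficients), defaulting to the
    packaged sertraline / reference-female configuration."""
    return (
        load_drug_params(drug),
        load_physiology(physiology),
        load_gestational_coefficients(gestation),
    )


def save_config(model: BaseModel, path: str | Path) -> None:
    """Write a configuration object back to YAML (round-trips with the loaders)."""
    with open(path, "w") as fh:
        yaml.safe_dump(model.model_dump(mode="json"), fh, sort_keys=False)
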