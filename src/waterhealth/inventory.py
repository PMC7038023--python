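"""Life-cycle inventory: annual chemical releases of a water system.

A system design is an ordered list of stages (water treatment, water
distribution, wastewater collection, centralized treatment, septic,
residual transport, construction, ...).  Each stage carries intensity
parameters — energy or chemical demand per m³ of water or wastewater, per
household-year, or fixed annual amounts — described by distributions.
Scaling a sampled intensity by the functional unit (the community's annual
water and wastewater service demand) gives an annual carrier amount
(MJ of electricity, kg of coagulant, ...), and an emission-factor table
maps each carrier to the chemicals it releases to air, water and soil,
per unit carrier, across its supply chain.

The product of these three layers is the inventory: kg/year of each
chemical released to each compartment, tagged by stage so downstream
impact results can be decomposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .distributions import Distribution, uniform

__all__ = [
    "BASES",
    "COMPARTMENTS",
    "StageParameter",
    "Stage",
    "CreditDefinition",
    "SystemConfig",
    "FunctionalUnit",
    "EmissionFactorTable",
    "annual_carrier_amount",
    "build_inventory",
    "system_parameter_distributions",
    "GALLON_M3",
]

BASES = ("per_m3_water", "per_m3_wastewater", "per_household_year", "fixed_annual")
COMPARTMENTS = ("air", "water", "soil")

#: fixed US-gallon to m³ conversion used throughout
GALLON_M3 = 3.78541e-3

INVENTORY_COLUMNS = ["system", "stage", "chemical", "compartment", "mass_kg_per_year"]


class ConfigurationError(ValueError):
    """Inconsistent system / functional-unit configuration."""


class CarrierLookupError(KeyError):
    """A stage parameter's carrier is absent from the emission-factor table."""


@dataclass(frozen=True)
class StageParameter:
    """One uncertain intensity of a stage (e.g. MJ electricity per m³)."""

    name: str
    distribution: Distribution
    units: str
    carrier: str

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "distribution": self.distribution.to_dict(),
            "units": self.units,
            "carrier": self.carrier,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StageParameter":
        return cls(d["name"], Distribution.from_dict(d["distribution"]), d["units"], d["carrier"])


@dataclass(frozen=True)
class Stage:
    name: str
    throughput_basis: str
    parameters: tuple[StageParameter, ...]

    def __post_init__(self) -> None:
        if self.throughput_basis not in BASES:
            raise ConfigurationError(f"unknown throughput basis {self.throughput_basis!r}")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate parameter names in stage {self.name!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "throughput_basis": self.throughput_basis,
            "parameters": [p.to_dict() for p in self.parameters],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Stage":
        return cls(
            d["name"],
            d["throughput_basis"],
            tuple(StageParameter.from_dict(p) for p in d["parameters"]),
        )


@dataclass(frozen=True)
class CreditDefinition:
    """Avoided impacts from a recovered product displacing a synthetic one.

    ``annual_amount_kg`` is the recovered nutrient mass (e.g. fertilizer-N
    from urine) per year; the characterization-factor equivalents are the
    life-cycle cancer/noncancer cases per kg of the displaced synthetic
    product.
    """

    product: str
    annual_amount_kg: float
    cf_cancer_per_kg: float
    cf_noncancer_per_kg: float

    def __post_init__(self) -> None:
        if self.annual_amount_kg < 0:
            raise ConfigurationError("credit amount must be >= 0")

    def to_dict(self) -> dict:
        return {
            "product": self.product,
            "annual_amount_kg": self.annual_amount_kg,
            "cf_cancer_per_kg": self.cf_cancer_per_kg,
            "cf_noncancer_per_kg": self.cf_noncancer_per_kg,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CreditDefinition":
        return cls(
            d["product"], d["annual_amount_kg"], d["cf_cancer_per_kg"], d["cf_noncancer_per_kg"]
        )


@dataclass(frozen=True)
class SystemConfig:
    """A named system design: ordered stages plus avoided-impact credits."""

    name: str
    stages: tuple[Stage, ...]
    credits: tuple[CreditDefinition, ...] = ()

    def __post_init__(self) -> None:
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate stage names in system {self.name!r}")

    def stage(self, name: str) -> Stage:
        for s in self.stages:
            if s.name == name:
                return s
        raise ConfigurationError(f"system {self.name!r} has no stage {name!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "stages": [s.to_dict() for s in self.stages],
            "credits": [c.to_dict() for c in self.credits],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SystemConfig":
        return cls(
            d["name"],
            tuple(Stage.from_dict(s) for s in d["stages"]),
            tuple(CreditDefinition.from_dict(c) for c in d.get("credits", [])),
        )


@dataclass(frozen=True)
class FunctionalUnit:
    """The reference service: a community's annual water/wastewater demand.

    ``annual_water_m3`` is delivered water demand; volumes treated and
    distributed upstream of the loss point are inflated by
    ``1/(1 − loss)``, with the loss fraction an uncertain input.
    ``annual_wastewater_m3`` defaults to the delivered water volume.
    """

    annual_water_m3: float
    households: int
    distribution_loss_fraction: Distribution = field(
        default_factory=lambda: uniform(0.08, 0.15)
    )
    annual_wastewater_m3: float | None = None

    def __post_init__(self) -> None:
        if self.annual_water_m3 <= 0 or self.households <= 0:
            raise ConfigurationError("functional unit volumes/households must be positive")

    @property
    def wastewater_m3(self) -> float:
        return (
            self.annual_water_m3
            if self.annual_wastewater_m3 is None
            else self.annual_wastewater_m3
        )

    def to_dict(self) -> dict:
        return {
            "annual_water_m3": self.annual_water_m3,
            "households": self.households,
            "distribution_loss_fraction": self.distribution_loss_fraction.to_dict(),
            "annual_wastewater_m3": self.annual_wastewater_m3,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FunctionalUnit":
        return cls(
            d["annual_water_m3"],
            d["households"],
            Distribution.from_dict(d["distribution_loss_fraction"]),
            d.get("annual_wastewater_m3"),
        )


class EmissionFactorTable:
    """Chemical releases per unit carrier, by compartment.

    Wraps a DataFrame with columns ``carrier, chemical, compartment,
    factor`` (kg released per unit carrier).  Rows are unique on
    ``(carrier, chemical, compartment)`` and factors are non-negative.
    """

    columns = ["carrier", "chemical", "compartment", "factor"]

    def __init__(self, data: pd.DataFrame):
        df = data[self.columns].copy().reset_index(drop=True)
        if (df["factor"] < 0).any():
            raise ConfigurationError("emission factors must be >= 0")
        bad = ~df["compartment"].isin(COMPARTMENTS)
        if bad.any():
            raise ConfigurationError(
                f"unknown compartments: {sorted(df.loc[bad, 'compartment'].unique())}"
            )
        if df.duplicated(["carrier", "chemical", "compartment"]).any():
            raise ConfigurationError("duplicate (carrier, chemical, compartment) rows")
        self.data = df

    @property
    def carriers(self) -> set[str]:
        return set(self.data["carrier"].unique())

    def for_carrier(self, carrier: str) -> pd.DataFrame:
        sub = self.data[self.data["carrier"] == carrier]
        if sub.empty:
            raise CarrierLookupError(f"carrier {carrier!r} not in emission-factor table")
        return sub

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmissionFactorTable":
        return cls(pd.read_csv(path, comment="#"))


# ---------------------------------------------------------------------- #

def annual_carrier_amount(
    basis: str,
    fu: FunctionalUnit,
    sampled_value,
    loss_fraction=0.0,
):
    """Scale a sampled per-unit intensity to an annual carrier amount.

    ``per_m3_water`` multiplies by the annual water volume inflated by
    ``1/(1 − loss)`` (treatment and distribution sit upstream of the loss
    point); ``per_m3_wastewater`` multiplies by the wastewater volume;
    ``per_household_year`` by the household count; ``fixed_annual`` passes
    the sampled value through.  Vectorized over sampled values and loss.
    """
    x = np.asarray(sampled_value, dtype=float)
    if basis == "per_m3_water":
        loss = np.asarray(loss_fraction, dtype=float)
        if np.any((loss < 0) | (loss >= 1)):
            raise ConfigurationError("loss fraction must lie in [0, 1)")
        out = x * fu.annual_water_m3 / (1.0 - loss)
    elif basis == "per_m3_wastewater":
        out = x * fu.wastewater_m3
    elif basis == "per_household_year":
        out = x * fu.households
    elif basis == "fixed_annual":
        out = x
    else:
        raise ConfigurationError(f"unknown throughput basis {basis!r}")
    return float(out) if np.ndim(out) == 0 else out


LOSS_PARAM = "functional_unit.distribution_loss_fraction"


def system_parameter_distributions(
    sys: SystemConfig, fu: FunctionalUnit
) -> dict[str, Distribution]:
    """Named distributions of every uncertain inventory input of a system."""
    params: dict[str, Distribution] = {LOSS_PARAM: fu.distribution_loss_fraction}
    for stage in sys.stages:
        for p in stage.parameters:
            params[f"{stage.name}.{p.name}"] = p.distribution
    return params


def build_inventory(
    sys: SystemConfig,
    fu: FunctionalUnit,
    ef: EmissionFactorTable,
    sampled: Mapping[str, float],
) -> pd.DataFrame:
    """Annual chemical-release inventory of a system at sampled input values.

    ``sampled`` maps ``"<stage>.<parameter>"`` names (and the loss-fraction
    name) to values; see :func:`system_parameter_distributions`.  Returns a
    DataFrame with columns ``system, stage, chemical, compartment,
    mass_kg_per_year``, one row per (stage, chemical, compartment).
    """
    loss = sampled.get(LOSS_PARAM, 0.0)
    frames: list[pd.DataFrame] = []
    for stage in sys.stages:
        for p in stage.parameters:
            key = f"{stage.name}.{p.name}"
            if key not in sampled:
                raise ConfigurationError(f"no sampled value for parameter {key!r}")
            amount = annual_carrier_amount(stage.throughput_basis, fu, sampled[key], loss)
            factors = ef.for_carrier(p.carrier)
            frames.append(
                pd.DataFrame(
                    {
                        "system": sys.name,
                        "stage": stage.name,
                        "chemical": factors["chemical"].to_numpy(),
                        "compartment": factors["compartment"].to_numpy(),
                        "mass_kg_per_year": amount * factors["factor"].to_numpy(),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=INVENTORY_COLUMNS)
    inv = pd.concat(frames, ignore_index=True)
    # two parameters of one stage may emit the same chemical: aggregate
    return (
        inv.groupby(["system", "stage", "chemical", "compartment"], as_index=False, sort=False)[
            "mass_kg_per_year"
        ].sum()
    )
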