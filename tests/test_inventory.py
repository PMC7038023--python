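"""Inventory scaling and release accounting."""

import numpy as np
import pandas as pd
import pytest

from waterhealth.distributions import normal, point, uniform
from waterhealth.inventory import (
    CarrierLookupError,
    ConfigurationError,
    EmissionFactorTable,
    FunctionalUnit,
    Stage,
    StageParameter,
    SystemConfig,
    annual_carrier_amount,
    build_inventory,
    system_parameter_distributions,
)


@pytest.fixture
def fu():
    return FunctionalUnit(
        annual_water_m3=1.0e6, households=100, distribution_loss_fraction=point(0.0)
    )


@pytest.fixture
def ef():
    return EmissionFactorTable(
        pd.DataFrame(
            [
                ("electricity", "SO2", "air", 1.0e-4),
                ("electricity", "As", "water", 2.0e-7),
                ("diesel", "NOx", "air", 5.0e-4),
            ],
            columns=["carrier", "chemical", "compartment", "factor"],
        )
    )


def _one_param_system(value=1.27, basis="per_m3_water", carrier="electricity"):
    return SystemConfig(
        "sys",
        (
            Stage(
                "water_treatment",
                basis,
                (StageParameter("energy", point(value), "MJ/m3", carrier),),
            ),
        ),
    )


@pytest.mark.parametrize(
    "basis, value, expected",
    [
        ("per_m3_water", 1.27, 1.27e6),  # 1.27 MJ/m3 x 1e6 m3, no loss
        ("per_m3_wastewater", 2.0, 2.0e6),
        ("per_household_year", 440.0, 4.4e4),  # 440 MJ/(hh yr) x 100 households
        ("fixed_annual", 5.0e4, 5.0e4),
        ("per_m3_water", 0.0, 0.0),
    ],
)
def test_annual_carrier_amount(fu, basis, value, expected):
    assert annual_carrier_amount(basis, fu, value) == pytest.approx(expected)


def test_loss_inflates_upstream_water_volume(fu):
    # at 20% loss the treated volume is delivered / (1 - 0.2)
    assert annual_carrier_amount("per_m3_water", fu, 1.0, 0.2) == pytest.approx(1.25e6)
    with pytest.raises(ConfigurationError):
        annual_carrier_amount("per_m3_water", fu, 1.0, 1.0)
    with pytest.raises(ConfigurationError):
        annual_carrier_amount("per_m3_beer", fu, 1.0)


def test_build_inventory_single_row(fu):
    ef = EmissionFactorTable(
        pd.DataFrame(
            [("electricity", "SO2", "air", 1.0e-4)],
            columns=["carrier", "chemical", "compartment", "factor"],
        )
    )
    sys = _one_param_system(value=1.0, basis="fixed_annual")
    inv = build_inventory(sys, fu, ef, {"water_treatment.energy": 1.0e3})
    assert len(inv) == 1
    assert inv["mass_kg_per_year"].iloc[0] == pytest.approx(0.1)  # 1e3 MJ x 1e-4 kg/MJ


def test_build_inventory_empty_system(fu, ef):
    inv = build_inventory(SystemConfig("empty", ()), fu, ef, {})
    assert inv.empty


def test_two_stages_same_chemical_additive(fu, ef):
    sys = SystemConfig(
        "sys",
        (
            Stage("a", "fixed_annual", (StageParameter("e", point(1.0), "MJ", "electricity"),)),
            Stage("b", "fixed_annual", (StageParameter("e", point(1.0), "MJ", "electricity"),)),
        ),
    )
    inv = build_inventory(sys, fu, ef, {"a.e": 1000.0, "b.e": 500.0})
    so2 = inv[inv["chemical"] == "SO2"]
    assert set(so2["stage"]) == {"a", "b"}
    assert so2["mass_kg_per_year"].sum() == pytest.approx(0.15)


def test_linearity_in_sampled_values(fu, ef):
    sys = SystemConfig(
        "sys",
        (
            Stage(
                "s",
                "per_m3_water",
                (
                    StageParameter("e", normal(1.0, 0.1), "MJ/m3", "electricity"),
                    StageParameter("d", normal(2.0, 0.1), "MJ/m3", "diesel"),
                ),
            ),
        ),
    )
    v1 = {"s.e": 1.3, "s.d": 0.7}
    v2 = {k: 2 * v for k, v in v1.items()}
    inv1 = build_inventory(sys, fu, ef, v1).set_index(["chemical", "compartment"])
    inv2 = build_inventory(sys, fu, ef, v2).set_index(["chemical", "compartment"])
    assert np.allclose(
        inv2["mass_kg_per_year"], 2 * inv1.loc[inv2.index, "mass_kg_per_year"]
    )


def test_stage_partition_no_double_counting(scenarios):
    """Total inventory mass equals the sum over per-stage masses."""
    from waterhealth.inventory import LOSS_PARAM

    s = scenarios["BAU"]
    values = {
        name: d.median
        for name, d in system_parameter_distributions(s.system, s.functional_unit).items()
    }
    inv = build_inventory(s.system, s.functional_unit, s.emission_factors, values)
    per_stage = inv.groupby("stage")["mass_kg_per_year"].sum()
    assert per_stage.sum() == pytest.approx(inv["mass_kg_per_year"].sum(), rel=1e-12)
    assert not inv.duplicated(["stage", "chemical", "compartment"]).any()


def test_missing_carrier_is_loud(fu, ef):
    sys = _one_param_system(carrier="unobtainium")
    with pytest.raises(CarrierLookupError, match="unobtainium"):
        build_inventory(sys, fu, ef, {"water_treatment.energy": 1.0})


def test_missing_sampled_value_is_loud(fu, ef):
    with pytest.raises(ConfigurationError, match="water_treatment.energy"):
        build_inventory(_one_param_system(), fu, ef, {})


def test_emission_factor_table_validation():
    with pytest.raises(ConfigurationError):
        EmissionFactorTable(
            pd.DataFrame(
                [("e", "x", "air", -1.0)],
                columns=["carrier", "chemical", "compartment", "factor"],
            )
        )
    with pytest.raises(ConfigurationError):
        EmissionFactorTable(
            pd.DataFrame(
                [("e", "x", "lava", 1.0)],
                columns=["carrier", "chemical", "compartment", "factor"],
            )
        )


def test_emission_factor_csv_round_trip(tmp_path, ef):
    path = tmp_path / "ef.csv"
    ef.to_csv(path)
    back = EmissionFactorTable.from_csv(path)
    pd.testing.assert_frame_equal(back.data, ef.data)


def test_config_serialization_round_trip():
    sys = _one_param_system()
    assert SystemConfig.from_dict(sys.to_dict()) == sys
    fu = FunctionalUnit(1e6, 100, uniform(0.08, 0.15), 9e5)
    assert FunctionalUnit.from_dict(fu.to_dict()) == fu
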