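"""Exposure doses, dose-response models and risk characterization."""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waterhealth.distributions import point
from waterhealth.qmra import (
    CrossConnectionExposure,
    PathogenParams,
    PopulationContext,
    RecreationalExposure,
    SystemQmraConfig,
    WaterQuality,
    annual_daly,
    annual_illness_risk,
    cross_connection_dose,
    p_illness,
    p_infection,
    recreational_dose,
    system_microbial_risk,
)
from waterhealth.synthetic import default_pathogens

PATHOGENS = {p.name: p for p in default_pathogens()}


# -- doses --------------------------------------------------------------- #

def test_recreational_dose_hand_value():
    # 50 mL at dilution 0.1 of water carrying 10^(7-3) organisms/L
    assert recreational_dose(50.0, 0.1, 7.0, 3.0) == pytest.approx(50.0)


def test_recreational_dose_degenerate_cases():
    assert recreational_dose(40.0, 0.2, 5.0, 5.0) == pytest.approx(0.04 * 0.2)
    assert recreational_dose(40.0, 0.0, 5.0, 1.0) == 0.0
    with pytest.raises(ValueError):
        recreational_dose(-1.0, 0.1, 5.0, 1.0)


def test_cross_connection_dose_hand_value():
    # 1 L x 0.001 x 10^5 x 10^(-0.2*1*10) = 100 x 10^-2 = 1
    assert cross_connection_dose(1.0, 0.001, 5.0, 0.2, 1.0, 10.0) == pytest.approx(1.0)


def test_cross_connection_no_decay_cases():
    full = cross_connection_dose(1.0, 0.001, 5.0, 0.2, 1.0, 0.0)  # t = 0
    assert full == pytest.approx(100.0)
    assert cross_connection_dose(1.0, 0.001, 5.0, 0.0, 1.0, 60.0) == pytest.approx(full)


# -- dose-response ------------------------------------------------------- #

def test_exponential_id50_is_printed_value():
    crypto = PATHOGENS["cryptosporidium"]
    d50 = crypto.id50  # ln 2 / r
    assert p_infection(d50, crypto) == pytest.approx(0.5, abs=1e-12)
    assert round(d50) == 8


def test_beta_poisson_id50():
    campy = PATHOGENS["campylobacter_jejuni"]
    assert p_infection(896.0, campy) == pytest.approx(0.5, abs=1e-3)
    assert p_infection(campy.id50, campy) == pytest.approx(0.5, abs=1e-12)


def test_exact_beta_poisson_median_dose():
    noro = PATHOGENS["norovirus"]
    assert p_infection(26.0, noro) == pytest.approx(0.5, abs=5e-3)


@pytest.mark.parametrize("name", sorted(PATHOGENS))
def test_dose_response_properties(name):
    """All families: 0 at dose 0, monotone non-decreasing, bounded by 1."""
    p = PATHOGENS[name]
    doses = np.concatenate([[0.0], np.logspace(-3, 5, 60)])
    probs = np.array([p_infection(d, p) for d in doses])
    assert probs[0] == 0.0
    assert np.all(np.diff(probs) >= -1e-15)
    assert np.all((probs >= 0.0) & (probs <= 1.0))
    with pytest.raises(ValueError):
        p_infection(-1.0, p)


def test_hypergeometric_agrees_with_arbitrary_precision_oracle():
    """Series evaluation of 1 - 1F1(a, a+b, -d) to 1e-8 over 1e-2..1e4."""
    alpha, beta = 0.04, 0.055
    noro = PATHOGENS["norovirus"]
    mpmath.mp.dps = 40
    for d in np.logspace(-2, 4, 25):
        expected = float(1 - mpmath.hyp1f1(alpha, alpha + beta, -d))
        assert p_infection(float(d), noro) == pytest.approx(expected, abs=1e-8)


def test_hypergeometric_vectorized_matches_scalar():
    noro = PATHOGENS["norovirus"]
    doses = np.array([0.0, 0.5, 26.0, 300.0])
    vec = p_infection(doses, noro)
    assert np.allclose(vec, [p_infection(float(d), noro) for d in doses], rtol=1e-14)


# -- illness and annual risk --------------------------------------------- #

def test_p_illness_products():
    crypto = PATHOGENS["cryptosporidium"]
    assert p_illness(0.5, crypto) == pytest.approx(0.355)  # 0.5 x 0.71
    assert p_illness(0.0, crypto) == 0.0
    ka = PathogenParams("ka", "exponential", (1.0,), 1.0, 1.0)
    assert p_illness(0.37, ka) == pytest.approx(0.37)


def test_annual_risk_hand_values():
    assert annual_illness_risk([0.1, 0.2]) == pytest.approx(0.28)  # 1 - 0.9*0.8
    assert annual_illness_risk([0.37]) == pytest.approx(0.37)
    assert annual_illness_risk([0.0, 0.0, 0.0]) == 0.0
    with pytest.raises(ValueError):
        annual_illness_risk([1.2])


@given(
    st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20).map(sorted)
)
@settings(derandomize=True, max_examples=100)
def test_annual_risk_matches_brute_force_and_bounds(ps):
    """Complement-product oracle; max(p) <= annual <= min(1, sum(p)); order-free."""
    brute = 1.0
    for p in ps:
        brute *= 1.0 - p
    brute = 1.0 - brute
    got = annual_illness_risk(ps)
    assert got == pytest.approx(brute, abs=1e-12)
    assert got <= 1.0 + 1e-12
    assert got >= max(ps) - 1e-12
    assert got <= min(1.0, sum(ps)) + 1e-12
    assert annual_illness_risk(ps[::-1]) == pytest.approx(got, abs=1e-14)


def test_annual_daly_product():
    assert annual_daly(0.01, 1000, 4.6e-3) == pytest.approx(0.046)
    assert annual_daly(0.0, 1000, 4.6e-3) == 0.0
    assert annual_daly(0.01, 2000, 4.6e-3) == pytest.approx(2 * 0.046)


# -- system aggregation -------------------------------------------------- #

def _point_config(system="X", cross=False, c=3.0, r=3.0):
    pathogen = PathogenParams("ka", "exponential", (math.log(2.0),), 0.5, 4.0e-3,
                              k_inactivation=0.2)
    return SystemQmraConfig(
        system=system,
        pathogens=(pathogen,),
        water_quality={"ka": WaterQuality(point(c), point(r))},
        recreational=RecreationalExposure(point(1000.0), point(1.0)),
        cross_connection=CrossConnectionExposure(
            point(1.0), dilution_cc=0.001, chlorine_mg_l=1.0, contact_min=10.0
        )
        if cross
        else None,
    )


def _values(cfg):
    return {name: d.median for name, d in
            __import__("waterhealth.qmra", fromlist=["qmra_parameter_distributions"])
            .qmra_parameter_distributions(cfg).items()}


def test_deterministic_chain_matches_hand_oracle():
    """End-to-end: dose -> infection -> illness -> annual risk -> DALY."""
    cfg = _point_config(cross=True)
    ctx = PopulationContext(1000, 0.25, 0.10)
    out = system_microbial_risk(cfg, ctx, _values(cfg))
    # recreational: dose 1, p_inf 1/2, p_ill 1/4, 250 exposed, 4e-3 DALY/case
    assert out["ka.recreational"] == pytest.approx(0.25 * 250 * 4e-3, rel=1e-12)
    # cross-connection: dose 0.01, p_inf 1 - 2^-0.01, p_ill half that, 100 exposed
    expected_cc = (-math.expm1(-math.log(2) * 0.01)) * 0.5 * 100 * 4e-3
    assert out["ka.cross_connection"] == pytest.approx(expected_cc, rel=1e-12)
    assert out["total"] == pytest.approx(
        out["ka.recreational"] + out["ka.cross_connection"], rel=1e-15
    )


def test_decentralized_system_has_no_cross_connection_pathway():
    cfg = _point_config(system="CT-SS", cross=False)
    out = system_microbial_risk(cfg, PopulationContext(1000), _values(cfg))
    assert not any("cross_connection" in k for k in out)


def test_zero_pathogens_zero_risk():
    cfg = _point_config(c=-300.0, r=0.0)  # effectively organism-free water
    out = system_microbial_risk(cfg, PopulationContext(1000), _values(cfg))
    assert out["total"] == pytest.approx(0.0, abs=1e-250)


def test_parameter_validation():
    with pytest.raises(ValueError):
        PathogenParams("x", "beta_poisson", (0.1,), 0.5, 1e-3)
    with pytest.raises(ValueError):
        PathogenParams("x", "exponential", (-0.1,), 0.5, 1e-3)
    with pytest.raises(ValueError):
        CrossConnectionExposure(point(1.0), dilution_cc=2.0)
    with pytest.raises(ValueError):
        PopulationContext(100, fraction_swimmers=1.5)
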