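"""Life-cycle impact assessment: chemical releases to cases to DALY/year.

Characterization follows the comparative-toxicity convention in which a
factor expresses expected human-health cases per kg of chemical released
to a compartment.  The life-cycle cancer (noncancer) impact of a system is
the sum of products between released masses and the corresponding cancer
(noncancer) characterization factors; cases convert to disability-adjusted
life years at fixed severities (defaults: 11.5 DALY per cancer case,
2.7 DALY per noncancer case).

Avoided impacts — recovered nutrients displacing synthetic fertilizer —
enter as negative "credit" stage rows, so stage-contribution reports can
show them as offsets against the gross positive impact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .inventory import COMPARTMENTS, CreditDefinition, ConfigurationError

__all__ = [
    "CharacterizationTable",
    "DalyConversion",
    "LciaResult",
    "characterize",
    "apply_credits",
    "stage_contributions",
    "CREDIT_PREFIX",
]

CREDIT_PREFIX = "credit:"

_STAGE_COLUMNS = [
    "system",
    "stage",
    "cancer_cases",
    "noncancer_cases",
    "cancer_daly",
    "noncancer_daly",
]


class CharacterizationLookupError(KeyError):
    """An inventory chemical/compartment has no characterization factor."""


@dataclass(frozen=True)
class DalyConversion:
    """Severity of one case of illness, by impact category."""

    daly_per_cancer_case: float = 11.5
    daly_per_noncancer_case: float = 2.7

    def __post_init__(self) -> None:
        if self.daly_per_cancer_case <= 0 or self.daly_per_noncancer_case <= 0:
            raise ConfigurationError("DALY-per-case factors must be positive")


class CharacterizationTable:
    """Cancer and noncancer cases per kg released, by chemical and compartment."""

    columns = ["chemical", "compartment", "cf_cancer_cases_per_kg", "cf_noncancer_cases_per_kg"]

    def __init__(self, data: pd.DataFrame):
        df = data[self.columns].copy().reset_index(drop=True)
        if (df[["cf_cancer_cases_per_kg", "cf_noncancer_cases_per_kg"]] < 0).any().any():
            raise ConfigurationError("characterization factors must be >= 0")
        bad = ~df["compartment"].isin(COMPARTMENTS)
        if bad.any():
            raise ConfigurationError(
                f"unknown compartments: {sorted(df.loc[bad, 'compartment'].unique())}"
            )
        if df.duplicated(["chemical", "compartment"]).any():
            raise ConfigurationError("duplicate (chemical, compartment) rows")
        self.data = df

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CharacterizationTable":
        return cls(pd.read_csv(path, comment="#"))


@dataclass(frozen=True)
class LciaResult:
    """Per-stage life-cycle health impacts of one system.

    ``by_stage`` has columns ``system, stage, cancer_cases,
    noncancer_cases, cancer_daly, noncancer_daly``; credit rows are named
    ``credit:<product>`` and carry negative values.  Totals are sums over
    all rows (stages plus credits).
    """

    system: str
    by_stage: pd.DataFrame
    conversion: DalyConversion

    @property
    def cancer_daly(self) -> float:
        return float(self.by_stage["cancer_daly"].sum())

    @property
    def noncancer_daly(self) -> float:
        return float(self.by_stage["noncancer_daly"].sum())

    @property
    def total_daly(self) -> float:
        return self.cancer_daly + self.noncancer_daly

    def to_frame(self) -> pd.DataFrame:
        return self.by_stage.copy()


def characterize(
    inventory: pd.DataFrame,
    ct: CharacterizationTable,
    dc: DalyConversion = DalyConversion(),
) -> LciaResult:
    """Characterize an inventory into cases and DALY/year, per stage.

    Every (chemical, compartment) present in the inventory must have a
    characterization row; a missing pair raises (never a silent zero).
    """
    if inventory.empty:
        system = str(inventory["system"].iloc[0]) if len(inventory) else ""
        return LciaResult(system, pd.DataFrame(columns=_STAGE_COLUMNS), dc)
    systems = inventory["system"].unique()
    if len(systems) != 1:
        raise ConfigurationError("characterize expects a single-system inventory")
    merged = inventory.merge(ct.data, on=["chemical", "compartment"], how="left", sort=False)
    missing = merged["cf_cancer_cases_per_kg"].isna()
    if missing.any():
        pairs = sorted(
            set(zip(merged.loc[missing, "chemical"], merged.loc[missing, "compartment"]))
        )
        raise CharacterizationLookupError(
            f"no characterization factors for: {pairs}"
        )
    merged["cancer_cases"] = merged["mass_kg_per_year"] * merged["cf_cancer_cases_per_kg"]
    merged["noncancer_cases"] = merged["mass_kg_per_year"] * merged["cf_noncancer_cases_per_kg"]
    by_stage = merged.groupby(["system", "stage"], as_index=False, sort=False)[
        ["cancer_cases", "noncancer_cases"]
    ].sum()
    by_stage["cancer_daly"] = by_stage["cancer_cases"] * dc.daly_per_cancer_case
    by_stage["noncancer_daly"] = by_stage["noncancer_cases"] * dc.daly_per_noncancer_case
    return LciaResult(str(systems[0]), by_stage[_STAGE_COLUMNS], dc)


def apply_credits(
    res: LciaResult,
    credits: Sequence[CreditDefinition],
    dc: DalyConversion | None = None,
) -> LciaResult:
    """Append one negative stage row per avoided-impact credit."""
    if not credits:
        return res
    dc = dc or res.conversion
    rows = []
    for cr in credits:
        if cr.annual_amount_kg < 0:
            raise ConfigurationError("credit amount must be >= 0")
        cancer = -cr.annual_amount_kg * cr.cf_cancer_per_kg
        noncancer = -cr.annual_amount_kg * cr.cf_noncancer_per_kg
        rows.append(
            {
                "system": res.system,
                "stage": f"{CREDIT_PREFIX}{cr.product}",
                "cancer_cases": cancer,
                "noncancer_cases": noncancer,
                "cancer_daly": cancer * dc.daly_per_cancer_case,
                "noncancer_daly": noncancer * dc.daly_per_noncancer_case,
            }
        )
    by_stage = pd.concat([res.by_stage, pd.DataFrame(rows)], ignore_index=True)
    return LciaResult(res.system, by_stage[_STAGE_COLUMNS], dc)


def stage_contributions(res: LciaResult, impact: str = "noncancer_daly") -> pd.Series:
    """Fractional stage contributions to one impact column.

    Positive stages are expressed as fractions of the gross positive
    impact (summing to 1); credit rows appear as negative fractions of the
    same denominator, matching the convention of reporting offsets
    ("nutrient recovery mitigated 30% of the impact") separately.
    """
    if impact not in ("cancer_daly", "noncancer_daly", "cancer_cases", "noncancer_cases"):
        raise ConfigurationError(f"unknown impact column {impact!r}")
    vals = res.by_stage.set_index("stage")[impact]
    gross = vals[vals > 0].sum()
    if gross == 0:
        raise ConfigurationError("stage contributions undefined for zero gross impact")
    return vals / gross
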