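"""Integration of chemical and microbial health burdens, and comparison reports.

Life-cycle (cancer + noncancer) and microbial impacts are expressed in a
common DALY/year unit, so a system's total burden is their exact sum.
Comparison reports rank systems by median total burden and always
recompute percentages from stored absolute values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lcia import LciaResult

__all__ = ["HealthResult", "IntegrationError", "integrate", "compare_systems", "write_report"]


class IntegrationError(ValueError):
    """Results cannot be combined (system or functional-unit mismatch)."""


@dataclass(frozen=True)
class HealthResult:
    """Total human-health burden of one system, in DALY/year.

    ``total_daly`` is exactly ``cancer + noncancer + microbial``.
    ``per_stage`` carries the life-cycle stage decomposition (credits as
    negative rows); ``per_pathway`` the microbial pathogen × pathway
    decomposition.  ``percentiles`` (outputs × percentile columns) is
    present when the result summarizes a Monte Carlo run; deterministic
    results leave it None.  ``functional_unit_id`` ties the result to the
    service demand it was computed for, so unlike results cannot be
    compared silently.
    """

    system: str
    cancer_daly: float
    noncancer_daly: float
    microbial_daly: float
    per_stage: pd.DataFrame | None = None
    per_pathway: pd.DataFrame | None = None
    percentiles: pd.DataFrame | None = None
    functional_unit_id: tuple = ()

    @property
    def total_daly(self) -> float:
        return self.cancer_daly + self.noncancer_daly + self.microbial_daly

    @property
    def shares(self) -> dict[str, float]:
        """Fractional shares of the total, recomputed from absolute values."""
        t = self.total_daly
        if t == 0:
            raise IntegrationError("shares undefined for zero total")
        return {
            "cancer": self.cancer_daly / t,
            "noncancer": self.noncancer_daly / t,
            "microbial": self.microbial_daly / t,
            "lca": (self.cancer_daly + self.noncancer_daly) / t,
        }

    def to_dict(self) -> dict:
        d = {
            "system": self.system,
            "cancer_daly_per_year": self.cancer_daly,
            "noncancer_daly_per_year": self.noncancer_daly,
            "microbial_daly_per_year": self.microbial_daly,
            "total_daly_per_year": self.total_daly,
        }
        if self.percentiles is not None:
            d["percentiles"] = {
                out: {str(q): float(v) for q, v in row.items()}
                for out, row in self.percentiles.iterrows()
            }
        return d


def integrate(
    lcia: LciaResult,
    microbial_daly: float,
    per_pathway: pd.DataFrame | None = None,
    system: str | None = None,
    functional_unit_id: tuple = (),
    percentiles: pd.DataFrame | None = None,
) -> HealthResult:
    """Combine life-cycle and microbial burdens of one system (exact sum)."""
    if system is not None and lcia.system and system != lcia.system:
        raise IntegrationError(
            f"system mismatch: LCIA result is {lcia.system!r}, microbial is {system!r}"
        )
    if microbial_daly < 0:
        raise IntegrationError("microbial burden must be >= 0")
    return HealthResult(
        system=system or lcia.system,
        cancer_daly=lcia.cancer_daly,
        noncancer_daly=lcia.noncancer_daly,
        microbial_daly=float(microbial_daly),
        per_stage=lcia.to_frame(),
        per_pathway=per_pathway,
        percentiles=percentiles,
        functional_unit_id=functional_unit_id,
    )


def compare_systems(results: Sequence[HealthResult]) -> pd.DataFrame:
    """Rank systems by total burden (median where Monte Carlo summaries exist).

    Returns one row per system with cancer/noncancer/microbial/total
    DALY/yr (medians when available, else deterministic values), 5th/95th
    ranges of the total when available, and a 1-based ``rank`` (ties broken
    by system name, stable).  Results computed under different functional
    units cannot be compared.
    """
    if not results:
        raise IntegrationError("nothing to compare")
    fu_ids = {r.functional_unit_id for r in results}
    if len(fu_ids) > 1:
        raise IntegrationError(f"inconsistent functional units: {sorted(fu_ids)}")

    def _metric(r: HealthResult, output: str, fallback: float, q: float = 50.0) -> float:
        if r.percentiles is not None and output in r.percentiles.index:
            return float(r.percentiles.loc[output, q])
        return fallback

    rows = []
    for r in sorted(results, key=lambda r: r.system):
        rows.append(
            {
                "system": r.system,
                "cancer_daly": _metric(r, "cancer_daly", r.cancer_daly),
                "noncancer_daly": _metric(r, "noncancer_daly", r.noncancer_daly),
                "microbial_daly": _metric(r, "microbial_daly", r.microbial_daly),
                "total_daly": _metric(r, "total_daly", r.total_daly),
                "total_daly_p5": _metric(r, "total_daly", np.nan, 5.0),
                "total_daly_p95": _metric(r, "total_daly", np.nan, 95.0),
            }
        )
    df = pd.DataFrame(rows)
    df["rank"] = df["total_daly"].rank(method="first").astype(int)
    return df.sort_values(["rank", "system"], kind="stable").reset_index(drop=True)


def write_report(
    results: Sequence[HealthResult],
    outdir: str | Path,
    metadata: Mapping | None = None,
) -> None:
    """Write comparison CSV, per-system JSON summary and stage tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(results) > 1:
        compare_systems(results).to_csv(outdir / "comparison.csv", index=False)
    summary = {"systems": [r.to_dict() for r in results]}
    if metadata:
        summary["metadata"] = dict(metadata)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    for r in results:
        if r.per_stage is not None:
            r.per_stage.to_csv(outdir / f"{r.system}_stages.csv", index=False)
        if r.per_pathway is not None:
            r.per_pathway.to_csv(outdir / f"{r.system}_pathways.csv", index=False)


def plot_tornado(entries, ax=None, title: str | None = None):
    """Horizontal-bar tornado plot of a sensitivity analysis (optional)."""
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * max(len(entries), 4) + 1))
    ordered = list(entries)[::-1]  # widest on top
    for i, e in enumerate(ordered):
        lo, hi = sorted((e.low_output, e.high_output))
        ax.barh(i, hi - lo, left=lo, color="#4878a8")
    base = entries[0].base_output if entries else 0.0
    ax.axvline(base, color="k", lw=1)
    ax.set_yticks(range(len(ordered)), [e.parameter for e in ordered])
    ax.set_xlabel("total health burden, DALY/year")
    if title:
        ax.set_title(title)
    return ax
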