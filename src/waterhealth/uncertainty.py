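"""Monte Carlo variability propagation and one-at-a-time sensitivity.

A *model* here is any object exposing

* ``parameters`` — a mapping from parameter name to
  :class:`~waterhealth.distributions.Distribution`;
* ``evaluate(values)`` — a mapping from parameter values (scalars, or
  equal-length arrays for vectorized evaluation) to a mapping of named
  numeric outputs.

Monte Carlo samples every parameter independently through per-parameter
seeded substreams (so results are reproducible and insensitive to
parameter-set edits) and reports percentile summaries of each output.
The sensitivity analysis perturbs one parameter at a time to its 5th and
95th percentile, holding the others at their reference values (medians by
default), and ranks parameters by output swing — a tornado diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .distributions import Distribution, spawn_rngs

__all__ = ["MonteCarloSpec", "MonteCarloResult", "TornadoEntry", "run_monte_carlo", "tornado"]


class Model(Protocol):  # pragma: no cover - typing aid
    parameters: Mapping[str, Distribution]

    def evaluate(self, values: Mapping[str, float | np.ndarray]) -> Mapping[str, float | np.ndarray]:
        ...


@dataclass(frozen=True)
class MonteCarloSpec:
    iterations: int = 10_000
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class MonteCarloResult:
    """Raw draws (iterations × outputs) and percentile summary (outputs × percentiles)."""

    draws: pd.DataFrame
    summary: pd.DataFrame
    n_excluded: int = 0

    def percentile(self, output: str, q: float) -> float:
        return float(self.summary.loc[output, q])


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_output: float
    high_output: float
    base_output: float

    @property
    def width(self) -> float:
        return abs(self.high_output - self.low_output)


def run_monte_carlo(model: Model, spec: MonteCarloSpec) -> MonteCarloResult:
    """Propagate input variability through a model.

    Draws are generated by inverse transform per parameter from substreams
    of ``spec.seed``; the model is evaluated once, vectorized over all
    iterations.  Iterations yielding a non-finite value in any output are
    excluded from the summary, with the count reported.
    """
    n = spec.iterations
    rngs = spawn_rngs(spec.seed, model.parameters)
    values = {name: d.sample(n, rngs[name]) for name, d in model.parameters.items()}
    outputs = model.evaluate(values)
    draws = pd.DataFrame({k: np.broadcast_to(np.asarray(v, float), (n,)) for k, v in outputs.items()})
    finite = np.isfinite(draws.to_numpy()).all(axis=1)
    clean = draws[finite]
    if clean.empty:
        raise RuntimeError("all Monte Carlo iterations produced non-finite output")
    summary = pd.DataFrame(
        {q: clean.quantile(q / 100.0) for q in spec.percentiles}
    )
    return MonteCarloResult(draws=draws, summary=summary, n_excluded=int(n - finite.sum()))


def tornado(
    model: Model,
    parameters: Sequence[str] | None = None,
    reference: Mapping[str, float] | None = None,
    output: str = "total_daly",
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> list[TornadoEntry]:
    """One-at-a-time sensitivity of one model output.

    Each parameter is set in turn to its low/high quantile (default
    5th/95th) with every other parameter held at its reference value
    (distribution medians unless given); entries are sorted by swing
    ``|high − low|`` descending.  Point-valued parameters produce
    zero-width bars.
    """
    if parameters is None:
        parameters = list(model.parameters)
    unknown = [p for p in parameters if p not in model.parameters]
    if unknown:
        raise KeyError(f"parameters not in model: {unknown}")
    ref = {name: d.median for name, d in model.parameters.items()}
    if reference:
        ref.update(reference)

    def _eval(values: Mapping[str, float]) -> float:
        out = model.evaluate(values)
        if output not in out:
            raise KeyError(f"model has no output {output!r}")
        return float(np.asarray(out[output]))

    base = _eval(ref)
    entries = []
    for name in parameters:
        d = model.parameters[name]
        lo = dict(ref)
        hi = dict(ref)
        if d.kind == "point":
            lo_out = hi_out = base
        else:
            lo[name] = d.quantile(quantiles[0])
            hi[name] = d.quantile(quantiles[1])
            lo_out, hi_out = _eval(lo), _eval(hi)
        entries.append(TornadoEntry(name, lo_out, hi_out, base))
    entries.sort(key=lambda e: (-e.width, e.parameter))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    """Tabular view of a tornado analysis (parameter, low, base, high, width)."""
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low_output for e in entries],
            "base": [e.base_output for e in entries],
            "high": [e.high_output for e in entries],
            "width": [e.width for e in entries],
        }
    )
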