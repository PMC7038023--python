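"""Parametric univariate distributions for uncertain model inputs.

Every uncertain quantity in the framework (treatment-plant energy and
chemical intensities, pathogen concentrations, ingestion volumes, dilution
factors, ...) is described by one of five families:

``triangular(min, peak, max)``
    Used where only a plausible range and most-likely value are known.
``normal(mean, sd)``
    Used where enough utility data exist to fit a symmetric distribution.
``uniform(low, high)``
    Used for bounded factors with no preferred value, e.g. a septic-leakage
    dilution factor between 1/100 and 1/10.
``loguniform(low, high)``
    Uniform in log10 of the value; used for quantities spanning orders of
    magnitude such as soil log-removal of viruses.
``point(value)``
    A degenerate (deterministic) input.

Quantiles and CDFs are exact closed forms of the stated, untruncated
distribution; sampling is inverse-transform from a seeded generator, so a
seed fully determines every draw.  Normal inputs are *not* truncated at
zero by default (the analytic 5th percentiles are what reference tables
report); set ``nonnegative=True`` to resample negative draws when physical
plausibility matters more than the analytic quantiles.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "Distribution",
    "triangular",
    "normal",
    "uniform",
    "loguniform",
    "point",
    "scaled",
    "spawn_rngs",
    "anderson_darling_statistic",
]

_KINDS = ("triangular", "normal", "uniform", "loguniform", "point")
_NPARAMS = {"triangular": 3, "normal": 2, "uniform": 2, "loguniform": 2, "point": 1}


class ParameterError(ValueError):
    """Invalid distribution parameters or probability argument."""


@dataclass(frozen=True)
class Distribution:
    """A parametric univariate distribution with exact quantile/CDF contracts.

    Parameters
    ----------
    kind
        One of ``triangular``, ``normal``, ``uniform``, ``loguniform``,
        ``point``.
    params
        Family-specific parameters, in the conventional order:
        triangular ``(min, peak, max)``; normal ``(mean, sd)``;
        uniform / loguniform ``(low, high)``; point ``(value,)``.
    nonnegative
        If True, :meth:`sample` resamples negative draws (rejection).
        Quantile and CDF remain those of the untruncated distribution.
    """

    kind: str
    params: tuple[float, ...]
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown distribution kind {self.kind!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if len(p) != _NPARAMS[self.kind]:
            raise ParameterError(
                f"{self.kind} takes {_NPARAMS[self.kind]} parameters, got {len(p)}"
            )
        if not all(math.isfinite(v) for v in p):
            raise ParameterError(f"non-finite parameters {p}")
        if self.kind == "triangular":
            a, c, b = p
            if not (a <= c <= b) or not a < b:
                raise ParameterError(f"triangular requires min <= peak <= max, min < max; got {p}")
        elif self.kind == "normal":
            if p[1] < 0:
                raise ParameterError("normal sd must be >= 0")
        elif self.kind in ("uniform", "loguniform"):
            low, high = p
            if not low < high:
                raise ParameterError(f"{self.kind} requires low < high; got {p}")
            if self.kind == "loguniform" and low <= 0:
                raise ParameterError("loguniform requires low > 0")

    # ------------------------------------------------------------------ #

    def quantile(self, p):
        """Exact inverse CDF at probability ``p`` (scalar or array, in (0,1))."""
        p_arr = np.asarray(p, dtype=float)
        if np.any(p_arr <= 0.0) or np.any(p_arr >= 1.0):
            raise ParameterError("quantile requires 0 < p < 1")
        out = self._quantile(p_arr)
        return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out

    def _quantile(self, p: np.ndarray) -> np.ndarray:
        k = self.kind
        if k == "point":
            return np.full_like(p, self.params[0])
        if k == "uniform":
            low, high = self.params
            return low + p * (high - low)
        if k == "loguniform":
            low, high = self.params
            return 10.0 ** (np.log10(low) + p * (np.log10(high) - np.log10(low)))
        if k == "normal":
            mu, sd = self.params
            return mu + sd * ndtri(p)
        # triangular: piecewise inverse around the mode break F(c) = (c-a)/(b-a)
        a, c, b = self.params
        fc = (c - a) / (b - a)
        lower = a + np.sqrt(p * (b - a) * (c - a))
        upper = b - np.sqrt((1.0 - p) * (b - a) * (b - c))
        return np.where(p <= fc, lower, upper)

    def cdf(self, x):
        """F(x) in [0, 1]; satisfies cdf(quantile(p)) == p on the support."""
        x_arr = np.asarray(x, dtype=float)
        out = self._cdf(x_arr)
        return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out

    def _cdf(self, x: np.ndarray) -> np.ndarray:
        k = self.kind
        if k == "point":
            return (x >= self.params[0]).astype(float)
        if k == "uniform":
            low, high = self.params
            return np.clip((x - low) / (high - low), 0.0, 1.0)
        if k == "loguniform":
            low, high = self.params
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (np.log10(np.maximum(x, np.finfo(float).tiny)) - np.log10(low)) / (
                    np.log10(high) - np.log10(low)
                )
            return np.where(x <= low, 0.0, np.clip(f, 0.0, 1.0))
        if k == "normal":
            mu, sd = self.params
            if sd == 0.0:
                return (x >= mu).astype(float)
            return ndtr((x - mu) / sd)
        a, c, b = self.params
        f = np.where(
            x <= c,
            (x - a) ** 2 / ((b - a) * (c - a)) if c > a else (x > a).astype(float),
            1.0 - (b - x) ** 2 / ((b - a) * (b - c)) if c < b else (x >= b).astype(float),
        )
        return np.clip(np.where(x <= a, 0.0, np.where(x >= b, 1.0, f)), 0.0, 1.0)

    @property
    def median(self) -> float:
        return self.quantile(0.5) if self.kind != "point" else self.params[0]

    @property
    def mean(self) -> float:
        k, p = self.kind, self.params
        if k == "point":
            return p[0]
        if k == "uniform":
            return 0.5 * (p[0] + p[1])
        if k == "loguniform":
            low, high = p
            return (high - low) / (math.log(high) - math.log(low))
        if k == "normal":
            return p[0]
        a, c, b = p
        return (a + b + c) / 3.0

    def sample(self, n: int, rng: np.random.Generator | int) -> np.ndarray:
        """Draw ``n`` values by inverse transform from a seeded stream.

        ``rng`` may be a :class:`numpy.random.Generator` or an integer seed.
        The same seed always yields identical output.
        """
        if n < 1:
            raise ParameterError("sample size must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(int(rng))
        if self.kind == "point":
            return np.full(n, self.params[0])
        u = rng.random(n)
        x = self._quantile(u)
        if self.nonnegative:
            # rejection: redraw negatives until none remain
            bad = x < 0.0
            while np.any(bad):
                x[bad] = self._quantile(rng.random(int(bad.sum())))
                bad = x < 0.0
        return x

    # -- serialization -------------------------------------------------- #

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "params": list(self.params)}
        if self.nonnegative:
            d["nonnegative"] = True
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Distribution":
        return cls(d["kind"], tuple(d["params"]), bool(d.get("nonnegative", False)))


# ---------------------------------------------------------------------- #
# convenience constructors

def triangular(a: float, c: float, b: float, **kw) -> Distribution:
    """Triangular distribution with minimum ``a``, peak ``c``, maximum ``b``."""
    return Distribution("triangular", (a, c, b), **kw)


def normal(mean: float, sd: float, **kw) -> Distribution:
    return Distribution("normal", (mean, sd), **kw)


def uniform(low: float, high: float, **kw) -> Distribution:
    return Distribution("uniform", (low, high), **kw)


def loguniform(low: float, high: float, **kw) -> Distribution:
    """Uniform in log10 of the value over [low, high], low > 0."""
    return Distribution("loguniform", (low, high), **kw)


def point(value: float) -> Distribution:
    return Distribution("point", (value,))


def scaled(d: Distribution, factor: float) -> Distribution:
    """Rescale a distribution's value axis by a positive factor."""
    if factor <= 0:
        raise ParameterError("scale factor must be > 0")
    return Distribution(
        d.kind, tuple(v * factor for v in d.params), nonnegative=d.nonnegative
    )


# ---------------------------------------------------------------------- #

def _name_entropy(name: str) -> list[int]:
    digest = hashlib.blake2s(name.encode("utf-8"), digest_size=16).digest()
    return [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]


def spawn_rngs(seed: int, names: Iterable[str]) -> dict[str, np.random.Generator]:
    """Independent per-parameter generator substreams from one top-level seed.

    Each stream is keyed by a stable hash of the parameter name mixed with
    the seed, so adding or removing a parameter never perturbs the draws of
    the others.
    """
    return {
        name: np.random.default_rng(np.random.SeedSequence([int(seed)] + _name_entropy(name)))
        for name in names
    }


def anderson_darling_statistic(samples: np.ndarray, d: Distribution) -> float:
    """Anderson–Darling A² of a sample against a distribution's analytic CDF.

    A goodness-of-fit diagnostic (small values indicate agreement; for a
    correct fully-specified continuous model A² is ~1 and rarely exceeds
    2.5 at the 5% level). Degenerate (point) distributions are not testable.
    """
    if d.kind == "point":
        raise ParameterError("A-D statistic undefined for a point distribution")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ParameterError("need at least 2 samples")
    u = np.clip(d.cdf(x), 1e-15, 1.0 - 1e-15)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))
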