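"""Stochastic input models for the Monte-Carlo engine.

Concentrations are modelled as lognormals matched to a stratum's arithmetic
mean and SD by moment matching and truncated to the observed range;
questionnaire exposure factors as uniforms over their reported ranges.
Degenerate inputs fall back to a constant or to empirical resampling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import integrate, stats

Family = Literal["lognormal_truncated", "uniform", "constant", "empirical"]

_REJECTION_MAX_ROUNDS = 1000


class InfeasibleTruncationError(ValueError):
    """Essentially no probability mass lies inside the truncation bounds."""


@dataclass(frozen=True)
class DistributionSpec:
    """One sampled input of the risk model.

    Use the constructors :meth:`lognormal_truncated`, :meth:`uniform`,
    :meth:`constant` and :meth:`empirical` rather than filling fields by
    hand.  For the truncated lognormal, ``mean`` and ``sd`` are the
    *natural-scale* (arithmetic) moments of the untruncated lognormal;
    ``mu_log``/``sigma_log`` are the matched log-scale parameters.
    """

    family: Family
    mean: float | None = None
    sd: float | None = None
    low: float | None = None
    high: float | None = None
    value: float | None = None
    values: tuple[float, ...] | None = None
    mu_log: float = field(default=float("nan"), compare=False)
    sigma_log: float = field(default=float("nan"), compare=False)

    # -- constructors -------------------------------------------------------

    @classmethod
    def lognormal_truncated(cls, mean: float, sd: float, low: float, high: float) -> "DistributionSpec":
        """Lognormal moment-matched to (mean, sd), truncated to [low, high].

        mu_log = ln(m^2 / sqrt(m^2 + s^2)), sigma_log^2 = ln(1 + s^2/m^2).
        """
        if not (mean > 0 and sd > 0):
            raise ValueError("lognormal mean and sd must both be > 0")
        if not 0.0 <= low < high:
            raise ValueError(f"truncation bounds must satisfy 0 <= low < high, got [{low}, {high}]")
        m2, s2 = mean * mean, sd * sd
        mu_log = math.log(m2 / math.sqrt(m2 + s2))
        sigma_log = math.sqrt(math.log(1.0 + s2 / m2))
        return cls(
            family="lognormal_truncated",
            mean=mean, sd=sd, low=low, high=high,
            mu_log=mu_log, sigma_log=sigma_log,
        )

    @classmethod
    def uniform(cls, low: float, high: float) -> "DistributionSpec":
        if not low < high:
            raise ValueError(f"uniform requires low < high, got [{low}, {high}]")
        return cls(family="uniform", low=low, high=high)

    @classmethod
    def constant(cls, value: float) -> "DistributionSpec":
        return cls(family="constant", value=value)

    @classmethod
    def empirical(cls, values: Sequence[float]) -> "DistributionSpec":
        values = tuple(float(v) for v in values)
        if not values:
            raise ValueError("empirical spec needs at least one value")
        return cls(family="empirical", values=values)

    # -- underlying frozen distribution ------------------------------------

    def _lognorm(self) -> stats.rv_continuous:
        return stats.lognorm(s=self.sigma_log, scale=math.exp(self.mu_log))

    def _inside_mass(self) -> float:
        d = self._lognorm()
        return float(d.cdf(self.high) - d.cdf(self.low))

    # -- sampling -----------------------------------------------------------

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        method: Literal["rejection", "inverse"] = "rejection",
    ) -> np.ndarray:
        """Draw ``n`` values, reproducible for a given generator state.

        Truncation is enforced by rejection (resampling out-of-bounds draws,
        up to a bounded number of rounds, then clipping) or by inverse-CDF
        transform of uniforms — the latter supports common-random-number
        comparisons across specs.
        """
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        if self.family == "constant":
            return np.full(n, float(self.value))
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        if self.family == "empirical":
            return rng.choice(np.asarray(self.values, dtype=float), size=n, replace=True)
        # truncated lognormal
        mass = self._inside_mass()
        if mass < 1e-12:
            raise InfeasibleTruncationError(
                f"truncation [{self.low}, {self.high}] leaves no mass for "
                f"lognormal(mu={self.mu_log:.4g}, sigma={self.sigma_log:.4g})"
            )
        if method == "inverse":
            return self.ppf(rng.uniform(0.0, 1.0, size=n))
        d = self._lognorm()
        out = np.asarray(d.rvs(size=n, random_state=rng), dtype=float).reshape(n)
        bad = (out < self.low) | (out > self.high)
        rounds = 0
        while bad.any() and rounds < _REJECTION_MAX_ROUNDS:
            out[bad] = d.rvs(size=int(bad.sum()), random_state=rng)
            bad = (out < self.low) | (out > self.high)
            rounds += 1
        if bad.any():
            out = np.clip(out, self.low, self.high)
        return out

    def ppf(self, q: np.ndarray) -> np.ndarray:
        """Quantile function (truncated where applicable)."""
        q = np.asarray(q, dtype=float)
        if self.family == "constant":
            return np.full_like(q, float(self.value))
        if self.family == "uniform":
            return self.low + q * (self.high - self.low)
        if self.family == "empirical":
            return np.quantile(np.asarray(self.values, dtype=float), q)
        d = self._lognorm()
        lo_cdf, hi_cdf = d.cdf(self.low), d.cdf(self.high)
        if hi_cdf - lo_cdf < 1e-12:
            raise InfeasibleTruncationError("no mass inside truncation bounds")
        return d.ppf(lo_cdf + q * (hi_cdf - lo_cdf))

    # -- analytic moments ---------------------------------------------------

    def moments(self) -> tuple[float, float]:
        """(mean, sd) of the spec's actual distribution.

        For the truncated lognormal these are the truncated moments computed
        by numerical integration — not the matching targets, which refer to
        the untruncated law.
        """
        if self.family == "constant":
            return float(self.value), 0.0
        if self.family == "uniform":
            return (self.low + self.high) / 2.0, (self.high - self.low) / math.sqrt(12.0)
        if self.family == "empirical":
            v = np.asarray(self.values, dtype=float)
            return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0
        d = self._lognorm()
        mass = self._inside_mass()
        if mass < 1e-12:
            raise InfeasibleTruncationError("no mass inside truncation bounds")
        m1 = integrate.quad(lambda x: x * d.pdf(x), self.low, self.high, limit=200)[0] / mass
        m2 = integrate.quad(lambda x: x * x * d.pdf(x), self.low, self.high, limit=200)[0] / mass
        return m1, math.sqrt(max(m2 - m1 * m1, 0.0))


def fit_concentration_distribution(samples: Sequence[float]) -> DistributionSpec:
    """Fit a concentration model to observed shift samples.

    With >= 3 positive samples and nonzero spread, returns the
    moment-matched lognormal truncated to [min, max].  A zero-variance
    sample yields a constant.  Fewer than 3 positive samples fall back to
    empirical resampling with a warning.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size and np.ptp(x) == 0.0 and x[0] > 0:
        return DistributionSpec.constant(float(x[0]))
    pos = x[x > 0]
    if pos.size < 3:
        warnings.warn(
            f"only {pos.size} positive samples; falling back to empirical resampling",
            stacklevel=2,
        )
        if x.size == 0:
            raise ValueError("cannot fit a distribution to an empty sample")
        return DistributionSpec.empirical(x)
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if m <= 0 or s <= 0:
        warnings.warn("nonpositive mean or sd; falling back to empirical resampling", stacklevel=2)
        return DistributionSpec.empirical(x)
    return DistributionSpec.lognormal_truncated(m, s, float(x.min()), float(x.max()))
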