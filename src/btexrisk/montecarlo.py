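"""Seeded Monte-Carlo propagation of exposure uncertainty through the risk
equations.

Each stratum (workstation, season, analyte) owns an independent random
stream derived deterministically from the master seed and the stratum key,
so adding or reordering strata never perturbs the draws of existing ones.
Within a stream, the draw order is fixed: concentration, then ET, EF, ED,
BW.  Percentiles are reported on the full integer grid 1..99 ("certainty
band" endpoints 1% and 99%), matching the reporting convention of
probabilistic occupational-risk studies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .analytes import Analyte
from .distributions import DistributionSpec
from .risk import (
    AT_CANCER_DAYS,
    DEFAULT_INHALATION_RATE,
    Mode,
    classify_hq,
    classify_lcr,
)

StratumKey = tuple[str, str, str]  # (workstation, season, analyte)

#: Default stochastic models for the questionnaire exposure factors:
#: ET ~ U[8, 12] h/day, EF ~ U[234, 270] d/yr, ED ~ U[21, 40] yr,
#: BW ~ U[70, 97] kg; IR fixed at the adult default 16 m3/day.
DEFAULT_FACTOR_SPECS: dict[str, DistributionSpec] = {
    "et": DistributionSpec.uniform(8.0, 12.0),
    "ef": DistributionSpec.uniform(234.0, 270.0),
    "ed": DistributionSpec.uniform(21.0, 40.0),
    "bw": DistributionSpec.uniform(70.0, 97.0),
    "ir": DistributionSpec.constant(DEFAULT_INHALATION_RATE),
}

PERCENTILE_GRID = np.arange(1, 100)


def stratum_rng(seed: int, workstation: str, season: str, analyte: str) -> np.random.Generator:
    """Deterministic per-stratum generator derived from the master seed."""
    key = zlib.crc32(f"{workstation}|{season}|{analyte}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass(frozen=True)
class RiskSummary:
    """Monte-Carlo summary of one risk endpoint for one stratum.

    ``percentiles`` holds the endpoint value at each integer percentile
    1..99 (linear interpolation between order statistics); ``p95`` is entry
    95 of that grid and ``certainty_band`` its 1%/99% endpoints.  ``mean_in_band``
    flags (without failing) runs whose mean escapes the band — expected only
    at very small iteration counts or extreme skew.
    """

    endpoint: Literal["hq", "lcr"]
    n_iter: int
    seed: int
    mean: float
    sd: float
    percentiles: tuple[float, ...]
    category_at_mean: str
    category_at_p95: str
    mean_in_band: bool = True

    @property
    def p95(self) -> float:
        return self.percentiles[94]

    @property
    def certainty_band(self) -> tuple[float, float]:
        return self.percentiles[0], self.percentiles[98]


def summarize(values: np.ndarray, endpoint: Literal["hq", "lcr"], seed: int) -> RiskSummary:
    """Reduce a vector of simulated endpoint values to a RiskSummary."""
    values = np.asarray(values, dtype=float)
    n = values.size
    pct = np.percentile(values, PERCENTILE_GRID)  # linear interpolation
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    classify = classify_hq if endpoint == "hq" else classify_lcr
    return RiskSummary(
        endpoint=endpoint,
        n_iter=n,
        seed=seed,
        mean=mean,
        sd=sd,
        percentiles=tuple(float(p) for p in pct),
        category_at_mean=classify(mean),
        category_at_p95=classify(float(pct[94])),
        mean_in_band=bool(pct[0] <= mean <= pct[98]) or n < 1000,
    )


def _draw_inputs(
    conc_spec: DistributionSpec,
    factor_specs: Mapping[str, DistributionSpec],
    n_iter: int,
    rng: np.random.Generator,
    method: Literal["rejection", "inverse"] = "rejection",
) -> dict[str, np.ndarray]:
    draws = {"c": conc_spec.sample(n_iter, rng, method=method)}
    for name in ("et", "ef", "ed", "bw", "ir"):
        draws[name] = factor_specs[name].sample(n_iter, rng)
    return draws


def _evaluate(
    draws: Mapping[str, np.ndarray],
    analyte: Analyte,
    mode: Mode,
    at_cancer: float = AT_CANCER_DAYS,
    at_paper: float = 9000.0,
) -> dict[str, np.ndarray | None]:
    c, et, ef, ed, bw, ir = (draws[k] for k in ("c", "et", "ef", "ed", "bw", "ir"))
    if mode == "usepa":
        ec = c * (et / 24.0) * (ef / 365.0)
    else:
        ec = c * et * ed * ef / at_paper
    cdi = c * ir * ed * ef / (bw * at_cancer)
    hq = ec / analyte.rfc if analyte.rfc is not None else None
    lcr = np.minimum(cdi * analyte.sf, 1.0) if analyte.sf is not None else None
    return {"hq": hq, "lcr": lcr}


def run_monte_carlo(
    conc_specs: Mapping[StratumKey, DistributionSpec],
    analytes: Mapping[str, Analyte],
    factor_specs: Mapping[str, DistributionSpec] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    mode: Mode = "usepa",
) -> dict[StratumKey, dict[str, RiskSummary]]:
    """Propagate input uncertainty to HQ and LCR for every stratum.

    For each stratum, ``n_iter`` independent draws of (C, ET, EF, ED, BW)
    are pushed through the dose and risk equations; each available endpoint
    (HQ where the analyte has an RfC, LCR where it has an SF) is summarized
    into a :class:`RiskSummary`.  A missing RfC or SF silently drops that
    endpoint for the stratum rather than failing.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    factor_specs = {**DEFAULT_FACTOR_SPECS, **(factor_specs or {})}
    results: dict[StratumKey, dict[str, RiskSummary]] = {}
    for key, conc_spec in conc_specs.items():
        workstation, season, analyte_name = key
        analyte = analytes[analyte_name]
        rng = stratum_rng(seed, workstation, season, analyte_name)
        draws = _draw_inputs(conc_spec, factor_specs, n_iter, rng)
        endpoints = _evaluate(draws, analyte, mode)
        results[key] = {
            name: summarize(vals, name, seed)  # type: ignore[arg-type]
            for name, vals in endpoints.items()
            if vals is not None
        }
    return results


def compare_seasons(
    conc_specs: Mapping[StratumKey, DistributionSpec],
    analytes: Mapping[str, Analyte],
    factor_specs: Mapping[str, DistributionSpec] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    mode: Mode = "usepa",
    endpoint: Literal["hq", "lcr"] = "hq",
) -> dict[tuple[str, str], dict[str, float]]:
    """Paired summer-vs-winter comparison with common random numbers.

    For each (workstation, analyte) present in both seasons, the two
    seasonal concentration distributions are sampled by inverse-CDF
    transform of a *shared* uniform stream, and the exposure factors are
    drawn once and reused — so the seasonal difference estimate is free of
    the Monte-Carlo noise that independent streams would add.  Returns per
    pair the two endpoint means and their difference.
    """
    factor_specs = {**DEFAULT_FACTOR_SPECS, **(factor_specs or {})}
    pairs: dict[tuple[str, str], dict[str, DistributionSpec]] = {}
    for (workstation, season, analyte_name), spec in conc_specs.items():
        pairs.setdefault((workstation, analyte_name), {})[season] = spec
    out: dict[tuple[str, str], dict[str, float]] = {}
    for (workstation, analyte_name), by_season in sorted(pairs.items()):
        if set(by_season) != {"summer", "winter"}:
            continue
        analyte = analytes[analyte_name]
        rng = stratum_rng(seed, workstation, "paired", analyte_name)
        u = rng.uniform(0.0, 1.0, size=n_iter)
        factors = {name: factor_specs[name].sample(n_iter, rng) for name in ("et", "ef", "ed", "bw", "ir")}
        means: dict[str, float] = {}
        for season in ("summer", "winter"):
            draws = {"c": by_season[season].ppf(u), **factors}
            vals = _evaluate(draws, analyte, mode)[endpoint]
            if vals is None:
                break
            means[season] = float(np.mean(vals))
        if len(means) == 2:
            out[(workstation, analyte_name)] = {
                "summer_mean": means["summer"],
                "winter_mean": means["winter"],
                "difference": means["summer"] - means["winter"],
            }
    return out


def summaries_to_records(
    results: Mapping[StratumKey, Mapping[str, RiskSummary]],
) -> list[dict[str, object]]:
    """Flatten MC results to rows (one per stratum x endpoint) for CSV export."""
    rows: list[dict[str, object]] = []
    for (workstation, season, analyte_name), endpoints in results.items():
        for endpoint, s in endpoints.items():
            rows.append(
                {
                    "workstation": workstation,
                    "season": season,
                    "analyte": analyte_name,
                    "endpoint": endpoint,
                    "n_iter": s.n_iter,
                    "seed": s.seed,
                    "mean": s.mean,
                    "sd": s.sd,
                    "p5": s.percentiles[4],
                    "p25": s.percentiles[24],
                    "p50": s.percentiles[49],
                    "p75": s.percentiles[74],
                    "p95": s.p95,
                    "p99": s.percentiles[98],
                    "category_at_mean": s.category_at_mean,
                    "category_at_p95": s.category_at_p95,
                }
            )
    return rows
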