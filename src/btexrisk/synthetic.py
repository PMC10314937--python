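"""Synthetic exposure-campaign generator.

Emulates the statistical structure of a two-season refinery campaign: for
every workstation, season and analyte a truncated-lognormal concentration
model (moment-matched to the stratum's published mean/SD and truncated to
its observed range), uniform questionnaire exposure factors, shift-sample
durations uniform on [80, 120] min, and a paired design in which every
subject is measured in both seasons.  Field blanks close the QA loop: their
signal SD feeds the limit-of-detection formula.

The packaged stratum profiles reproduce the campaign's published summary
table; the generator defaults (84 subjects, 3 samples per shift, 25 blanks)
are the campaign's own sizes, so the default cohort yields 84 x 3 = 252
shift samples per analyte per season.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .distributions import DistributionSpec
from .exposure import NOMINAL_FACTOR_RANGES, SEASONS, WORKSTATIONS
from .io import CAMPAIGN_COLUMNS, validate_campaign
from .montecarlo import StratumKey, stratum_rng

#: Shift-sample duration bounds, minutes.
DURATION_RANGE = (80.0, 120.0)


@dataclass(frozen=True)
class StratumProfile:
    """Target concentration summary for one workstation/season/analyte."""

    workstation: str
    season: str
    analyte: str
    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.key()}: range must satisfy low < high")
        if not self.low < self.mean < self.high:
            raise ValueError(f"{self.key()}: mean must lie inside the range")
        if not self.sd > 0:
            raise ValueError(f"{self.key()}: sd must be > 0")

    def key(self) -> StratumKey:
        return (self.workstation, self.season, self.analyte)

    def to_spec(self) -> DistributionSpec:
        return DistributionSpec.lognormal_truncated(self.mean, self.sd, self.low, self.high)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic campaign.

    Defaults are the study conditions: 84 subjects, 3 samples per shift
    (252 samples per analyte-season), equal workstation allocation, and the
    questionnaire factor ranges ET 8-12 h/day, EF 234-270 d/yr, ED 21-40 yr,
    BW 70-97 kg.
    """

    n_subjects: int = 84
    samples_per_shift: int = 3
    workstation_allocation: dict[str, float] = field(
        default_factory=lambda: {ws: 0.25 for ws in WORKSTATIONS}
    )
    factor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(NOMINAL_FACTOR_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.samples_per_shift < 1:
            raise ValueError("n_subjects and samples_per_shift must be >= 1")
        total = sum(self.workstation_allocation.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"workstation allocation must sum to 1, got {total}")
        unknown = set(self.workstation_allocation) - set(WORKSTATIONS)
        if unknown:
            raise ValueError(f"unknown workstations in allocation: {sorted(unknown)}")


def load_study_strata(path: str | Path | None = None) -> dict[StratumKey, StratumProfile]:
    """Load stratum profiles; without ``path`` the packaged campaign table."""
    if path is None:
        text = resources.files("btexrisk.data").joinpath("strata.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out: dict[StratumKey, StratumProfile] = {}
    for rec in raw["strata"]:
        profile = StratumProfile(**rec)
        out[profile.key()] = profile
    return out


def strata_to_specs(
    profiles: dict[StratumKey, StratumProfile],
) -> dict[StratumKey, DistributionSpec]:
    """Concentration DistributionSpec per stratum, for the MC engine."""
    return {key: p.to_spec() for key, p in profiles.items()}


def _allocate(spec: CohortSpec) -> dict[str, int]:
    """Integer subject counts per workstation by largest-remainder rounding."""
    items = sorted(spec.workstation_allocation.items())
    raw = {ws: spec.n_subjects * frac for ws, frac in items}
    counts = {ws: int(np.floor(v)) for ws, v in raw.items()}
    short = spec.n_subjects - sum(counts.values())
    for ws, _ in sorted(raw.items(), key=lambda kv: kv[1] - np.floor(kv[1]), reverse=True)[:short]:
        counts[ws] += 1
    return counts


def generate_cohort(
    spec: CohortSpec,
    profiles: dict[StratumKey, StratumProfile] | None = None,
) -> pd.DataFrame:
    """Generate a full paired two-season campaign table.

    Every subject receives a workstation, one set of questionnaire factors,
    and — for each season and analyte — ``samples_per_shift`` concentration
    draws from the stratum's truncated lognormal with durations uniform on
    [80, 120] min.  Fully reproducible from ``spec.seed``.
    """
    profiles = load_study_strata() if profiles is None else profiles
    counts = _allocate(spec)
    analytes = sorted({a for (_, _, a) in profiles})
    for ws, n_ws in counts.items():
        if n_ws == 0:
            continue
        for season in SEASONS:
            for analyte in analytes:
                if (ws, season, analyte) not in profiles:
                    raise ValueError(f"no profile for allocated stratum {(ws, season, analyte)}")

    factor_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xFAC70]))
    subjects: list[tuple[str, str, dict[str, float]]] = []
    sid = 0
    for ws in sorted(counts):
        for _ in range(counts[ws]):
            sid += 1
            factors = {
                name: float(factor_rng.uniform(lo, hi))
                for name, (lo, hi) in spec.factor_ranges.items()
            }
            subjects.append((f"S{sid:04d}", ws, factors))

    frames: list[pd.DataFrame] = []
    for ws in sorted(counts):
        ws_subjects = [(s, f) for s, w, f in subjects if w == ws]
        n_ws = len(ws_subjects)
        if n_ws == 0:
            continue
        n_draws = n_ws * spec.samples_per_shift
        for season in SEASONS:
            for analyte in analytes:
                rng = stratum_rng(spec.seed, ws, season, analyte)
                conc = profiles[(ws, season, analyte)].to_spec().sample(n_draws, rng)
                dur = rng.uniform(*DURATION_RANGE, size=n_draws)
                frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": np.repeat(
                                [s for s, _ in ws_subjects], spec.samples_per_shift
                            ),
                            "workstation": ws,
                            "season": season,
                            "analyte": analyte,
                            "concentration_mg_m3": conc,
                            "duration_min": dur,
                            "below_lod": 0,
                            "et_h_day": np.repeat(
                                [f["et"] for _, f in ws_subjects], spec.samples_per_shift
                            ),
                            "ef_d_yr": np.repeat(
                                [f["ef"] for _, f in ws_subjects], spec.samples_per_shift
                            ),
                            "ed_yr": np.repeat(
                                [f["ed"] for _, f in ws_subjects], spec.samples_per_shift
                            ),
                            "bw_kg": np.repeat(
                                [f["bw"] for _, f in ws_subjects], spec.samples_per_shift
                            ),
                        }
                    )
                )
    table = pd.concat(frames, ignore_index=True)[CAMPAIGN_COLUMNS]
    return validate_campaign(table)


def generate_blanks(n: int = 25, noise_sd: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Field-blank signals: zero-mean Gaussian noise, for LOD estimation.

    Feeding ``signal.std(ddof=1)`` and the calibration slope into
    :func:`btexrisk.exposure.lod` closes the QA/QC loop.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB1A2C]))
    return pd.DataFrame(
        {"blank_id": [f"B{i:03d}" for i in range(1, n + 1)], "signal": rng.normal(0.0, noise_sd, n)}
    )
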