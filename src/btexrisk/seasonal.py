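"""Descriptive summaries and the paired seasonal comparison.

The seasonal comparison is the Friedman rank test on a complete
blocks-by-treatments matrix (subjects x seasons).  It is implemented from
the rank formulas with midranks and the standard tie correction; with two
treatments and no ties it reduces exactly to the two-sided sign test, which
serves as the brute-force oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exposure import SEASONS


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    minimum: float
    maximum: float
    mean: float
    sd: float | None  # None when n == 1

    @property
    def range(self) -> tuple[float, float]:
        return self.minimum, self.maximum


def descriptive_summary(samples) -> DescriptiveSummary:
    """Range, arithmetic mean and sample SD (n-1 denominator)."""
    x = np.asarray(list(samples), dtype=float)
    if x.size < 1:
        raise ValueError("descriptive_summary requires at least one value")
    return DescriptiveSummary(
        n=int(x.size),
        minimum=float(x.min()),
        maximum=float(x.max()),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else None,
    )


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    pvalue: float
    rank_sums: tuple[float, ...]


def friedman_test(matrix) -> FriedmanResult:
    """Friedman chi-square test on an n-blocks x k-treatments matrix.

    Entries are ranked within each block with midranks for ties.  The
    tie-corrected statistic is

        chi2_F = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (A - C),

    with A the sum of squared ranks and C = n*k*(k+1)^2/4; without ties this
    reduces to 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1).  The p-value is the
    chi-square(k-1) upper tail.  Blocks tied across all treatments carry no
    information; when every block is fully tied the statistic is 0 and
    p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-dimensional (blocks x treatments)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 blocks and >= 2 treatments, got {n} x {k}")
    if np.isnan(m).any():
        raise ValueError("matrix must be complete (no missing entries)")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    rank_sums = ranks.sum(axis=0)
    a = float((ranks**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    df = k - 1
    if a - c <= 0:  # every block fully tied
        return FriedmanResult(statistic=0.0, df=df, pvalue=1.0, rank_sums=tuple(rank_sums))
    chi2 = (k - 1) * float(((rank_sums - n * (k + 1) / 2.0) ** 2).sum()) / (a - c)
    p = float(stats.chi2.sf(chi2, df))
    return FriedmanResult(statistic=chi2, df=df, pvalue=p, rank_sums=tuple(rank_sums))


@dataclass(frozen=True)
class KSNormalityResult:
    statistic: float
    pvalue: float
    n: int
    #: The normal parameters were estimated from the sample (Lilliefors
    #: situation), so the asymptotic Kolmogorov p-value is conservative:
    #: the true p-value is smaller.
    params_estimated: bool = True


def ks_normality(samples) -> KSNormalityResult:
    """Kolmogorov-Smirnov D against a normal fitted to the sample.

    D is the sup-distance between the empirical CDF and the normal CDF with
    the sample's mean and SD; the p-value is the asymptotic Kolmogorov
    series evaluated at sqrt(n)*D.  Because the parameters are estimated
    (the Lilliefors situation) this p-value is an upper bound on the true
    one — small p remains decisive evidence against normality.
    """
    x = np.sort(np.asarray(list(samples), dtype=float))
    n = x.size
    if n < 5:
        raise ValueError(f"ks_normality requires n >= 5, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test is degenerate")
    cdf = stats.norm.cdf(x, loc=x.mean(), scale=sd)
    i = np.arange(1, n + 1)
    d = float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))
    p = float(stats.kstwobign.sf(np.sqrt(n) * d))
    return KSNormalityResult(statistic=d, pvalue=p, n=n)


def seasonal_comparison_table(campaign, alpha: float = 0.05):
    """Per-workstation, per-analyte seasonal comparison of subject TWAs.

    ``campaign`` is a campaign table in the canonical long format (see
    :mod:`btexrisk.io`).  Subject shift samples are reduced to a TWA per
    subject-season-analyte; subjects observed in both seasons form the
    paired matrix for the Friedman test.  Returns a DataFrame with one row
    per (workstation, analyte): seasonal means, the test statistic, raw p,
    and a significance flag at ``alpha``.
    """
    import pandas as pd

    twa = (
        campaign.groupby(["workstation", "analyte", "season", "subject_id"])
        .apply(
            lambda g: np.average(g["concentration_mg_m3"], weights=g["duration_min"]),
            include_groups=False,
        )
        .rename("twa")
        .reset_index()
    )
    rows = []
    for (workstation, analyte), grp in twa.groupby(["workstation", "analyte"]):
        wide = grp.pivot(index="subject_id", columns="season", values="twa")
        wide = wide.dropna()
        if wide.shape[0] < 2 or set(SEASONS) - set(wide.columns):
            continue
        res = friedman_test(wide[list(SEASONS)].to_numpy())
        rows.append(
            {
                "workstation": workstation,
                "analyte": analyte,
                "n_subjects": wide.shape[0],
                "summer_mean": float(wide["summer"].mean()),
                "winter_mean": float(wide["winter"].mean()),
                "chi2_f": res.statistic,
                "pvalue": res.pvalue,
                "significant": res.pvalue < alpha,
            }
        )
    return pd.DataFrame(rows)
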