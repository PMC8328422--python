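"""Growth biochronologies, variance partitioning and the plasticity F test.

A biochronology here is the posterior distribution of the year random
effects of the growth model, one series per group x environment stratum:
positive values are years in which fish of that group grew more than their
age/group baseline in that environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import Design, ModelError, PosteriorSamples


@dataclass
class ChronologyIndex:
    """Posterior year-effect distributions for every observed stratum-year.

    ``table`` has one row per (group, environment, year) with posterior mean,
    SD and central 95% quantiles; ``draws`` is the (n_draws, n_cells) matrix
    the summaries were computed from, kept so that downstream Monte Carlo
    tests can propagate the full posterior rather than the point summaries.
    """

    table: pd.DataFrame
    draws: np.ndarray
    cells: list[tuple]

    def stratum(self, group: str, environment: str) -> pd.DataFrame:
        sub = self.table[(self.table["group"] == group) & (self.table["environment"] == environment)]
        return sub.sort_values("year").reset_index(drop=True)

    def stratum_draws(self, group: str, environment: str) -> tuple[np.ndarray, np.ndarray]:
        """(years, draw matrix restricted to the stratum, ordered by year)."""
        idx_years = [
            (i, c[2]) for i, c in enumerate(self.cells) if c[0] == group and c[1] == environment
        ]
        idx_years.sort(key=lambda t: t[1])
        idx = [i for i, _ in idx_years]
        years = np.array([y for _, y in idx_years])
        return years, self.draws[:, idx]


def extract_chronology(samples: PosteriorSamples) -> ChronologyIndex:
    """Summarise the year-effect draws into per-cell chronologies.

    Pure function of the draws: no re-access to the data.
    """
    if samples.u_year.size == 0:
        raise ModelError("posterior contains no year-effect draws")
    draws = samples.u_year
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "group": [c[0] for c in samples.cells],
            "environment": [c[1] for c in samples.cells],
            "year": [c[2] for c in samples.cells],
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1),
            "q2.5": lo,
            "q97.5": hi,
        }
    ).sort_values(["group", "environment", "year"]).reset_index(drop=True)
    return ChronologyIndex(table=table, draws=draws, cells=list(samples.cells))


@dataclass
class VariancePartition:
    """Share of total variance per component (observation / fish / year).

    Shares are posterior-mean SDs squared over their sum, in percent, the
    standard mixed-model reading of "variance explained by" a random term.
    """

    table: pd.DataFrame

    def percent(self, component: str) -> float:
        return float(self.table.set_index("component").loc[component, "percent"])


def variance_partition(samples: PosteriorSamples) -> VariancePartition:
    """Partition total variance across the three components."""
    sds = {
        "observation": float(samples.sigma_obs.mean()),
        "fish": float(samples.sigma_fish.mean()) if samples.sigma_fish.size else 0.0,
        "year": float(samples.sigma_year.mean()) if samples.sigma_year.size else 0.0,
    }
    total = sum(s**2 for s in sds.values())
    if total == 0:
        raise ModelError("all variance components are zero")
    table = pd.DataFrame(
        [
            {"component": k, "sd_mean": s, "percent": 100.0 * s**2 / total}
            for k, s in sds.items()
        ]
    )
    return VariancePartition(table)


@dataclass
class PlasticityTest:
    """Variance-ratio comparison of per-fish intercepts between groups."""

    var_hatchery: float
    var_wild: float
    f_statistic: float  # hatchery / wild
    df_num: int
    df_den: int
    p_value: float
    two_sided: bool


def fish_plasticity_test(
    samples: PosteriorSamples,
    fish_groups: pd.Series | None = None,
    design: Design | None = None,
    two_sided: bool = True,
) -> PlasticityTest:
    """F test of equal fish-intercept variance between hatchery and wild.

    Uses the posterior means of the fish random intercepts as point
    summaries (the conventional two-step procedure; its nonconservatism is
    documented).  F = var(hatchery) / var(wild) with (n_h - 1, n_w - 1)
    degrees of freedom.
    """
    if fish_groups is None:
        if design is None:
            raise ModelError("provide fish_groups or the design")
        fish_groups = design.fish_groups
    if samples.u_fish.size == 0:
        raise ModelError("posterior contains no fish-intercept draws")
    means = pd.Series(samples.u_fish.mean(axis=0), index=samples.fish_ids)
    groups = fish_groups.reindex(means.index)
    if groups.isna().any():
        missing = list(means.index[groups.isna()])[:5]
        raise ModelError(f"no group known for fish {missing}")
    hatch = means[groups == "hatchery"].to_numpy()
    wild = means[groups == "wild"].to_numpy()
    return f_test_variances(hatch, wild, two_sided=two_sided)


def f_test_variances(
    hatchery: np.ndarray, wild: np.ndarray, two_sided: bool = True
) -> PlasticityTest:
    """Variance-ratio F test on two samples of per-fish summaries."""
    if len(hatchery) < 2 or len(wild) < 2:
        raise ModelError("each group needs at least 2 fish")
    v_h = float(np.var(hatchery, ddof=1))
    v_w = float(np.var(wild, ddof=1))
    if v_w == 0:
        raise ModelError("wild-group variance is zero")
    f = v_h / v_w
    df1, df2 = len(hatchery) - 1, len(wild) - 1
    cdf = stats.f.cdf(f, df1, df2)
    p = 2.0 * min(cdf, 1.0 - cdf) if two_sided else 1.0 - cdf
    return PlasticityTest(
        var_hatchery=v_h, var_wild=v_w, f_statistic=f,
        df_num=df1, df_den=df2, p_value=float(min(p, 1.0)), two_sided=two_sided,
    )
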