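"""Temperature aggregation and posterior-propagating correlation tests.

The growth-temperature association is assessed per group x environment
stratum by correlating each posterior draw of the year-effect series with
the yearly temperature series, rather than correlating the posterior mean
alone.  The spread of the per-draw correlations carries the uncertainty of
the chronology into the secondary test; collapsing the posterior to its
mean recovers the classical (nonconservative) two-step procedure as a
special case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chronology import ChronologyIndex
from .model import ModelError

MONTH_WINDOWS = {"annual": tuple(range(1, 13)), "jul_dec": (7, 8, 9, 10, 11, 12)}


def aggregate_monthly(
    monthly: pd.DataFrame,
    months: tuple[int, ...] | str,
    years: list[int] | None = None,
    environment: str | None = None,
) -> pd.DataFrame:
    """Aggregate a monthly series (year, month, temperature_c) to yearly means.

    ``months`` is a tuple of month numbers or one of the named windows
    ``"annual"`` / ``"jul_dec"`` (the sea window: July-December).  Years with
    any month of the window missing are flagged ``missing=True`` and carry
    NaN; callers drop them with a warning.
    """
    if isinstance(months, str):
        months = MONTH_WINDOWS[months]
    if len(months) == 0:
        raise ValueError("empty month window")
    sub = monthly[monthly["month"].isin(months)]
    if years is None:
        years = sorted(monthly["year"].unique())
    rows = []
    for year in years:
        vals = sub.loc[sub["year"] == year, "temperature_c"]
        complete = len(vals) == len(months)
        if not complete:
            warnings.warn(f"year {year}: month window incomplete, flagged missing", stacklevel=2)
        rows.append(
            {
                "environment": environment or "",
                "year": year,
                "temperature_c": float(vals.mean()) if complete else np.nan,
                "missing": not complete,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MonteCarloCorrelation:
    """Per-draw correlations between one stratum's chronology and temperature."""

    group: str
    environment: str
    r_draws: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    mean_r: float
    ci_low: float
    ci_high: float
    important: bool  # 95% interval excludes zero
    n_years: int
    n_draws: int
    years: np.ndarray
    temperature: np.ndarray
    mean_chronology: np.ndarray


def monte_carlo_correlation(
    chronology: ChronologyIndex,
    temperature: pd.DataFrame,
    group: str,
    environment: str,
    n_draws: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> MonteCarloCorrelation:
    """Correlate posterior year-effect draws with temperature.

    For each retained draw the year-effect vector of the stratum is
    correlated (Pearson by default, Spearman by flag) with the temperature
    series over the overlapping years, and a least-squares line is fitted
    for plotting.  If the posterior holds more draws than requested, a
    seeded subsample is used.
    """
    years, draws = chronology.stratum_draws(group, environment)
    temp = (
        temperature.loc[temperature["environment"] == environment]
        .dropna(subset=["temperature_c"])
        .set_index("year")["temperature_c"]
    )
    common = np.array([y for y in years if y in temp.index])
    if len(common) < 3:
        raise ModelError(
            f"need >= 3 overlapping years between chronology and temperature, got {len(common)}"
        )
    keep = np.isin(years, common)
    draws = draws[:, keep]
    t = temp.loc[common].to_numpy(float)
    if np.std(t) == 0:
        raise ModelError("temperature series has zero variance over the overlap")

    rng = np.random.default_rng(seed)
    if n_draws > draws.shape[0]:
        n_draws = draws.shape[0]
    idx = rng.choice(draws.shape[0], size=n_draws, replace=False)
    sub = draws[idx]

    if method == "spearman":
        from scipy.stats import rankdata

        sub_r = rankdata(sub, axis=1)
        t_r = rankdata(t)
    elif method == "pearson":
        sub_r, t_r = sub, t
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    tc = t_r - t_r.mean()
    gc = sub_r - sub_r.mean(axis=1, keepdims=True)
    denom = np.sqrt((gc**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(invalid="ignore"):
        r = np.where(denom > 0, (gc @ tc) / denom, 0.0)

    # least-squares line of the (raw) year effect on temperature, per draw
    tc_raw = t - t.mean()
    slopes = ((sub - sub.mean(axis=1, keepdims=True)) @ tc_raw) / (tc_raw @ tc_raw)
    intercepts = sub.mean(axis=1) - slopes * t.mean()

    lo, hi = np.percentile(r, [2.5, 97.5])
    return MonteCarloCorrelation(
        group=group,
        environment=environment,
        r_draws=r,
        slopes=slopes,
        intercepts=intercepts,
        mean_r=float(r.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        important=bool(lo > 0 or hi < 0),
        n_years=len(common),
        n_draws=n_draws,
        years=common,
        temperature=t,
        mean_chronology=draws.mean(axis=0),
    )


def correlation_report(results: list[MonteCarloCorrelation]) -> pd.DataFrame:
    """Tidy one-row-per-stratum table of the Monte Carlo correlations."""
    if not results:
        raise ValueError("no strata to report")
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "environment": r.environment,
                "mean_r": r.mean_r,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "important": r.important,
                "n_years": r.n_years,
                "n_draws": r.n_draws,
            }
            for r in results
        ]
    )


def plot_correlations(results: list[MonteCarloCorrelation], path=None, max_lines: int = 200):
    """Scatter of chronology vs temperature with per-draw thin regression
    lines and the mean-fit bold line, one panel per stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(4 * len(results), 3.5), squeeze=False)
    for ax, res in zip(axes[0], results):
        xs = np.linspace(res.temperature.min(), res.temperature.max(), 20)
        for s, b in zip(res.slopes[:max_lines], res.intercepts[:max_lines]):
            ax.plot(xs, b + s * xs, color="steelblue", alpha=0.05, lw=0.6)
        mean_slope = res.slopes.mean()
        mean_int = res.intercepts.mean()
        ax.plot(xs, mean_int + mean_slope * xs, color="black", lw=2)
        ax.scatter(res.temperature, res.mean_chronology, color="firebrick", zorder=3, s=18)
        ax.set_title(
            f"{res.group} / {res.environment}\n"
            f"r = {res.mean_r:.2f} [{res.ci_low:.2f}, {res.ci_high:.2f}]"
        )
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("year effect (log μm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
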