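"""Somatic-growth proxy validation: fork length against scale radius/circuli.

Ordinary least squares of fork length (cm) on a scale predictor with a
wild/hatchery group offset and slope interaction, to check that scale growth
tracks somatic growth equally in both groups before increments are used as
the growth proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

PREDICTOR_COLUMNS = {"radius": "scale_radius_um", "circuli": "circulus_count"}


@dataclass
class CalibrationFit:
    """OLS summary of the fork length ~ predictor * group model."""

    predictor: str
    coefficients: pd.DataFrame  # term, estimate, ci_low, ci_high, p_value
    r_squared: float
    n: int
    reduced_coefficients: pd.DataFrame  # no-group model (slope + intercept)
    reduced_r_squared: float

    def coefficient(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "estimate"])


def fit_calibration(fish: pd.DataFrame, predictor: str = "radius") -> CalibrationFit:
    """Fit fork_length_cm ~ predictor * group by OLS.

    Group is coded with hatchery as reference so the interaction term reads
    as the wild-group slope offset.  The reduced (no-group) model is fitted
    alongside — it is the form usually quoted as the calibration line.
    """
    if predictor not in PREDICTOR_COLUMNS:
        raise ValueError(f"predictor must be one of {sorted(PREDICTOR_COLUMNS)}")
    col = PREDICTOR_COLUMNS[predictor]
    if col not in fish.columns:
        raise ValueError(f"fish table lacks column {col!r}")
    if (fish[col] <= 0).any():
        raise ValueError(f"non-positive values in {col!r}")

    df = fish[[col, "fork_length_cm", "group"]].rename(columns={col: "x"}).copy()
    df["wild"] = (df["group"] == "wild").astype(float)

    full = smf.ols("fork_length_cm ~ x * wild", data=df).fit()
    reduced = smf.ols("fork_length_cm ~ x", data=df).fit()

    def _table(res, names: dict[str, str]) -> pd.DataFrame:
        ci = res.conf_int()
        return pd.DataFrame(
            {
                "term": [names[t] for t in res.params.index],
                "estimate": res.params.to_numpy(),
                "ci_low": ci[0].to_numpy(),
                "ci_high": ci[1].to_numpy(),
                "p_value": res.pvalues.to_numpy(),
            }
        )

    full_names = {
        "Intercept": "Intercept",
        "x": predictor.capitalize(),
        "wild": "Group[Wild]",
        "x:wild": f"{predictor.capitalize()}:Group[Wild]",
    }
    reduced_names = {"Intercept": "Intercept", "x": predictor.capitalize()}

    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("degenerate (collinear) calibration design")

    return CalibrationFit(
        predictor=predictor,
        coefficients=_table(full, full_names),
        r_squared=float(full.rsquared),
        n=int(full.nobs),
        reduced_coefficients=_table(reduced, reduced_names),
        reduced_r_squared=float(reduced.rsquared),
    )


def compare_predictors(fish: pd.DataFrame) -> pd.DataFrame:
    """R-squared comparison of the radius and circulus-count calibrations."""
    rows = []
    for predictor in ("radius", "circuli"):
        fit = fit_calibration(fish, predictor)
        rows.append(
            {"predictor": predictor, "r_squared": fit.r_squared, "n": fit.n}
        )
    return pd.DataFrame(rows)
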