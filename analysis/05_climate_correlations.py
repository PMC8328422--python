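"""Correlate growth chronologies with temperature, propagating uncertainty.

For each group x environment stratum, correlates 1,000 posterior draws of
the year-effect series with the environment's temperature series and
summarises the distribution of correlations.  Two sources of uncertainty
are visible: the Monte Carlo interval reflects chronology estimation error,
while the short (12-13 year) overlap makes the *realized* truth-temperature
correlation scatter widely around the planted population coupling — the
table therefore prints the realized correlation of the generative year
effects next to each estimate, which is what the method can be expected to
recover on one cohort.

Reads results/posterior.npz and results/data/; writes correlations.csv and
correlations.png.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from scalechron import (
    PosteriorSamples,
    correlation_report,
    extract_chronology,
    monte_carlo_correlation,
    read_temperature_csv,
)
from scalechron.climate import plot_correlations
from scalechron.experiments import derive_seed


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--draws", type=int, default=1000)
    args = parser.parse_args()

    samples = PosteriorSamples.load(args.out / "posterior.npz")
    temperature = read_temperature_csv(args.out / "data" / "temperature.csv")
    truth = pd.read_csv(args.out / "data" / "true_year_effects.csv")
    chron = extract_chronology(samples)

    results, realized = [], []
    for env in ("freshwater", "sea"):
        for group in ("hatchery", "wild"):
            res = monte_carlo_correlation(
                chron, temperature, group, env,
                n_draws=args.draws, seed=derive_seed(args.seed, 3),
            )
            results.append(res)
            e = truth[(truth.group == group) & (truth.environment == env)]
            e = e.set_index("year")["effect"].loc[res.years]
            realized.append(float(np.corrcoef(e, res.temperature)[0, 1]))
    table = correlation_report(results)
    table["realized_truth_r"] = np.round(realized, 3)
    table.to_csv(args.out / "correlations.csv", index=False)
    plot_correlations(results, args.out / "correlations.png")
    print(table.round(3).to_string(index=False))
    print("(planted population couplings: fw/hatchery 0.05, fw/wild 0.21, "
          "sea/hatchery 0.29, sea/wild 0.41; the realized column shows their "
          "13-year sample realisations)")


if __name__ == "__main__":
    main()
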