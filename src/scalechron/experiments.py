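"""Canned end-to-end experiments at the study's sample sizes.

These drive the parameter-recovery and plasticity-test experiments that the
analysis scripts and the acceptance checks share: simulate a cohort from the
generative truth at full size, run the standard filtering, fit the growth
model, and report the recovered posterior summaries next to the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chronology import PlasticityTest, extract_chronology, f_test_variances
from .data import exclude_rare_life_histories, filter_increments, validate_dataset
from .model import Design, GrowthModelSpec, PosteriorSamples, SamplerConfig, build_design, fit
from .simulate import CohortConfig, GenerativeParams, generate_cohort


def derive_seed(seed: int, index: int) -> int:
    """Stable sub-seed < 2^31 from a root seed and a stream index."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


@dataclass
class RecoveryResult:
    """Simulate-and-refit experiment output."""

    fixed_effects: pd.DataFrame  # posterior summaries with truth column
    sd_components: pd.DataFrame  # posterior summaries of the three SDs with truth
    design: Design
    samples: PosteriorSamples
    truth: GenerativeParams
    n_increments: int
    n_fish: int
    year_effect_recovery_r: float

    def fixed_mean(self, name: str) -> float:
        return float(self.fixed_effects.set_index("coefficient").loc[name, "mean"])

    def fixed_sd(self, name: str) -> float:
        return float(self.fixed_effects.set_index("coefficient").loc[name, "sd"])

    def sd_mean(self, component: str) -> float:
        return float(self.sd_components.set_index("component").loc[component, "mean"])


def parameter_recovery_experiment(
    seed: int,
    cohort: CohortConfig | None = None,
    truth: GenerativeParams | None = None,
    sampler: SamplerConfig | None = None,
) -> RecoveryResult:
    """Simulate at full study size from the generative truth and refit.

    Defaults: 1,596 regular fish (plus 7 rare, excluded by the standard
    rule), the coefficient-table truth, and 2 chains x 1,250 post-burn-in
    draws under PC priors.
    """
    cohort = cohort or CohortConfig()
    truth = truth or GenerativeParams()
    sampler = sampler or SamplerConfig(draws=1250, burnin=600, chains=2)

    dataset, _, year_effects = generate_cohort(cohort, truth, derive_seed(seed, 0))
    dataset = filter_increments(exclude_rare_life_histories(dataset))
    validate_dataset(dataset, filtered=True)

    spec = GrowthModelSpec()
    design = build_design(dataset, spec)
    samples = fit(design, spec, sampler, seed=derive_seed(seed, 1))

    fixed = samples.fixed_effects_summary()
    fixed["truth"] = [
        truth.beta.get(name, np.nan) if name != "Intercept" else truth.beta["Intercept"]
        for name in fixed["coefficient"]
    ]
    sds = samples.sd_summary()
    sds["truth"] = [truth.sigma_obs, truth.sigma_fish, truth.sigma_year]

    chron = extract_chronology(samples)
    planted = year_effects.set_index(["group", "environment", "year"])["effect"]
    tru = np.array(
        [planted.loc[(r["group"], r["environment"], r["year"])] for _, r in chron.table.iterrows()]
    )
    recovery_r = float(np.corrcoef(chron.table["mean"].to_numpy(), tru)[0, 1])

    return RecoveryResult(
        fixed_effects=fixed,
        sd_components=sds,
        design=design,
        samples=samples,
        truth=truth,
        n_increments=design.n,
        n_fish=design.n_fish,
        year_effect_recovery_r=recovery_r,
    )


def plasticity_ratio_experiment(
    seed: int,
    n_hatchery: int = 1147,
    n_wild: int = 449,
    variance_ratio: float = 0.41,
    scale: float = 0.058,
) -> PlasticityTest:
    """Variance-ratio F test on intercepts drawn with a planted ratio.

    Hatchery intercepts have variance ``variance_ratio`` times the wild
    variance, with the study's group sizes, so the expected F statistic is
    the planted ratio and the dfs are (n_hatchery - 1, n_wild - 1).
    """
    rng = np.random.default_rng(derive_seed(seed, 2))
    hatchery = rng.normal(0.0, np.sqrt(variance_ratio) * scale, n_hatchery)
    wild = rng.normal(0.0, scale, n_wild)
    return f_test_variances(hatchery, wild)
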