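"""Synthetic sea trout cohorts with the generative structure the analysis assumes.

Increment widths are log-normal: for a zone of age class ``a`` grown by a fish
of group ``g`` in year ``t``,

    log width_um = beta0 + beta_age[a] + beta_group[g] + beta_int[a, g]
                   + u_fish + u_year[g, env(a), t] + eps

with ``u_fish ~ N(0, sigma_fish^2)``, ``u_year ~ N(0, sigma_year^2)`` and
``eps ~ N(0, sigma_obs^2)``, all on the natural-log micrometre scale.  Year
effects are optionally coupled to the yearly temperature series of their
environment with a configurable correlation per group x environment stratum,
which is what makes growth-temperature correlation tests recoverable.

The cohort composition (smolt ages, sea ages, group and sex ratios, repeat
spawning) and the temperature climatologies default to the study conditions;
every default is a plain dataclass field and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ages import AgeCode, age_class_sequence, environment_of
from .data import AnalysisDataset, assign_growth_years

#: Fixed-effect truth on the log-um scale (hatchery FW1 baseline).
DEFAULT_BETA = {
    "Intercept": 6.70,
    "FW2": -0.23,
    "SW1": 0.61,
    "SW2": 0.58,
    "SW3": 0.23,
    "Wild": -0.39,
    "FW2:Wild": 0.32,
    "SW1:Wild": 0.53,
    "SW2:Wild": 0.35,
    "SW3:Wild": 0.24,
}


@dataclass(frozen=True)
class CohortConfig:
    """Composition of a simulated spawning-run sample.

    Defaults reproduce the study sample: 1,596 fish caught 2007-2016, 89.9%
    FW1 smolts, sea-age mix 63.0/35.1/1.9% (SW1/SW2/SW3), 10.7% repeat
    spawners, group split from the plasticity-test group sizes (449 wild,
    1,147 hatchery) and sex ratio 1,249 female : 347 male.  ``rare_life_histories``
    are extra fish appended on top of ``n_fish`` so the default cohort holds
    1,603 fish of which the standard exclusion rule removes exactly 7.
    """

    n_fish: int = 1596
    p_wild: float = 449 / 1596
    p_fw1: float = 0.899
    sea_age_probs: tuple[float, ...] = (0.630, 0.351, 0.019)  # SW1, SW2, SW3
    p_repeat_spawner: float = 0.107
    capture_years: tuple[int, int] = (2007, 2016)
    p_female: float = 1249 / 1596
    rare_life_histories: dict = field(
        default_factory=lambda: {"2.0+": 3, "2.3+": 3, "3.1+": 1}
    )
    marginal_fraction_range: tuple[float, float] = (0.2, 0.8)
    spawning_erosion_factor: float = 0.7

    def __post_init__(self) -> None:
        probs = [self.p_wild, self.p_fw1, self.p_repeat_spawner, self.p_female]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.sea_age_probs) - 1.0) > 1e-9:
            raise ValueError("sea_age_probs must sum to 1")
        if self.capture_years[0] > self.capture_years[1]:
            raise ValueError("capture_years range is inverted")


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the log-normal increment model and its climate coupling.

    ``beta`` is keyed like the fitted model's coefficient table.  Temperature
    climatologies are the study's: sea Jul-Dec mean 12.0 +/- 0.7 degC,
    freshwater annual mean 9.1 +/- 0.5 degC.  ``rho`` holds the year-effect /
    temperature correlation per (environment, group); defaults plant the
    coupling magnitudes the correlation analysis reports.
    """

    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_obs: float = 0.155
    sigma_fish: float = 0.058
    sigma_year: float = 0.065
    rho: dict = field(
        default_factory=lambda: {
            ("sea", "wild"): 0.41,
            ("sea", "hatchery"): 0.29,
            ("freshwater", "wild"): 0.21,
            ("freshwater", "hatchery"): 0.05,
        }
    )
    temperature_mean: dict = field(
        default_factory=lambda: {"sea": 12.0, "freshwater": 9.1}
    )
    temperature_sd: dict = field(default_factory=lambda: {"sea": 0.7, "freshwater": 0.5})
    temperature_ar1: float = 0.0
    # Somatic-growth proxies for the fish table (length in cm, radius in um).
    fl_intercept: float = 17.128
    fl_slope: float = 0.013
    fl_noise_sd: float = 5.4
    circuli_per_um: float = 0.0302
    circuli_noise_sd: float = 4.0

    def __post_init__(self) -> None:
        for name in ("sigma_obs", "sigma_fish", "sigma_year"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(abs(r) > 1.0 for r in self.rho.values()):
            raise ValueError("|rho| must be <= 1")

    def linear_predictor(self, age_class: str, group: str) -> float:
        """Fixed-effect part of log width for one cell."""
        # .get so that rare-life-history classes absent from the coefficient
        # table (e.g. FW3) fall back to the baseline; those fish exist only
        # to exercise the exclusion rule
        eta = self.beta["Intercept"]
        if age_class != "FW1":
            eta += self.beta.get(age_class, 0.0)
        if group == "wild":
            eta += self.beta["Wild"]
            if age_class != "FW1":
                eta += self.beta.get(f"{age_class}:Wild", 0.0)
        return eta


def generate_temperature(
    years: range | list[int],
    params: GenerativeParams,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw yearly temperature series for both environments.

    Independent normal draws with the configured climatology by default; an
    AR(1) coefficient > 0 adds interannual persistence while keeping the
    stationary mean and SD.
    """
    rng = np.random.default_rng(seed)
    years = list(years)
    rows = []
    phi = params.temperature_ar1
    for env in ("freshwater", "sea"):
        mu, sd = params.temperature_mean[env], params.temperature_sd[env]
        z = rng.standard_normal(len(years))
        if phi != 0.0:
            x = np.empty(len(years))
            innov_sd = np.sqrt(1.0 - phi**2)
            x[0] = z[0]
            for t in range(1, len(years)):
                x[t] = phi * x[t - 1] + innov_sd * z[t]
            z = x
        for year, zt in zip(years, z):
            rows.append({"environment": env, "year": year, "temperature_c": mu + sd * zt})
    return pd.DataFrame(rows)


def generate_year_effects(
    years: range | list[int],
    params: GenerativeParams,
    temperature: pd.DataFrame,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw year random effects per group x environment, temperature-coupled.

    For each stratum the effect is ``sigma_year * (rho * z_temp +
    sqrt(1 - rho^2) * z)`` where ``z_temp`` is that environment's
    sample-standardised temperature and ``z`` is fresh standard-normal noise,
    so the population correlation with temperature is exactly ``rho``.
    """
    rng = np.random.default_rng(seed)
    years = list(years)
    rows = []
    for env in ("freshwater", "sea"):
        temps = (
            temperature.loc[temperature["environment"] == env]
            .set_index("year")["temperature_c"]
            .reindex(years)
        )
        if temps.isna().any():
            missing = [y for y, t in temps.items() if pd.isna(t)]
            raise ValueError(f"temperature series for {env!r} missing years {missing}")
        t = temps.to_numpy()
        sd = t.std(ddof=0)
        z_temp = (t - t.mean()) / sd if sd > 0 else np.zeros_like(t)
        for group in ("wild", "hatchery"):
            rho = params.rho.get((env, group), 0.0)
            z = rng.standard_normal(len(years))
            eff = params.sigma_year * (rho * z_temp + np.sqrt(1.0 - rho**2) * z)
            for year, e in zip(years, eff):
                rows.append(
                    {"group": group, "environment": env, "year": year, "effect": e}
                )
    return pd.DataFrame(rows)


def _draw_life_histories(config: CohortConfig, rng: np.random.Generator) -> list[AgeCode]:
    """Regular fish life histories, rejecting combinations listed as rare."""
    rare = set(config.rare_life_histories)
    codes: list[AgeCode] = []
    while len(codes) < config.n_fish:
        fw = 1 if rng.random() < config.p_fw1 else 2
        sw = int(rng.choice(np.arange(1, len(config.sea_age_probs) + 1), p=config.sea_age_probs))
        code = AgeCode(fw, sw, plus=True)
        if str(code) in rare:
            continue  # rare combinations are injected explicitly, not drawn
        codes.append(code)
    for code_str, count in config.rare_life_histories.items():
        from .ages import parse_age_code

        codes.extend([parse_age_code(code_str)] * count)
    return codes


def generate_cohort(
    config: CohortConfig,
    params: GenerativeParams,
    seed: int | np.random.Generator,
    year_effects: pd.DataFrame | None = None,
    temperature: pd.DataFrame | None = None,
) -> tuple[AnalysisDataset, pd.DataFrame, pd.DataFrame]:
    """Simulate a full pre-filtering dataset.

    Returns ``(dataset, temperature, year_effects)``.  The dataset includes
    marginal and spawning zones (they are what the filtering stage removes),
    calendar-anchored growth years, and a fish table whose scale radius is
    the sum of that fish's zone widths, with fork length and circulus count
    derived from the radius.

    Temperature and year effects are drawn here unless supplied; the span
    covers every growth year any simulated zone can occupy.
    """
    rng = np.random.default_rng(seed)
    c_lo, c_hi = config.capture_years
    max_zones = 1 + max(
        (AgeCode(int(s[0]), int(s[2]), True).n_completed_zones for s in config.rare_life_histories),
        default=0,
    )
    max_zones = max(max_zones, 1 + 2 + len(config.sea_age_probs))
    years = range(c_lo - max_zones + 1, c_hi + 1)

    if temperature is None:
        temperature = generate_temperature(years, params, rng)
    if year_effects is None:
        year_effects = generate_year_effects(years, params, temperature, rng)
    eff = year_effects.set_index(["group", "environment", "year"])["effect"]

    codes = _draw_life_histories(config, rng)
    n_total = len(codes)
    groups = np.where(rng.random(n_total) < config.p_wild, "wild", "hatchery")
    sexes = np.where(rng.random(n_total) < config.p_female, "female", "male")
    capture = rng.integers(c_lo, c_hi + 1, size=n_total)
    u_fish = rng.normal(0.0, params.sigma_fish, size=n_total)

    # Repeat spawners need a completed post-spawning sea zone, i.e. sea age >= 2.
    sw_ages = np.array([c.sw_age for c in codes])
    p_sw2 = float((sw_ages >= 2).mean())
    p_rs_cond = min(1.0, config.p_repeat_spawner / p_sw2) if p_sw2 > 0 else 0.0
    repeat = (sw_ages >= 2) & (rng.random(n_total) < p_rs_cond)

    fish_rows, inc_rows = [], []
    frac_lo, frac_hi = config.marginal_fraction_range
    for i, code in enumerate(codes):
        fid = f"F{i + 1:04d}"
        group, cap_year = groups[i], int(capture[i])
        classes = age_class_sequence(code)
        widths = []
        m = len(classes)
        # zone k's year effect uses the same calendar anchoring that
        # assign_growth_years re-derives downstream
        for k, age_class in enumerate(classes, start=1):
            env = environment_of(age_class)
            gyear = cap_year - 1 - (m - k)
            log_w = (
                params.linear_predictor(age_class, group)
                + u_fish[i]
                + eff.loc[(group, env, gyear)]
                + rng.normal(0.0, params.sigma_obs)
            )
            widths.append(float(np.exp(log_w)))
        is_spawning = [False] * m
        if repeat[i]:
            # last completed sea zone formed after the first spawning run
            is_spawning[m - 1] = True
            widths[m - 1] *= config.spawning_erosion_factor

        # marginal plus-growth zone: a fraction of what the next full year
        # at sea would have been (its value is discarded by the pipeline)
        marginal_width = None
        if code.plus:
            next_class = f"SW{min(code.sw_age + 1, 3)}" if code.sw_age >= 1 else "SW1"
            full = np.exp(
                params.linear_predictor(next_class, group)
                + u_fish[i]
                + eff.loc[(group, "sea", cap_year)]
                + rng.normal(0.0, params.sigma_obs)
            )
            marginal_width = float(full * rng.uniform(frac_lo, frac_hi))

        for k, (age_class, w) in enumerate(zip(classes, widths), start=1):
            inc_rows.append(
                {
                    "fish_id": fid,
                    "group": group,
                    "sex": sexes[i],
                    "capture_year": cap_year,
                    "age_code": str(code),
                    "increment_index": k,
                    "age_class": age_class,
                    "width_um": w,
                    "is_marginal": False,
                    "is_spawning_zone": is_spawning[k - 1],
                }
            )
        if marginal_width is not None:
            inc_rows.append(
                {
                    "fish_id": fid,
                    "group": group,
                    "sex": sexes[i],
                    "capture_year": cap_year,
                    "age_code": str(code),
                    "increment_index": m + 1,
                    "age_class": f"SW{min(code.sw_age + 1, 3)}" if code.sw_age >= 1 else "SW1",
                    "width_um": marginal_width,
                    "is_marginal": True,
                    "is_spawning_zone": False,
                }
            )

        radius = float(sum(widths) + (marginal_width or 0.0))
        fork_length = params.fl_intercept + params.fl_slope * radius + rng.normal(
            0.0, params.fl_noise_sd
        )
        circuli = int(
            round(max(1.0, params.circuli_per_um * radius + rng.normal(0.0, params.circuli_noise_sd)))
        )
        fish_rows.append(
            {
                "fish_id": fid,
                "group": group,
                "sex": sexes[i],
                "capture_year": cap_year,
                "age_code": str(code),
                "fork_length_cm": max(1.0, float(fork_length)),
                "scale_radius_um": radius,
                "circulus_count": circuli,
                "repeat_spawner": bool(repeat[i]),
            }
        )

    fish = pd.DataFrame(fish_rows)
    increments = pd.DataFrame(inc_rows)
    increments = assign_growth_years(fish, increments)
    dataset = AnalysisDataset(
        fish=fish, increments=increments, provenance={"rows_in": len(increments)}
    )
    return dataset, temperature, year_effects


def with_zero_variances(params: GenerativeParams) -> GenerativeParams:
    """Convenience: the same fixed effects with all random variation off."""
    return replace(params, sigma_obs=0.0, sigma_fish=0.0, sigma_year=0.0)
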