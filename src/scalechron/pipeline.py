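"""End-to-end run orchestration: simulate/load -> filter -> fit -> report.

A run is configured by a YAML file (or a :class:`RunConfig` built in code),
executes each stage with a seed deterministically derived from the single
global seed, and writes every artifact plus a provenance log into the output
directory.  Identical config + seed give identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import calibration as calib
from . import chronology as chron
from . import climate as clim
from .data import (
    AnalysisDataset,
    assign_growth_years,
    exclude_rare_life_histories,
    filter_increments,
    read_increment_csv,
    read_temperature_csv,
    validate_dataset,
    write_increment_csv,
)
from .model import GrowthModelSpec, SamplerConfig, build_design, compare_terms, dic, fit
from .simulate import CohortConfig, GenerativeParams, generate_cohort

log = logging.getLogger("scalechron")

#: Stage names with fixed positions in the seed-derivation sequence.
STAGES = ("simulate", "fit", "chronology", "climate", "compare")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed.

    Uses ``numpy.random.SeedSequence([global_seed, stage_index])`` so stages
    can be re-run standalone with the same stream they get inside a full run.
    """
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    fish_csv: str | None = None
    increments_csv: str | None = None
    temperature_csv: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    params: GenerativeParams = field(default_factory=GenerativeParams)
    model: GrowthModelSpec = field(default_factory=GrowthModelSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    compare: list[str] = field(default_factory=list)  # e.g. ["sex"]
    correlation_draws: int = 1000
    correlation_method: str = "pearson"
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, klass in (
            ("cohort", CohortConfig),
            ("params", GenerativeParams),
            ("model", GrowthModelSpec),
            ("sampler", SamplerConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if key == "params":
                    # YAML mappings with tuple keys are awkward; accept
                    # "env group" string keys for rho
                    if "rho" in sub and isinstance(sub["rho"], dict):
                        sub["rho"] = {
                            tuple(k.split()) if isinstance(k, str) else tuple(k): v
                            for k, v in sub["rho"].items()
                        }
                for tup_key in ("capture_years", "sea_age_probs", "marginal_fraction_range"):
                    if tup_key in sub and isinstance(sub[tup_key], list):
                        sub[tup_key] = tuple(sub[tup_key])
                kwargs[key] = klass(**sub)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown run-config key(s): {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {(" ".join(map(str, k)) if isinstance(k, tuple) else k): convert(v)
                        for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: convert(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _prepare_data(config: RunConfig, out: Path):
    if config.simulate:
        seed = stage_seed(config.seed, "simulate")
        log.info("simulating cohort (seed %d)", seed)
        dataset, temperature, year_effects = generate_cohort(
            config.cohort, config.params, seed
        )
        year_effects.to_csv(out / "true_year_effects.csv", index=False)
    else:
        if not (config.fish_csv and config.increments_csv and config.temperature_csv):
            raise ValueError("non-simulated run needs fish_csv, increments_csv, temperature_csv")
        dataset = read_increment_csv(config.increments_csv, config.fish_csv)
        temperature = read_temperature_csv(config.temperature_csv)
        if "growth_year" not in dataset.increments.columns:
            dataset.increments = assign_growth_years(dataset.fish, dataset.increments)
    validate_dataset(dataset, capture_years=config.cohort.capture_years)
    temperature.to_csv(out / "temperature.csv", index=False)
    write_increment_csv(dataset, out / "increments.csv", out / "fish.csv")
    return dataset, temperature


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; return the output directory.

    Stages: (1) simulate or load + validate; (2) exclusion and filtering
    with provenance counts; (3) calibration OLS; (4) optional DIC term
    comparisons; (5) growth-model fit; (6) chronology, variance partition
    and plasticity test; (7) temperature correlations; (8) figures.
    Any stage failure aborts with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))

    try:
        stage = "data"
        dataset, temperature = _prepare_data(config, out)

        stage = "filtering"
        dataset = exclude_rare_life_histories(dataset)
        dataset = filter_increments(dataset)
        validate_dataset(dataset, filtered=True)
        log.info("provenance: %s", dataset.provenance)
        (out / "provenance.json").write_text(json.dumps(dataset.provenance, indent=2))

        stage = "calibration"
        cal_rows = []
        for predictor in ("radius", "circuli"):
            fitres = calib.fit_calibration(dataset.fish, predictor)
            coeffs = fitres.coefficients.copy()
            coeffs.insert(0, "predictor", predictor)
            coeffs["r_squared"] = fitres.r_squared
            cal_rows.append(coeffs)
        import pandas as pd

        pd.concat(cal_rows, ignore_index=True).to_csv(out / "calibration.csv", index=False)

        stage = "model comparison"
        if config.compare:
            comparison = compare_terms(
                dataset, config.model, config.compare, config.sampler,
                seed=stage_seed(config.seed, "compare"),
            )
            comparison.table.to_csv(out / "model_comparison.csv", index=False)
            for _, row in comparison.table.iterrows():
                if row["model"] != "base":
                    log.info(
                        "delta-DIC %s: %.2f -> %s", row["model"], row["delta_dic"],
                        "supported" if row["supported"] else "not supported",
                    )

        stage = "model fit"
        design = build_design(dataset, config.model)
        samples = fit(design, config.model, config.sampler, seed=stage_seed(config.seed, "fit"))
        samples.save(out / "posterior.npz")
        samples.fixed_effects_summary().to_csv(out / "fixed_effects.csv", index=False)
        samples.sd_summary().to_csv(out / "random_effect_sds.csv", index=False)
        model_dic, model_pd = dic(samples, design)
        log.info("DIC %.1f (pD %.1f)", model_dic, model_pd)

        stage = "chronology"
        chronology = chron.extract_chronology(samples)
        chronology.table.to_csv(out / "chronology.csv", index=False)
        partition = chron.variance_partition(samples)
        partition.table.to_csv(out / "variance_partition.csv", index=False)
        plasticity = chron.fish_plasticity_test(samples, design=design)
        (out / "plasticity_test.json").write_text(
            json.dumps(dataclasses.asdict(plasticity), indent=2)
        )

        stage = "climate"
        results = []
        for env in ("freshwater", "sea"):
            for group in ("wild", "hatchery"):
                results.append(
                    clim.monte_carlo_correlation(
                        chronology, temperature, group, env,
                        n_draws=config.correlation_draws,
                        seed=stage_seed(config.seed, "climate"),
                        method=config.correlation_method,
                    )
                )
        clim.correlation_report(results).to_csv(out / "correlations.csv", index=False)

        stage = "figures"
        if config.make_figures:
            clim.plot_correlations(results, out / "correlations.png")
            _plot_chronology(chronology, out / "chronology.png")
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _plot_chronology(chronology: chron.ChronologyIndex, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for ax, env in zip(axes, ("freshwater", "sea")):
        for group, color in (("wild", "tab:blue"), ("hatchery", "tab:orange")):
            sub = chronology.stratum(group, env)
            ax.errorbar(sub["year"], sub["mean"], yerr=sub["sd"], label=group,
                        color=color, marker="o", ms=3, capsize=2)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_ylabel(f"{env}\nyear effect (log μm)")
        ax.legend(frameon=False, fontsize=8)
    axes[-1].set_xlabel("growth year")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
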