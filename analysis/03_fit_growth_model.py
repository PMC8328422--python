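"""Fit the Bayesian growth model and test model terms by DIC.

Loads the filtered increment data, fits the crossed-random-intercepts model
of log increment width (age x group fixed effects; fish and
group:environment:year random intercepts; PC priors on the random-effect
SDs), and runs the delta-DIC > 2 term-support comparison for sex — which,
as in the data the generator emulates, carries no signal and is dropped.

Reads results/data/; writes results/posterior.npz, fixed_effects.csv,
random_effect_sds.csv, model_comparison.csv.
"""

import argparse
from pathlib import Path

from scalechron import (
    GrowthModelSpec,
    SamplerConfig,
    build_design,
    compare_terms,
    dic,
    exclude_rare_life_histories,
    filter_increments,
    fit,
    read_increment_csv,
    validate_dataset,
)
from scalechron.experiments import derive_seed


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--draws", type=int, default=1250)
    parser.add_argument("--burnin", type=int, default=600)
    args = parser.parse_args()

    data = args.out / "data"
    dataset = read_increment_csv(data / "increments.csv", data / "fish.csv")
    dataset = filter_increments(exclude_rare_life_histories(dataset))
    validate_dataset(dataset, filtered=True)

    cfg = SamplerConfig(draws=args.draws, burnin=args.burnin, chains=2)
    spec = GrowthModelSpec()

    comparison = compare_terms(
        dataset, GrowthModelSpec(include_sex=True), ["sex"],
        SamplerConfig(draws=1000, burnin=500, chains=2), seed=derive_seed(args.seed, 10),
    )
    comparison.table.to_csv(args.out / "model_comparison.csv", index=False)
    row = comparison.table.set_index("model").loc["-sex"]
    se = (comparison.table["dic_se"] ** 2).sum() ** 0.5
    print(f"sex term: delta-DIC = {row['delta_dic']:.2f} (MC se ~{se:.2f}) -> "
          f"{'supported' if row['supported'] else 'not supported'} by the >2 rule; "
          "the main model drops sex")

    design = build_design(dataset, spec)
    samples = fit(design, spec, cfg, seed=derive_seed(args.seed, 1))
    samples.save(args.out / "posterior.npz")
    samples.fixed_effects_summary().to_csv(args.out / "fixed_effects.csv", index=False)
    samples.sd_summary().to_csv(args.out / "random_effect_sds.csv", index=False)

    model_dic, p_d = dic(samples, design)
    print(f"fitted {design.n} increments / {design.n_fish} fish / "
          f"{design.n_cells} year cells; DIC = {model_dic:.1f} (pD = {p_d:.1f})")
    print("R-hat:", {k: round(v, 3) for k, v in samples.diagnostics.items()})
    print(samples.fixed_effects_summary().round(3).to_string(index=False))
    print(samples.sd_summary().round(4).to_string(index=False))


if __name__ == "__main__":
    main()
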