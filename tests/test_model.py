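import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from scalechron import (
    CohortConfig,
    GenerativeParams,
    GrowthModelSpec,
    PriorSpec,
    SamplerConfig,
    build_design,
    compare_terms,
    dic,
    exclude_rare_life_histories,
    filter_increments,
    fit,
    generate_cohort,
    pc_prior_logdensity,
    prior_sensitivity,
)
from scalechron.model import ModelError, conditional_posterior_mean


def _small_dataset(n_fish=40, seed=3, **params_kw):
    ds, _, _ = generate_cohort(
        CohortConfig(n_fish=n_fish, rare_life_histories={}),
        GenerativeParams(**params_kw),
        seed=seed,
    )
    return filter_increments(exclude_rare_life_histories(ds))


class TestDesign:
    def test_dummy_coding_references(self, small_filtered):
        dataset, _, _ = small_filtered
        design = build_design(dataset, GrowthModelSpec())
        inc = dataset.increments.reset_index(drop=True)
        names = design.coef_names
        # wild SW1 row activates {SW1, Wild, SW1:Wild}; hatchery FW1 is intercept-only
        wild_sw1 = inc.index[(inc["group"] == "wild") & (inc["age_class"] == "SW1")][0]
        row = dict(zip(names, design.X[wild_sw1]))
        assert row["SW1"] == 1 and row["Wild"] == 1 and row["SW1:Wild"] == 1
        assert row["FW2"] == 0 and row["SW2"] == 0
        hat_fw1 = inc.index[(inc["group"] == "hatchery") & (inc["age_class"] == "FW1")][0]
        assert design.X[hat_fw1].sum() == 1.0  # intercept only

    def test_full_design_shape_at_study_composition(self, default_cohort):
        dataset, _, _ = default_cohort
        dataset = filter_increments(exclude_rare_life_histories(dataset))
        design = build_design(dataset, GrowthModelSpec())
        assert design.p == 10
        assert design.n_fish == 1596
        # 2 groups x 2 environments x observed years; sea years 2004-2015,
        # freshwater years 2003-2014 under the anchoring convention
        assert 40 <= design.n_cells <= 52
        assert design.coef_names[0] == "Intercept"
        assert set(design.coef_names) == {
            "Intercept", "FW2", "SW1", "SW2", "SW3", "Wild",
            "FW2:Wild", "SW1:Wild", "SW2:Wild", "SW3:Wild",
        }

    def test_response_is_log_width(self, small_filtered):
        dataset, _, _ = small_filtered
        design = build_design(dataset, GrowthModelSpec())
        np.testing.assert_allclose(
            design.y, np.log(dataset.increments["width_um"].to_numpy())
        )

    def test_unfiltered_dataset_rejected(self, default_cohort):
        dataset, _, _ = default_cohort
        with pytest.raises(ModelError, match="filtered"):
            build_design(dataset, GrowthModelSpec())


class TestPcPrior:
    def test_tail_probability_is_alpha(self):
        for U, alpha in [(1.0, 0.01), (0.5, 0.1), (3.0, 0.05)]:
            tail, _ = quad(lambda s: np.exp(pc_prior_logdensity(s, U, alpha)), U, np.inf)
            assert tail == pytest.approx(alpha, rel=1e-6)

    def test_rate_and_origin_density(self):
        lam = -np.log(0.01) / 1.0
        assert lam == pytest.approx(4.6052, abs=1e-4)
        assert np.exp(pc_prior_logdensity(0.0, 1.0, 0.01)) == pytest.approx(lam)

    def test_domain_violations(self):
        with pytest.raises(ModelError):
            pc_prior_logdensity(-0.1, 1.0, 0.01)
        with pytest.raises(ModelError):
            pc_prior_logdensity(0.5, 1.0, 1.5)
        with pytest.raises(ModelError):
            pc_prior_logdensity(0.5, -1.0, 0.01)


class TestOracle:
    """Frozen-variance conditional means must equal the mixed-model-equations
    (GLS/BLUP) solution built densely and independently."""

    def test_matches_dense_normal_equations(self):
        dataset = _small_dataset(n_fish=40)
        design = build_design(dataset, GrowthModelSpec())
        assert design.n <= 200
        so, sf, sy, bsd = 0.15, 0.06, 0.07, 100.0
        beta, u_f, u_y = conditional_posterior_mean(design, so, sf, sy, bsd)

        n, p, F, C = design.n, design.p, design.n_fish, design.n_cells
        Zf = np.zeros((n, F)); Zf[np.arange(n), design.fish_idx] = 1.0
        Zy = np.zeros((n, C)); Zy[np.arange(n), design.cell_idx] = 1.0
        W = np.hstack([design.X, Zy, Zf])
        prec = np.concatenate(
            [np.full(p, bsd**-2), np.full(C, sy**-2), np.full(F, sf**-2)]
        )
        A = W.T @ W / so**2 + np.diag(prec)
        sol = np.linalg.solve(A, W.T @ design.y / so**2)
        ref = np.concatenate([beta, u_y, u_f])
        np.testing.assert_allclose(sol, ref, rtol=1e-6, atol=1e-9)

    def test_sampler_centres_on_oracle_with_fixed_variances(self):
        dataset = _small_dataset(n_fish=30, seed=9)
        spec = GrowthModelSpec(
            prior_obs=PriorSpec.fixed(0.155),
            prior_fish=PriorSpec.fixed(0.058),
            prior_year=PriorSpec.fixed(0.065),
        )
        design = build_design(dataset, spec)
        samples = fit(design, spec, SamplerConfig(draws=2000, burnin=10, chains=1), seed=4)
        beta_hat, _, _ = conditional_posterior_mean(design, 0.155, 0.058, 0.065)
        mc_sd = samples.beta.std(axis=0, ddof=1) / np.sqrt(samples.n_draws)
        # draws are iid here, so a 4-sigma MC band is an honest check
        np.testing.assert_array_less(
            np.abs(samples.beta.mean(axis=0) - beta_hat), 4.5 * mc_sd + 1e-12
        )
        assert np.all(samples.sigma_obs == 0.155)


class TestFit:
    def test_seeded_determinism(self, small_filtered):
        dataset, _, _ = small_filtered
        spec = GrowthModelSpec()
        design = build_design(dataset, spec)
        cfg = SamplerConfig(draws=50, burnin=20, chains=2)
        a = fit(design, spec, cfg, seed=1)
        b = fit(design, spec, cfg, seed=1)
        c = fit(design, spec, cfg, seed=2)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.sigma_year, b.sigma_year)
        assert not np.array_equal(a.beta, c.beta)

    def test_scale_equivariance(self, small_filtered):
        """Multiplying widths by c shifts only the intercept, by ln(c)."""
        dataset, _, _ = small_filtered
        scaled = dataset.copy()
        c = 10.0
        scaled.increments["width_um"] = scaled.increments["width_um"] * c
        spec = GrowthModelSpec()
        cfg = SamplerConfig(draws=200, burnin=100, chains=1)
        base = fit(build_design(dataset, spec), spec, cfg, seed=5)
        shifted = fit(build_design(scaled, spec), spec, cfg, seed=5)
        delta = shifted.beta.mean(axis=0) - base.beta.mean(axis=0)
        names = base.coef_names
        assert delta[names.index("Intercept")] == pytest.approx(np.log(c), abs=1e-3)
        for i, name in enumerate(names):
            if name != "Intercept":
                assert abs(delta[i]) < 1e-3
        assert np.allclose(shifted.sigma_obs, base.sigma_obs, atol=1e-6)

    def test_dropped_fish_term_collapses_gracefully(self, small_filtered):
        dataset, _, _ = small_filtered
        spec = GrowthModelSpec().drop("fish")
        design = build_design(dataset, spec)
        assert design.n_fish == 0
        samples = fit(design, spec, SamplerConfig(draws=50, burnin=20, chains=1), seed=6)
        assert samples.u_fish.shape == (50, 0)

    def test_posterior_round_trip(self, tmp_path, small_filtered):
        dataset, _, _ = small_filtered
        spec = GrowthModelSpec()
        design = build_design(dataset, spec)
        samples = fit(design, spec, SamplerConfig(draws=30, burnin=10, chains=2), seed=7)
        samples.save(tmp_path / "post.npz")
        from scalechron import PosteriorSamples

        back = PosteriorSamples.load(tmp_path / "post.npz")
        np.testing.assert_array_equal(back.beta, samples.beta)
        assert back.cells == samples.cells
        assert back.coef_names == samples.coef_names

    def test_credible_interval_coverage(self):
        """95% intervals cover the generative fixed effects at a compatible rate."""
        truth = GenerativeParams()
        names_to_truth = dict(truth.beta)
        covered = total = 0
        for rep in range(20):
            ds, _, _ = generate_cohort(
                CohortConfig(n_fish=150, rare_life_histories={}), truth, seed=100 + rep
            )
            ds = filter_increments(exclude_rare_life_histories(ds))
            spec = GrowthModelSpec()
            design = build_design(ds, spec)
            samples = fit(design, spec, SamplerConfig(draws=400, burnin=200, chains=1),
                          seed=200 + rep)
            summary = samples.fixed_effects_summary().set_index("coefficient")
            for name, true_val in names_to_truth.items():
                key = "Intercept" if name == "Intercept" else name
                if key not in summary.index:
                    continue
                row = summary.loc[key]
                total += 1
                covered += int(row["q2.5"] <= true_val <= row["q97.5"])
        # binomial(total, 0.95) with within-replicate correlation: generous band
        assert covered / total >= 0.85


class TestDic:
    def test_matches_naive_per_draw_computation(self, small_filtered):
        dataset, _, _ = small_filtered
        spec = GrowthModelSpec()
        design = build_design(dataset, spec)
        samples = fit(design, spec, SamplerConfig(draws=60, burnin=30, chains=1), seed=8)
        got_dic, got_pd = dic(samples, design)

        # independent naive recomputation, draw by draw
        devs = []
        for d in range(samples.n_draws):
            eta = design.X @ samples.beta[d]
            eta += samples.u_year[d][design.cell_idx]
            eta += samples.u_fish[d][design.fish_idx]
            s2 = samples.sigma_obs[d] ** 2
            devs.append(
                design.n * np.log(2 * np.pi * s2) + ((design.y - eta) ** 2).sum() / s2
            )
        dbar = np.mean(devs)
        eta_hat = (
            design.X @ samples.beta.mean(axis=0)
            + samples.u_year.mean(axis=0)[design.cell_idx]
            + samples.u_fish.mean(axis=0)[design.fish_idx]
        )
        s2_hat = samples.sigma_obs.mean() ** 2
        d_hat = design.n * np.log(2 * np.pi * s2_hat) + ((design.y - eta_hat) ** 2).sum() / s2_hat
        assert got_pd == pytest.approx(dbar - d_hat, rel=1e-10)
        assert got_dic == pytest.approx(2 * dbar - d_hat, rel=1e-10)

    def test_duplicated_data_doubles_deviance(self, small_filtered):
        dataset, _, _ = small_filtered
        spec = GrowthModelSpec()
        design = build_design(dataset, spec)
        samples = fit(design, spec, SamplerConfig(draws=40, burnin=20, chains=1), seed=9)
        doubled = dataset.copy()
        doubled.increments = pd.concat(
            [dataset.increments, dataset.increments], ignore_index=True
        )
        design2 = build_design(doubled, spec)
        dic1, pd1 = dic(samples, design)
        dic2, pd2 = dic(samples, design2)
        assert dic2 == pytest.approx(2 * dic1, rel=1e-10)
        assert pd2 == pytest.approx(2 * pd1, rel=1e-10)

    def test_effective_parameters_of_fixed_effect_only_model(self):
        """With sigma_obs frozen and no random effects, pD ~ number of betas."""
        dataset = _small_dataset(n_fish=60, seed=12)
        spec = GrowthModelSpec(
            include_fish=False,
            include_year=False,
            prior_obs=PriorSpec.fixed(0.155),
        )
        design = build_design(dataset, spec)
        samples = fit(design, spec, SamplerConfig(draws=4000, burnin=10, chains=1), seed=13)
        _, p_d = dic(samples, design)
        assert p_d == pytest.approx(design.p, rel=0.25)

    def test_too_few_draws_rejected(self, small_filtered):
        dataset, _, _ = small_filtered
        spec = GrowthModelSpec()
        design = build_design(dataset, spec)
        samples = fit(design, spec, SamplerConfig(draws=10, burnin=5, chains=1), seed=1)
        samples.beta = samples.beta[:1]
        samples.sigma_obs = samples.sigma_obs[:1]
        with pytest.raises(ModelError):
            dic(samples, design)


class TestModelComparison:
    def test_age_supported_sex_not(self):
        """Planted age signal is supported; absent sex signal is not."""
        ds = _small_dataset(n_fish=120, seed=20)
        cfg = SamplerConfig(draws=300, burnin=150, chains=1)
        base = GrowthModelSpec(include_sex=True)
        comparison = compare_terms(ds, base, ["age", "sex"], cfg, seed=21)
        assert comparison.supported("age")
        assert not comparison.supported("sex")
        tbl = comparison.table.set_index("model")
        assert tbl.loc["-age", "delta_dic"] > 2
        assert tbl.loc["-sex", "delta_dic"] < 2

    def test_unknown_term_rejected(self, small_filtered):
        dataset, _, _ = small_filtered
        with pytest.raises(ModelError, match="droppable"):
            GrowthModelSpec().drop("nonsense")


class TestPriorSensitivity:
    def test_fixed_effects_insensitive_at_moderate_n(self):
        ds = _small_dataset(n_fish=200, seed=30)
        cfg = SamplerConfig(draws=300, burnin=150, chains=1)
        table = prior_sensitivity(
            ds, GrowthModelSpec(), ["pc", "half_cauchy", "inv_gamma_default"], cfg, seed=31
        )
        fixed = table[~table["parameter"].str.startswith("sd_")]
        assert fixed["max_abs_diff"].max() < 0.08
        assert set(table["family"]) == {"pc", "half_cauchy", "inv_gamma_default"}

    def test_single_family_table(self, small_filtered):
        dataset, _, _ = small_filtered
        cfg = SamplerConfig(draws=100, burnin=50, chains=1)
        table = prior_sensitivity(dataset, GrowthModelSpec(), ["pc"], cfg, seed=32)
        assert set(table["family"]) == {"pc"}
        assert (table["max_abs_diff"] == 0).all()
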