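"""Bayesian Gaussian mixed model of log increment width.

The model has crossed random intercepts,

    log w_i = x_i' beta + u_fish[f(i)] + u_year[c(i)] + eps_i,
    eps_i ~ N(0, sigma_obs^2),   u_fish ~ N(0, sigma_fish^2),
    u_year ~ N(0, sigma_year^2),

where ``f(i)`` indexes the fish and ``c(i)`` the group:environment:year cell
of increment ``i``.  Fixed effects are age class (FW1 reference), group
(hatchery reference), their interaction, and optionally sex.

Inference is a blocked Gibbs sampler.  Given the three variance components,
(beta, u_year, u_fish) has a multivariate normal full conditional (the
mixed-model normal equations); we draw from it exactly by sampling
(beta, u_year) from its marginal — the fish block, being diagonal, is folded
in by a Schur complement — and then the fish intercepts from their diagonal
conditional.  Given the effects, each variance is updated conjugately
(gamma prior on the precision) or by univariate slice sampling (penalized
complexity and half-Cauchy priors on the standard deviation).

Fixed effects carry independent zero-mean normal priors with a large SD
(default 100 on the log scale), so their posterior is data-dominated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .data import AnalysisDataset

AGE_LEVELS = ("FW1", "FW2", "SW1", "SW2", "SW3")  # FW1 is the reference


class ModelError(ValueError):
    """Raised for invalid designs or sampler misuse."""


# ---------------------------------------------------------------------------
# Priors on variance components


@dataclass(frozen=True)
class PriorSpec:
    """Prior on one variance component.

    family:
      - ``"pc"``: penalized-complexity prior, exponential on the SD with
        rate ``-ln(alpha)/U`` so that P(sigma > U) = alpha
        (params: ``U``, ``alpha``);
      - ``"half_cauchy"``: half-Cauchy on the SD (params: ``scale``);
      - ``"inv_gamma_default"``: gamma on the precision (params: ``shape``,
        ``rate``), the conventional weakly-informative default
        (shape 1, rate 5e-5);
      - ``"fixed"``: the SD is held at ``value`` (degenerate prior; used by
        the exact-oracle checks).
    """

    family: str = "pc"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("pc", "half_cauchy", "inv_gamma_default", "fixed"):
            raise ModelError(f"unknown prior family {self.family!r}")

    @staticmethod
    def pc(U: float = 1.0, alpha: float = 0.01) -> "PriorSpec":
        return PriorSpec("pc", {"U": U, "alpha": alpha})

    @staticmethod
    def half_cauchy(scale: float = 1.0) -> "PriorSpec":
        return PriorSpec("half_cauchy", {"scale": scale})

    @staticmethod
    def inv_gamma_default(shape: float = 1.0, rate: float = 5e-5) -> "PriorSpec":
        return PriorSpec("inv_gamma_default", {"shape": shape, "rate": rate})

    @staticmethod
    def fixed(value: float) -> "PriorSpec":
        return PriorSpec("fixed", {"value": value})


def pc_prior_logdensity(sigma: float, U: float, alpha: float) -> float:
    """Log density of the PC prior for a random-effect SD.

    Exponential with rate ``lambda = -ln(alpha)/U``, the penalized-complexity
    prior for a Gaussian random-effect standard deviation, calibrated so that
    P(sigma > U) = alpha.
    """
    if sigma < 0:
        raise ModelError("sigma must be >= 0")
    if U <= 0 or not (0.0 < alpha < 1.0):
        raise ModelError("require U > 0 and 0 < alpha < 1")
    lam = -np.log(alpha) / U
    return float(np.log(lam) - lam * sigma)


def _log_prior_sd(sigma: float, prior: PriorSpec) -> float:
    """Unnormalised log prior density of the SD for slice sampling."""
    if prior.family == "pc":
        return pc_prior_logdensity(sigma, prior.params.get("U", 1.0), prior.params.get("alpha", 0.01))
    if prior.family == "half_cauchy":
        s = prior.params.get("scale", 1.0)
        return float(-np.log1p((sigma / s) ** 2))
    raise ModelError(f"no slice-sampling density for family {prior.family!r}")


def _slice_sample_log_sigma(
    x0: float, k: int, ss: float, prior: PriorSpec, rng: np.random.Generator,
    w: float = 0.5, max_steps: int = 50,
) -> float:
    """One slice-sampling update of x = log(sigma) given sum of squares ``ss``
    of ``k`` effects, using stepping-out and shrinkage."""

    def logpost(x: float) -> float:
        sigma = np.exp(x)
        # Gaussian likelihood of k effects + prior on sigma + log-Jacobian
        return -k * x - ss / (2.0 * sigma**2) + _log_prior_sd(sigma, prior) + x

    y = logpost(x0) - rng.exponential()
    lo = x0 - w * rng.random()
    hi = lo + w
    j = int(max_steps * rng.random())
    m = max_steps - 1 - j
    while j > 0 and logpost(lo) > y:
        lo -= w
        j -= 1
    while m > 0 and logpost(hi) > y:
        hi += w
        m -= 1
    for _ in range(200):
        x1 = lo + (hi - lo) * rng.random()
        if logpost(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pathological slice; keep the current value


def _update_sigma(
    sigma: float, k: int, ss: float, prior: PriorSpec, rng: np.random.Generator
) -> float:
    if prior.family == "fixed":
        return float(prior.params["value"])
    if k == 0:
        # no levels observed: draw from the prior itself
        if prior.family == "inv_gamma_default":
            tau = rng.gamma(prior.params.get("shape", 1.0), 1.0 / prior.params.get("rate", 5e-5))
            return float(1.0 / np.sqrt(tau))
        return float(np.exp(_slice_sample_log_sigma(np.log(max(sigma, 1e-3)), 0, 0.0, prior, rng)))
    if prior.family == "inv_gamma_default":
        shape = prior.params.get("shape", 1.0) + 0.5 * k
        rate = prior.params.get("rate", 5e-5) + 0.5 * ss
        tau = rng.gamma(shape, 1.0 / rate)
        return float(1.0 / np.sqrt(tau))
    x = _slice_sample_log_sigma(np.log(max(sigma, 1e-8)), k, ss, prior, rng)
    return float(np.exp(x))


# ---------------------------------------------------------------------------
# Model specification and design


@dataclass(frozen=True)
class GrowthModelSpec:
    """Fixed/random structure and priors of the growth model.

    The full default reproduces the selected model: age + group +
    age x group fixed effects, fish and group:environment:year random
    intercepts, PC priors on the random-effect SDs and the conventional
    gamma-on-precision default on the observation noise.
    """

    include_age: bool = True
    include_group: bool = True
    include_interaction: bool = True
    include_sex: bool = False
    include_fish: bool = True
    include_year: bool = True
    prior_obs: PriorSpec = field(default_factory=PriorSpec.inv_gamma_default)
    prior_fish: PriorSpec = field(default_factory=PriorSpec.pc)
    prior_year: PriorSpec = field(default_factory=PriorSpec.pc)
    beta_prior_sd: float = 100.0

    def drop(self, term: str) -> "GrowthModelSpec":
        """Return a copy with one term removed (for DIC comparisons)."""
        mapping = {
            "sex": {"include_sex": False},
            "interaction": {"include_interaction": False},
            "age": {"include_age": False, "include_interaction": False},
            "group": {"include_group": False, "include_interaction": False},
            "fish": {"include_fish": False},
            "year": {"include_year": False},
        }
        if term not in mapping:
            raise ModelError(f"unknown droppable term {term!r}")
        return replace(self, **mapping[term])

    def with_priors(self, family: str) -> "GrowthModelSpec":
        """Copy with the given family on all three variance components."""
        builders = {
            "pc": PriorSpec.pc,
            "half_cauchy": PriorSpec.half_cauchy,
            "inv_gamma_default": PriorSpec.inv_gamma_default,
        }
        if family not in builders:
            raise ModelError(f"unknown prior family {family!r}")
        p = builders[family]()
        return replace(self, prior_obs=p, prior_fish=p, prior_year=p)


@dataclass
class Design:
    """Numeric design: response, fixed matrix and random-effect index maps."""

    y: np.ndarray  # log width, length n
    X: np.ndarray  # (n, p)
    coef_names: list[str]
    fish_idx: np.ndarray  # (n,) int, -1-free indices into fish_ids
    fish_ids: list[str]
    cell_idx: np.ndarray  # (n,) int indices into cells
    cells: list[tuple]  # (group, environment, year)
    fish_groups: pd.Series  # fish_id -> group, for downstream tests

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def build_design(dataset: AnalysisDataset, spec: GrowthModelSpec) -> Design:
    """Build the design from a *filtered* dataset.

    The response is natural-log increment width (micrometres).  Dummy coding
    uses FW1, hatchery and female as references, so the intercept is the
    hatchery FW1 baseline on the log-um scale.
    """
    inc = dataset.increments
    if inc["is_marginal"].any() or inc["is_spawning_zone"].any():
        raise ModelError("design requires a filtered dataset (marginal/spawning zones present)")
    if "growth_year" not in inc.columns or "environment" not in inc.columns:
        raise ModelError("increments must be calendar-anchored (run assign_growth_years)")
    if (inc["width_um"] <= 0).any():
        raise ModelError("non-positive increment width in design input")
    unknown = set(inc["age_class"]) - set(AGE_LEVELS)
    if unknown:
        raise ModelError(f"unknown age_class {sorted(unknown)} in design input")

    n = len(inc)
    y = np.log(inc["width_um"].to_numpy(float))

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    age = inc["age_class"].to_numpy()
    wild = (inc["group"].to_numpy() == "wild").astype(float)
    if spec.include_age:
        for level in AGE_LEVELS[1:]:
            if (age == level).any():
                cols.append((age == level).astype(float))
                names.append(level)
    if spec.include_group:
        cols.append(wild)
        names.append("Wild")
    if spec.include_interaction:
        if not (spec.include_age and spec.include_group):
            raise ModelError("interaction requires both age and group main effects")
        for level in AGE_LEVELS[1:]:
            col = (age == level).astype(float) * wild
            if col.any():
                cols.append(col)
                names.append(f"{level}:Wild")
    if spec.include_sex:
        cols.append((inc["sex"].to_numpy() == "male").astype(float))
        names.append("Male")
    X = np.column_stack(cols)

    if spec.include_fish:
        fish_ids = sorted(inc["fish_id"].unique())
        fish_map = {f: i for i, f in enumerate(fish_ids)}
        fish_idx = inc["fish_id"].map(fish_map).to_numpy(int)
    else:
        fish_ids, fish_idx = [], np.full(n, -1, dtype=int)

    if spec.include_year:
        cell_frame = inc[["group", "environment", "growth_year"]]
        cells = sorted(set(map(tuple, cell_frame.itertuples(index=False))))
        cell_map = {c: i for i, c in enumerate(cells)}
        cell_idx = np.array([cell_map[t] for t in map(tuple, cell_frame.itertuples(index=False))])
    else:
        cells, cell_idx = [], np.full(n, -1, dtype=int)

    fish_groups = dataset.fish.set_index("fish_id")["group"]
    return Design(y, X, names, fish_idx, fish_ids, cell_idx, cells, fish_groups)


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class PosteriorSamples:
    """Joint posterior draws with named coefficient/level metadata.

    Arrays are stacked over chains: shape (n_draws_total, dim).  ``chain``
    labels each draw's chain for split-chain diagnostics.
    """

    beta: np.ndarray
    u_fish: np.ndarray
    u_year: np.ndarray
    sigma_obs: np.ndarray
    sigma_fish: np.ndarray
    sigma_year: np.ndarray
    coef_names: list[str]
    fish_ids: list[str]
    cells: list[tuple]
    chain: np.ndarray
    meta: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.sigma_obs)

    def fixed_effects_summary(self) -> pd.DataFrame:
        """Posterior mean and central 95% interval per fixed effect."""
        lo, hi = np.percentile(self.beta, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "coefficient": self.coef_names,
                "mean": self.beta.mean(axis=0),
                "sd": self.beta.std(axis=0, ddof=1),
                "q2.5": lo,
                "q97.5": hi,
            }
        )

    def sd_summary(self) -> pd.DataFrame:
        rows = []
        for name, draws in (
            ("observation", self.sigma_obs),
            ("fish", self.sigma_fish),
            ("year", self.sigma_year),
        ):
            rows.append(
                {
                    "component": name,
                    "mean": float(np.mean(draws)),
                    "sd": float(np.std(draws, ddof=1)),
                    "q2.5": float(np.percentile(draws, 2.5)),
                    "q97.5": float(np.percentile(draws, 97.5)),
                }
            )
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        """Serialize to a .npz container with named arrays."""
        np.savez_compressed(
            path,
            beta=self.beta,
            u_fish=self.u_fish,
            u_year=self.u_year,
            sigma_obs=self.sigma_obs,
            sigma_fish=self.sigma_fish,
            sigma_year=self.sigma_year,
            chain=self.chain,
            coef_names=np.array(self.coef_names),
            fish_ids=np.array(self.fish_ids),
            cells=np.array([[str(g), str(e), str(y)] for g, e, y in self.cells]),
            meta=np.array([repr(self.meta)]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        import ast

        z = np.load(path, allow_pickle=False)
        cells = [(g, e, int(y)) for g, e, y in z["cells"]] if z["cells"].size else []
        return cls(
            beta=z["beta"],
            u_fish=z["u_fish"],
            u_year=z["u_year"],
            sigma_obs=z["sigma_obs"],
            sigma_fish=z["sigma_fish"],
            sigma_year=z["sigma_year"],
            coef_names=list(z["coef_names"]),
            fish_ids=list(z["fish_ids"]),
            cells=cells,
            chain=z["chain"],
            meta=ast.literal_eval(str(z["meta"][0])),
        )

    def to_inference_data(self):
        """Hyperparameter draws as an arviz InferenceData (for diagnostics)."""
        import arviz as az

        chains = np.unique(self.chain)
        per = min((self.chain == c).sum() for c in chains)

        def stack(x: np.ndarray) -> np.ndarray:
            return np.stack([x[self.chain == c][:per] for c in chains])

        return az.from_dict(
            posterior={
                "sigma_obs": stack(self.sigma_obs),
                "sigma_fish": stack(self.sigma_fish),
                "sigma_year": stack(self.sigma_year),
                "beta": stack(self.beta),
            }
        )


# ---------------------------------------------------------------------------
# Sampler


@dataclass(frozen=True)
class SamplerConfig:
    draws: int = 1000  # post-burn-in draws per chain
    burnin: int = 500
    thin: int = 1
    chains: int = 2
    rhat_warn: float = 1.01


class _Precompute:
    """Sufficient statistics of the design that do not change across draws."""

    def __init__(self, design: Design):
        X, y = design.X, design.y
        n, p = X.shape
        F, C = design.n_fish, design.n_cells
        self.n, self.p, self.F, self.C = n, p, F, C
        self.q = p + C  # dimension of the (beta, u_year) block

        XtX = X.T @ X
        if C > 0:
            XtZy = np.zeros((p, C))
            np.add.at(XtZy.T, design.cell_idx, X)
            n_c = np.bincount(design.cell_idx, minlength=C).astype(float)
            Zy_y = np.bincount(design.cell_idx, weights=y, minlength=C)
        else:
            XtZy = np.zeros((p, 0))
            n_c = np.zeros(0)
            Zy_y = np.zeros(0)
        self.A_tt = np.zeros((self.q, self.q))
        self.A_tt[:p, :p] = XtX
        self.A_tt[:p, p:] = XtZy
        self.A_tt[p:, :p] = XtZy.T
        self.A_tt[p:, p:] = np.diag(n_c)

        if F > 0:
            XtZf = np.zeros((p, F))
            np.add.at(XtZf.T, design.fish_idx, X)
            self.n_f = np.bincount(design.fish_idx, minlength=F).astype(float)
            self.Zf_y = np.bincount(design.fish_idx, weights=y, minlength=F)
            if C > 0:
                ZyZf = np.zeros((C, F))
                np.add.at(ZyZf, (design.cell_idx, design.fish_idx), 1.0)
            else:
                ZyZf = np.zeros((0, F))
            self.A_tf = np.vstack([XtZf, ZyZf])
        else:
            self.n_f = np.zeros(0)
            self.Zf_y = np.zeros(0)
            self.A_tf = np.zeros((self.q, 0))

        self.T_y = np.concatenate([X.T @ y, Zy_y])


def conditional_posterior_mean(
    design: Design,
    sigma_obs: float,
    sigma_fish: float,
    sigma_year: float,
    beta_prior_sd: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior mean of (beta, u_fish, u_year) with variances frozen.

    This is the ridge-penalised mixed-model-equations (GLS/BLUP) solution;
    the Gibbs sampler's full conditional is centred exactly here.
    """
    pre = _Precompute(design)
    theta, u_f, _ = _joint_draw(pre, design, sigma_obs, sigma_fish, sigma_year,
                                beta_prior_sd, rng=None)
    beta = theta[: design.p]
    u_year = theta[design.p:]
    return beta, u_f, u_year


def _joint_draw(
    pre: _Precompute,
    design: Design,
    s_obs: float,
    s_fish: float,
    s_year: float,
    beta_prior_sd: float,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact draw of (theta=(beta,u_year), u_fish) from the Gaussian full
    conditional given variances; with ``rng=None`` returns the mean."""
    s2e = s_obs**2
    prior_prec = np.concatenate(
        [
            np.full(pre.p, 1.0 / beta_prior_sd**2),
            np.full(pre.C, 1.0 / s_year**2) if pre.C else np.zeros(0),
        ]
    )
    Q_tt = pre.A_tt / s2e + np.diag(prior_prec)
    b_t = pre.T_y / s2e

    if pre.F > 0:
        q_f = pre.n_f / s2e + 1.0 / s_fish**2
        B = pre.A_tf / s2e
        S = Q_tt - (B / q_f) @ B.T
        b_f = pre.Zf_y / s2e
        rhs = b_t - B @ (b_f / q_f)
    else:
        q_f = np.zeros(0)
        B = pre.A_tf
        S = Q_tt
        b_f = np.zeros(0)
        rhs = b_t

    try:
        c, low = cho_factor(S, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ModelError(f"singular design in joint update: {exc}") from exc
    mean_t = cho_solve((c, low), rhs)
    if rng is not None:
        z = rng.standard_normal(pre.q)
        theta = mean_t + solve_triangular(c, z, lower=True, trans="T")
    else:
        theta = mean_t

    if pre.F > 0:
        mean_f = (b_f - B.T @ theta) / q_f
        if rng is not None:
            u_f = mean_f + rng.standard_normal(pre.F) / np.sqrt(q_f)
        else:
            u_f = mean_f
    else:
        u_f = np.zeros(0)
    return theta, u_f, q_f


def fit(
    design: Design,
    spec: GrowthModelSpec,
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Run the blocked Gibbs sampler and return joint posterior draws.

    Identical ``seed`` + config give bit-identical draws.  A split-chain
    R-hat above the configured threshold on any variance component emits a
    warning with the diagnostics attached to ``samples.diagnostics``.
    """
    cfg = sampler_config or SamplerConfig()
    if cfg.draws < 2:
        raise ModelError("need at least 2 post-burn-in draws")
    pre = _Precompute(design)
    if design.p > design.n:
        raise ModelError("more fixed effects than observations")

    sd_y = float(np.std(design.y)) or 1.0
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(cfg.chains)

    kept = cfg.draws // cfg.thin
    total = kept * cfg.chains
    beta_d = np.empty((total, pre.p))
    uf_d = np.empty((total, pre.F))
    uy_d = np.empty((total, pre.C))
    so_d = np.empty(total)
    sf_d = np.empty(total)
    sy_d = np.empty(total)
    chain_lbl = np.empty(total, dtype=int)

    pos = 0
    for ch, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        s_obs = sd_y if spec.prior_obs.family != "fixed" else spec.prior_obs.params["value"]
        s_fish = 0.1 * sd_y if spec.prior_fish.family != "fixed" else spec.prior_fish.params["value"]
        s_year = 0.1 * sd_y if spec.prior_year.family != "fixed" else spec.prior_year.params["value"]
        s_fish = max(s_fish, 1e-6)
        s_year = max(s_year, 1e-6)

        for it in range(cfg.burnin + cfg.draws):
            theta, u_f, _ = _joint_draw(
                pre, design, s_obs, max(s_fish, 1e-10), max(s_year, 1e-10),
                spec.beta_prior_sd, rng,
            )
            beta = theta[: pre.p]
            u_y = theta[pre.p:]

            resid = design.y - design.X @ beta
            if pre.C:
                resid = resid - u_y[design.cell_idx]
            if pre.F:
                resid = resid - u_f[design.fish_idx]
            s_obs = _update_sigma(s_obs, pre.n, float(resid @ resid), spec.prior_obs, rng)
            if spec.include_fish:
                s_fish = _update_sigma(s_fish, pre.F, float(u_f @ u_f), spec.prior_fish, rng)
            if spec.include_year:
                s_year = _update_sigma(s_year, pre.C, float(u_y @ u_y), spec.prior_year, rng)

            k = it - cfg.burnin
            if k >= 0 and k % cfg.thin == 0:
                beta_d[pos] = beta
                uf_d[pos] = u_f
                uy_d[pos] = u_y
                so_d[pos] = s_obs
                sf_d[pos] = s_fish
                sy_d[pos] = s_year
                chain_lbl[pos] = ch
                pos += 1

    samples = PosteriorSamples(
        beta=beta_d, u_fish=uf_d, u_year=uy_d,
        sigma_obs=so_d, sigma_fish=sf_d, sigma_year=sy_d,
        coef_names=design.coef_names, fish_ids=design.fish_ids, cells=design.cells,
        chain=chain_lbl,
        meta={
            "draws": cfg.draws, "burnin": cfg.burnin, "thin": cfg.thin,
            "chains": cfg.chains, "seed": seed,
        },
    )
    samples.diagnostics = _convergence_diagnostics(samples, spec)
    bad = {k: v for k, v in samples.diagnostics.items() if v > cfg.rhat_warn}
    if bad:
        warnings.warn(f"split-chain R-hat above {cfg.rhat_warn}: {bad}", stacklevel=2)
    return samples


def _convergence_diagnostics(samples: PosteriorSamples, spec: GrowthModelSpec) -> dict:
    """Split-chain potential-scale-reduction on the variance components."""
    import arviz as az

    out = {}
    for name, draws, prior in (
        ("sigma_obs", samples.sigma_obs, spec.prior_obs),
        ("sigma_fish", samples.sigma_fish, spec.prior_fish),
        ("sigma_year", samples.sigma_year, spec.prior_year),
    ):
        if prior.family == "fixed" or draws.size == 0 or np.ptp(draws) == 0:
            continue
        chains = np.unique(samples.chain)
        per = min((samples.chain == c).sum() for c in chains)
        arr = np.stack([draws[samples.chain == c][:per] for c in chains])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[name] = float(np.asarray(az.rhat(az.convert_to_dataset(arr))["x"]).item())
    return out


# ---------------------------------------------------------------------------
# DIC and model comparison


def _deviance_draws(samples: PosteriorSamples, design: Design, chunk: int = 256) -> np.ndarray:
    """Per-draw conditional deviance D(theta)."""
    y, X = design.y, design.X
    n = design.n
    log2pi = np.log(2.0 * np.pi)
    out = np.empty(samples.n_draws)
    for start in range(0, samples.n_draws, chunk):
        sl = slice(start, min(start + chunk, samples.n_draws))
        eta = samples.beta[sl] @ X.T
        if design.n_cells:
            eta += samples.u_year[sl][:, design.cell_idx]
        if design.n_fish:
            eta += samples.u_fish[sl][:, design.fish_idx]
        sse = ((y[None, :] - eta) ** 2).sum(axis=1)
        s2 = samples.sigma_obs[sl] ** 2
        out[sl] = n * (log2pi + np.log(s2)) + sse / s2
    return out


def dic_standard_error(
    samples: PosteriorSamples, design: Design, n_batches: int = 20
) -> float:
    """Batch-means Monte Carlo standard error of the mean deviance.

    DIC from sampler output carries MC noise (unlike DIC from a
    deterministic approximation); delta-DIC values within a few standard
    errors of zero should not be over-read.
    """
    d = _deviance_draws(samples, design)
    usable = (len(d) // n_batches) * n_batches
    if usable < n_batches:
        raise ModelError("too few draws for a batch-means standard error")
    batches = d[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))


def dic(samples: PosteriorSamples, design: Design, chunk: int = 256) -> tuple[float, float]:
    """Deviance information criterion with the likelihood conditional on the
    latent effects.

    D(theta) = -2 log N(y | X beta + Z u, sigma_obs^2 I); DIC = mean D + pD,
    pD = mean D - D(posterior means).
    """
    if samples.n_draws < 2:
        raise ModelError("too few draws for DIC")
    y, X = design.y, design.X
    n = design.n
    log2pi = np.log(2.0 * np.pi)
    dbar = float(_deviance_draws(samples, design, chunk).mean())

    eta_hat = X @ samples.beta.mean(axis=0)
    if design.n_cells:
        eta_hat += samples.u_year.mean(axis=0)[design.cell_idx]
    if design.n_fish:
        eta_hat += samples.u_fish.mean(axis=0)[design.fish_idx]
    s2_hat = float(samples.sigma_obs.mean()) ** 2
    d_hat = n * (log2pi + np.log(s2_hat)) + float(((y - eta_hat) ** 2).sum()) / s2_hat

    p_d = dbar - d_hat
    return float(dbar + p_d), float(p_d)


@dataclass
class ModelComparison:
    """DIC table for a base model and its term-dropped variants."""

    table: pd.DataFrame  # columns: model, dic, p_d, delta_dic, supported

    def supported(self, term: str) -> bool:
        row = self.table.loc[self.table["model"] == f"-{term}"]
        if row.empty:
            raise ModelError(f"term {term!r} was not compared")
        return bool(row["supported"].iloc[0])


def compare_terms(
    dataset: AnalysisDataset,
    base_spec: GrowthModelSpec,
    candidate_terms: list[str],
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
) -> ModelComparison:
    """Fit the base model and each term-dropped variant; apply the
    delta-DIC > 2 support rule.

    ``delta_dic`` for a dropped term is DIC(without term) - DIC(base); the
    term is supported when removing it raises DIC by more than 2.  All fits
    share the same seed policy so comparisons are reproducible.
    """
    rows = []
    base_design = build_design(dataset, base_spec)
    base_samples = fit(base_design, base_spec, sampler_config, seed=seed)
    base_dic, base_pd = dic(base_samples, base_design)
    base_se = dic_standard_error(base_samples, base_design)
    rows.append({"model": "base", "dic": base_dic, "p_d": base_pd, "dic_se": base_se,
                 "delta_dic": 0.0, "supported": None})

    for term in candidate_terms:
        spec_wo = base_spec.drop(term)
        try:
            design_wo = build_design(dataset, spec_wo)
            samples_wo = fit(design_wo, spec_wo, sampler_config, seed=seed)
        except ModelError as exc:
            raise ModelError(f"fit failed for model without {term!r}: {exc}") from exc
        dic_wo, pd_wo = dic(samples_wo, design_wo)
        se_wo = dic_standard_error(samples_wo, design_wo)
        delta = dic_wo - base_dic
        rows.append({"model": f"-{term}", "dic": dic_wo, "p_d": pd_wo, "dic_se": se_wo,
                     "delta_dic": delta, "supported": delta > 2.0})
    return ModelComparison(pd.DataFrame(rows))


def prior_sensitivity(
    dataset: AnalysisDataset,
    spec: GrowthModelSpec,
    families: list[str],
    sampler_config: SamplerConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit under each prior family; tabulate posterior means side by side.

    Returns a long table (family, parameter, mean) plus a ``max_abs_diff``
    attribute-style column computed across families per parameter.
    """
    if len(families) < 1:
        raise ModelError("need at least one prior family")
    frames = []
    for family in families:
        s = spec.with_priors(family)
        design = build_design(dataset, s)
        samples = fit(design, s, sampler_config, seed=seed)
        fe = samples.fixed_effects_summary()[["coefficient", "mean"]].rename(
            columns={"coefficient": "parameter"}
        )
        sd = samples.sd_summary()[["component", "mean"]].rename(columns={"component": "parameter"})
        sd["parameter"] = "sd_" + sd["parameter"]
        part = pd.concat([fe, sd], ignore_index=True)
        part.insert(0, "family", family)
        frames.append(part)
    table = pd.concat(frames, ignore_index=True)
    spread = table.groupby("parameter")["mean"].agg(lambda v: v.max() - v.min())
    table = table.merge(spread.rename("max_abs_diff"), on="parameter")
    return table
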