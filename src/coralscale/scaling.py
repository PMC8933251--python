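"""Hierarchical Bayesian allometric scaling model.

For a physiological rate R (whole colony) and live 3D surface area x,
the model is a log-log regression with correlated species-level
deviations of intercept and slope:

    ln R_{s,i} ~ Normal(mu_{s,i}, sigma)
    mu_{s,i}   = (ln_alpha + zeta[s,1]) + (beta + zeta[s,2]) * ln x_i
    zeta_s     = diag(sigma_zeta) @ L_Omega @ delta_s      (non-centered)
    delta_s    ~ Normal(0, 1)

where L_Omega is the Cholesky factor of the 2x2 correlation matrix with
off-diagonal rho, itself given an LKJ(1) prior (uniform over rho).
Remaining priors: beta ~ N(0,5), ln_alpha ~ N(0,5),
sigma ~ Gamma(shape 2, rate 0.1), sigma_zeta ~ Gamma(2, 0.1) each.

beta is the among-species scaling exponent: beta = 1 is isometry
(area-specific rates constant across colony size), beta < 1 is
hypo-allometry (smaller colonies run faster per unit area).  The
exponent of area-specific rates is 1 - beta.

Sampling is collapsed: conditional on (sigma, sigma_zeta, rho) the
model is linear-Gaussian, so the 2 + 2S regression coefficients are
integrated out analytically and an affine-invariant ensemble (emcee)
explores only the smooth 4-dimensional marginal of the scale
parameters (on the unconstrained scale: log SDs, atanh correlation,
with Jacobians).  Coefficients are then drawn exactly from their
Gaussian conditional for each retained draw.  Each requested chain is
an independent ensemble whose post-burn-in states are thinned to
exactly ``draws_per_chain - warmup`` retained draws, so the
chains x (draws - warmup) bookkeeping is exact and the split
potential-scale-reduction factor (R-hat) is computable across chains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import emcee
import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "PriorSpec",
    "FitConfig",
    "TEST_FIT",
    "PAPER_FIT",
    "ModelData",
    "ScalingParams",
    "PosteriorDraws",
    "log_posterior",
    "sample_posterior",
    "fit_scaling_model",
    "rhat",
    "summarize_posterior",
    "area_specific_exponent",
    "prob_isometry",
    "bayes_r2",
    "predict_rate",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the prior distributions (defaults as documented above)."""

    ln_alpha_loc: float = 0.0
    ln_alpha_scale: float = 5.0
    beta_loc: float = 0.0
    beta_scale: float = 5.0
    sigma_shape: float = 2.0
    sigma_rate: float = 0.1  # rate = inverse scale
    sigma_zeta_shape: float = 2.0
    sigma_zeta_rate: float = 0.1
    lkj_eta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ln_alpha_scale", "beta_scale", "sigma_shape", "sigma_rate",
                     "sigma_zeta_shape", "sigma_zeta_rate", "lkj_eta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FitConfig:
    """MCMC run configuration.

    ``draws_per_chain`` and ``warmup`` follow the classic per-chain
    accounting: the fit retains chains x (draws - warmup) draws.  The
    ensemble knobs (walkers, minimum burn/sample steps) control the
    underlying sampler's mixing and are independent of that accounting.
    """

    n_chains: int = 3
    draws_per_chain: int = 5000
    warmup: int = 2500
    seed: int = 0
    rhat_max: float = 1.05
    n_walkers: int = 20
    min_burn_steps: int = 400
    min_sample_steps: int = 400

    def __post_init__(self) -> None:
        if not self.warmup < self.draws_per_chain:
            raise ValueError("warmup must be smaller than draws_per_chain")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for R-hat")

    @property
    def retained_per_chain(self) -> int:
        return self.draws_per_chain - self.warmup

    @property
    def n_retained(self) -> int:
        return self.n_chains * self.retained_per_chain


#: The full-scale profile (3 x 5000 draws, 2500 warm-up -> 7500 retained).
PAPER_FIT = FitConfig()
#: Reduced profile for tests and quick exploration (3 x 1000/500 -> 1500).
TEST_FIT = FitConfig(draws_per_chain=1000, warmup=500)


@dataclass(frozen=True)
class ModelData:
    """Arrays the likelihood needs: log rates, log areas, species index."""

    ln_rate: np.ndarray
    ln_area: np.ndarray
    species_idx: np.ndarray
    species: tuple[str, ...]

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        rate_col: str,
        area_col: str = "area_cm2",
        species_col: str = "species",
    ) -> "ModelData":
        """Build from a tidy colony table, dropping non-positive rates.

        The log transform requires positivity; any dropped rows are
        reported with a warning.
        """
        rate = df[rate_col].to_numpy(dtype=float)
        area = df[area_col].to_numpy(dtype=float)
        ok = (rate > 0) & (area > 0) & np.isfinite(rate) & np.isfinite(area)
        if not ok.all():
            warnings.warn(
                f"dropping {np.count_nonzero(~ok)} rows with non-positive or "
                f"non-finite {rate_col}/{area_col} before log transform"
            )
        species = tuple(sorted(df.loc[ok, species_col].unique()))
        if len(species) < 2:
            warnings.warn("fewer than 2 species: hierarchical SDs are weakly identified")
        lookup = {s: i for i, s in enumerate(species)}
        idx = df.loc[ok, species_col].map(lookup).to_numpy(dtype=int)
        counts = np.bincount(idx, minlength=len(species))
        if (counts < 3).any():
            warnings.warn("some species have fewer than 3 observations")
        return cls(
            ln_rate=np.log(rate[ok]),
            ln_area=np.log(area[ok]),
            species_idx=idx,
            species=species,
        )

    @property
    def n_obs(self) -> int:
        return self.ln_rate.size

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class ScalingParams:
    """One point in constrained parameter space."""

    ln_alpha: float
    beta: float
    sigma: float
    sigma_zeta: tuple[float, float]
    rho: float
    delta: np.ndarray  # (n_species, 2) standardized deviations

    def zeta(self) -> np.ndarray:
        """Species deviations (n_species, 2) from the non-centered construction."""
        s1, s2 = self.sigma_zeta
        d = np.asarray(self.delta, dtype=float)
        z1 = s1 * d[:, 0]
        z2 = s2 * (self.rho * d[:, 0] + math.sqrt(max(0.0, 1.0 - self.rho ** 2)) * d[:, 1])
        return np.column_stack([z1, z2])


def _lkj_2x2_logpdf(rho: np.ndarray | float, eta: float) -> np.ndarray | float:
    """Exact LKJ density of the single correlation of a 2x2 matrix.

    rho follows a scaled Beta(eta, eta) on (-1, 1):
    f(rho) = (1 - rho^2)^(eta-1) / (2^(2 eta - 1) B(eta, eta)).
    """
    log_norm = (2.0 * eta - 1.0) * math.log(2.0) + special.betaln(eta, eta)
    if eta == 1.0:  # density constant in rho; avoid 0 * log(0) at |rho| = 1
        return np.zeros_like(np.asarray(rho, dtype=float)) - log_norm
    return (eta - 1.0) * np.log1p(-np.square(rho)) - log_norm


def log_posterior(params: ScalingParams, data: ModelData, priors: PriorSpec = PriorSpec()) -> float:
    """Unnormalized log posterior at one constrained parameter point.

    Sum of the Gaussian log-likelihood of all log rates and every prior
    log-density (including each standardized deviation delta).  Raises
    with the offending term named if the result is not finite.

    A sigma_zeta entry of exactly 0 switches that random-effect
    dimension off structurally (zeta fixed at 0): its Gamma prior term
    is skipped rather than evaluated at the boundary, so the density
    collapses cleanly to the lower-level model.
    """
    if params.sigma <= 0 or min(params.sigma_zeta) < 0:
        raise ValueError("sigma must be positive and sigma_zeta non-negative")
    if not -1.0 <= params.rho <= 1.0:
        raise ValueError(f"rho out of [-1, 1]: {params.rho}")
    zeta = params.zeta()
    mu = (params.ln_alpha + zeta[data.species_idx, 0]) + (
        params.beta + zeta[data.species_idx, 1]
    ) * data.ln_area
    terms = {
        "likelihood": float(np.sum(stats.norm.logpdf(data.ln_rate, mu, params.sigma))),
        "ln_alpha_prior": float(
            stats.norm.logpdf(params.ln_alpha, priors.ln_alpha_loc, priors.ln_alpha_scale)
        ),
        "beta_prior": float(stats.norm.logpdf(params.beta, priors.beta_loc, priors.beta_scale)),
        "sigma_prior": float(
            stats.gamma.logpdf(params.sigma, priors.sigma_shape, scale=1.0 / priors.sigma_rate)
        ),
        "sigma_zeta_prior": float(
            sum(
                stats.gamma.logpdf(
                    sz, priors.sigma_zeta_shape, scale=1.0 / priors.sigma_zeta_rate
                )
                for sz in params.sigma_zeta
                if sz > 0
            )
        ),
        "omega_prior": float(_lkj_2x2_logpdf(params.rho, priors.lkj_eta)),
        "delta_prior": float(np.sum(stats.norm.logpdf(np.asarray(params.delta)))),
    }
    total = sum(terms.values())
    if not np.isfinite(total):
        bad = [k for k, v in terms.items() if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite log posterior; offending terms: {bad}")
    return total


# ---------------------------------------------------------------------------
# Collapsed sampler machinery.
#
# Conditional on the scale parameters phi = (sigma, sigma_zeta, rho), the
# model is linear-Gaussian in the coefficient vector
# c = (ln_alpha, beta, zeta[:, 1], zeta[:, 2]): ln R = X c + eps with a
# Gaussian prior on c.  The coefficients are therefore integrated out in
# closed form; the ensemble sampler only has to explore the smooth
# 4-dimensional marginal posterior of phi (on the unconstrained scale:
# log SDs, atanh correlation), which removes the funnel geometry that
# makes the joint 6 + 2S dimensional posterior hard for non-gradient
# samplers.  For every retained phi draw, c is then drawn exactly from
# its multivariate-Gaussian conditional, so the recovered joint draws
# target the full posterior without approximation.
# ---------------------------------------------------------------------------

_LOG_2PI = math.log(2.0 * math.pi)


class _CollapsedModel:
    """Precomputed sufficient statistics and the collapsed densities."""

    def __init__(self, data: ModelData, priors: PriorSpec):
        s, n = data.n_species, data.n_obs
        p = 2 + 2 * s
        x = np.zeros((n, p))
        x[:, 0] = 1.0
        x[:, 1] = data.ln_area
        x[np.arange(n), 2 + data.species_idx] = 1.0
        x[np.arange(n), 2 + s + data.species_idx] = data.ln_area
        self.xtx = x.T @ x
        self.xty = x.T @ data.ln_rate
        self.yty = float(data.ln_rate @ data.ln_rate)
        self.n, self.s, self.p = n, s, p
        self.priors = priors

    def prior_factor(self, s1: float, s2: float, rho: float) -> np.ndarray:
        """Square factor L with V0 = L Lᵀ for the coefficient prior covariance.

        Rows/cols ordered (ln_alpha, beta, zeta1 per species, zeta2 per
        species); each species' (zeta1, zeta2) pair has the 2x2
        covariance built from sigma_zeta and rho.  Valid (one-sided)
        factor even in the degenerate limits s1, s2 -> 0 or |rho| -> 1.
        """
        pr = self.priors
        s_ = self.s
        l = np.zeros((self.p, self.p))
        l[0, 0] = pr.ln_alpha_scale
        l[1, 1] = pr.beta_scale
        c = math.sqrt(max(0.0, 1.0 - rho * rho))
        for j in range(s_):
            l[2 + j, 2 + j] = s1
            l[2 + s_ + j, 2 + j] = s2 * rho
            l[2 + s_ + j, 2 + s_ + j] = s2 * c
        return l

    def marginal_loglik(self, sigma: float, s1: float, s2: float, rho: float) -> float:
        """log p(ln R | sigma, sigma_zeta, rho) with coefficients integrated out.

        Uses the determinant identity |V0 P| = |I + Lᵀ Q L| (Q = XᵀX/σ²)
        and the Woodbury form P⁻¹ = L A⁻¹ Lᵀ, which stay finite as the
        hierarchical SDs shrink to zero.
        """
        q = self.xtx / sigma ** 2
        l = self.prior_factor(s1, s2, rho)
        a = np.eye(self.p) + l.T @ q @ l
        try:
            ca = np.linalg.cholesky(a)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet_a = 2.0 * float(np.sum(np.log(np.diag(ca))))
        u = l.T @ (self.xty / sigma ** 2)
        z = np.linalg.solve(ca, u)  # triangular in effect; p is tiny
        quad = float(z @ z)
        return (
            -0.5 * self.n * _LOG_2PI
            - self.n * math.log(sigma)
            - 0.5 * logdet_a
            + 0.5 * quad
            - 0.5 * self.yty / sigma ** 2
        )

    def log_post_phi(self, phi: np.ndarray) -> np.ndarray:
        """Marginal log posterior of unconstrained phi rows.

        phi columns: log sigma, log sigma_zeta1, log sigma_zeta2,
        atanh(rho); includes priors and transform Jacobians.
        """
        phi = np.atleast_2d(phi)
        pr = self.priors
        out = np.empty(phi.shape[0])
        for i, row in enumerate(phi):
            ls, l1, l2, zr = row
            if max(abs(ls), abs(l1), abs(l2)) > 30.0 or abs(zr) > 20.0:
                out[i] = -np.inf
                continue
            sigma, s1, s2 = math.exp(ls), math.exp(l1), math.exp(l2)
            rho = math.tanh(zr)
            lp = self.marginal_loglik(sigma, s1, s2, rho)

            def gamma_lp(x, logx, a, rate):
                return a * math.log(rate) - float(special.gammaln(a)) + (a - 1.0) * logx - rate * x

            lp += gamma_lp(sigma, ls, pr.sigma_shape, pr.sigma_rate)
            lp += gamma_lp(s1, l1, pr.sigma_zeta_shape, pr.sigma_zeta_rate)
            lp += gamma_lp(s2, l2, pr.sigma_zeta_shape, pr.sigma_zeta_rate)
            lp += float(_lkj_2x2_logpdf(rho, pr.lkj_eta))
            # Jacobians of exp (x3) and tanh.
            lp += ls + l1 + l2 + math.log1p(-rho * rho) if abs(rho) < 1 else -np.inf
            out[i] = lp if np.isfinite(lp) else -np.inf
        return out

    def draw_coefficients(
        self, sigma: float, s1: float, s2: float, rho: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Exact draw of c | phi, data ~ N(P⁻¹ Xᵀy/σ², P⁻¹)."""
        q = self.xtx / sigma ** 2
        l = self.prior_factor(s1, s2, rho)
        a = np.eye(self.p) + l.T @ q @ l
        ca = np.linalg.cholesky(a)
        u = l.T @ (self.xty / sigma ** 2)
        # mean m = L A^{-1} u; sample m + (L R^{-T}) xi with A = R Rᵀ.
        ainv_u = np.linalg.solve(ca.T, np.linalg.solve(ca, u))
        m = l @ ainv_u
        xi = rng.standard_normal(self.p)
        return m + l @ np.linalg.solve(ca.T, xi)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (n_chains, draws_per_chain - warmup, ...)."""

    ln_alpha: np.ndarray            # (C, T)
    beta: np.ndarray                # (C, T)
    sigma: np.ndarray               # (C, T)
    sigma_zeta: np.ndarray          # (C, T, 2)
    rho: np.ndarray                 # (C, T)
    delta: np.ndarray               # (C, T, S, 2)
    species: tuple[str, ...]
    config: FitConfig
    rhat_values: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        c, t = self.ln_alpha.shape
        expect = self.config.n_chains * self.config.retained_per_chain
        assert c * t == expect, "retained-draw bookkeeping violated"

    @property
    def n_retained(self) -> int:
        return self.ln_alpha.size

    @property
    def zeta(self) -> np.ndarray:
        """Species deviations (C, T, S, 2)."""
        s1 = self.sigma_zeta[..., 0][..., None]
        s2 = self.sigma_zeta[..., 1][..., None]
        r = self.rho[..., None]
        z1 = s1 * self.delta[..., 0]
        z2 = s2 * (r * self.delta[..., 0] + np.sqrt(np.clip(1 - r ** 2, 0, None)) * self.delta[..., 1])
        return np.stack([z1, z2], axis=-1)

    @property
    def species_intercept(self) -> np.ndarray:
        """Per-species ln alpha + zeta1, shape (C, T, S)."""
        return self.ln_alpha[..., None] + self.zeta[..., 0]

    @property
    def species_slope(self) -> np.ndarray:
        """Per-species beta + zeta2, shape (C, T, S)."""
        return self.beta[..., None] + self.zeta[..., 1]

    def flat(self, arr: np.ndarray) -> np.ndarray:
        """Collapse the chain axis: (C, T, ...) -> (C*T, ...)."""
        return arr.reshape(-1, *arr.shape[2:])


def _initial_phi_walkers(
    data: ModelData, cfg: FitConfig, rng: np.random.Generator
) -> np.ndarray:
    """Overdispersed 4-dim starts around a pooled least-squares residual SD."""
    res = stats.linregress(data.ln_area, data.ln_rate)
    resid_sd = float(np.std(data.ln_rate - (res.intercept + res.slope * data.ln_area)))
    resid_sd = max(resid_sd, 1e-3)
    center = np.array([math.log(resid_sd), math.log(0.4), math.log(0.1), 0.0])
    scatter = np.array([0.3, 0.7, 0.7, 0.5])
    return center[None, :] + scatter[None, :] * rng.standard_normal((cfg.n_walkers, 4))


def _delta_from_zeta(
    zeta: np.ndarray, s1: np.ndarray, s2: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    """Invert the non-centered construction: delta = L_zeta^{-1} zeta.

    Shapes: zeta (..., S, 2); s1, s2, rho broadcastable to (...).  SDs
    and the correlation complement are floored at a tiny value so the
    inversion stays finite in the degenerate limits (where delta is
    unidentified anyway).
    """
    eps = 1e-12
    s1 = np.maximum(s1, eps)[..., None]
    s2 = np.maximum(s2, eps)[..., None]
    r = rho[..., None]
    c = np.sqrt(np.clip(1.0 - r ** 2, eps, None))
    d1 = zeta[..., 0] / s1
    d2 = (zeta[..., 1] / s2 - r * d1) / c
    return np.stack([d1, d2], axis=-1)


def sample_posterior(
    data: ModelData, priors: PriorSpec = PriorSpec(), cfg: FitConfig = PAPER_FIT
) -> PosteriorDraws:
    """Run the MCMC fit and return exactly chains x (draws - warmup) draws.

    Each chain is an independent affine-invariant ensemble (emcee) on
    the 4-dimensional collapsed posterior of (sigma, sigma_zeta, rho),
    seeded from ``cfg.seed``.  After burn-in the ensemble states are
    flattened in (step, walker) order and thinned deterministically to
    the retained count; the linear coefficients (ln alpha, beta, species
    deviations) are then drawn exactly from their Gaussian conditional
    for every retained draw, so the assembled draws target the full
    joint posterior.  R-hat is computed per parameter across chains; if
    any exceeds ``cfg.rhat_max`` the result is flagged
    ``converged=False`` (and a warning emitted) but still returned.
    """
    if data.n_species < 2:
        warnings.warn("fewer than 2 species; hierarchical structure weakly identified")
    s = data.n_species
    model = _CollapsedModel(data, priors)
    retained = cfg.retained_per_chain
    burn_steps = max(cfg.min_burn_steps, math.ceil(cfg.warmup / cfg.n_walkers))
    sample_steps = max(cfg.min_sample_steps, math.ceil(retained / cfg.n_walkers))
    ss = np.random.SeedSequence(cfg.seed)
    phi_chains, coef_chains = [], []
    for child in ss.spawn(cfg.n_chains):
        seeds = child.generate_state(3)
        rng = np.random.default_rng(seeds[0])
        p0 = _initial_phi_walkers(data, cfg, rng)
        sampler = emcee.EnsembleSampler(
            cfg.n_walkers, 4, model.log_post_phi, vectorize=True
        )
        # emcee expects the raw get_state() tuple; anything else is
        # silently ignored and the ensemble would inherit global state.
        sampler.random_state = np.random.RandomState(int(seeds[1] % 2 ** 31)).get_state()
        state = sampler.run_mcmc(p0, burn_steps, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, sample_steps, progress=False)
        flat = sampler.get_chain().reshape(-1, 4)  # (steps*walkers, 4)
        total = flat.shape[0]
        idx = (np.arange(retained) * total) // retained
        phi = flat[idx]
        phi_chains.append(phi)
        crng = np.random.default_rng(seeds[2])
        coefs = np.empty((retained, model.p))
        for t in range(retained):
            ls, l1, l2, zr = phi[t]
            coefs[t] = model.draw_coefficients(
                math.exp(ls), math.exp(l1), math.exp(l2), math.tanh(zr), crng
            )
        coef_chains.append(coefs)
    phi = np.stack(phi_chains)      # (C, T, 4)
    coef = np.stack(coef_chains)    # (C, T, 2 + 2S)
    sigma_zeta = np.exp(phi[..., 1:3])
    rho = np.tanh(phi[..., 3])
    zeta = np.stack([coef[..., 2: 2 + s], coef[..., 2 + s:]], axis=-1)  # (C, T, S, 2)
    draws = PosteriorDraws(
        ln_alpha=coef[..., 0],
        beta=coef[..., 1],
        sigma=np.exp(phi[..., 0]),
        sigma_zeta=sigma_zeta,
        rho=rho,
        delta=_delta_from_zeta(
            zeta, sigma_zeta[..., 0], sigma_zeta[..., 1], rho
        ),
        species=data.species,
        config=cfg,
    )
    rh = {
        "ln_alpha": rhat(draws.ln_alpha),
        "beta": rhat(draws.beta),
        "sigma": rhat(draws.sigma),
        "sigma_zeta_intercept": rhat(draws.sigma_zeta[..., 0]),
        "sigma_zeta_slope": rhat(draws.sigma_zeta[..., 1]),
        "rho": rhat(draws.rho),
    }
    for j, sp in enumerate(data.species):
        rh[f"slope[{sp}]"] = rhat(draws.species_slope[..., j])
        rh[f"intercept[{sp}]"] = rhat(draws.species_intercept[..., j])
    draws.rhat_values = rh
    worst = np.nanmax(list(rh.values()))
    draws.converged = bool(worst < cfg.rhat_max)
    if not draws.converged:
        warnings.warn(
            f"fit flagged non-converged: max R-hat {worst:.3f} >= {cfg.rhat_max}"
        )
    return draws


def fit_scaling_model(
    df: pd.DataFrame,
    rate_col: str,
    priors: PriorSpec = PriorSpec(),
    cfg: FitConfig = PAPER_FIT,
    area_col: str = "area_cm2",
    species_col: str = "species",
) -> PosteriorDraws:
    """Convenience wrapper: tidy colony frame -> posterior draws."""
    data = ModelData.from_frame(df, rate_col, area_col, species_col)
    return sample_posterior(data, priors, cfg)


def rhat(x: np.ndarray) -> float:
    """Split potential scale-reduction factor for draws shaped (chains, draws).

    The classic split-R-hat of chain-half means/variances (not the
    rank-normalized variant).  Returns NaN when the within-chain
    variance is zero (degenerate, e.g. identical constant chains).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need (chains >= 2, draws >= 4) array")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m, n = splits.shape
    chain_means = splits.mean(axis=1)
    chain_vars = splits.var(axis=1, ddof=1)
    w = chain_vars.mean()
    if w == 0:
        return float("nan")
    b = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean and central 95% interval for all reported parameters.

    Fixed effects and hierarchical SDs/correlation first (the shape of a
    fixed-effects table), then per-species alpha (natural scale) and
    slope beta (per-species table shape).
    """
    rows = []

    def add(name, a, kind):
        a = np.ravel(a)
        rows.append(
            {
                "parameter": name,
                "kind": kind,
                "mean": float(np.mean(a)),
                "q2.5": float(np.quantile(a, 0.025)),
                "q97.5": float(np.quantile(a, 0.975)),
                "rhat": draws.rhat_values.get(name, float("nan")),
            }
        )

    add("ln_alpha", draws.ln_alpha, "fixed")
    add("beta", draws.beta, "fixed")
    add("sigma", draws.sigma, "fixed")
    add("sigma_zeta_intercept", draws.sigma_zeta[..., 0], "random")
    add("sigma_zeta_slope", draws.sigma_zeta[..., 1], "random")
    add("rho", draws.rho, "random")
    for j, sp in enumerate(draws.species):
        add(f"alpha[{sp}]", np.exp(draws.species_intercept[..., j]), "species")
        add(f"beta[{sp}]", draws.species_slope[..., j], "species")
    return pd.DataFrame(rows)


def area_specific_exponent(draws: PosteriorDraws, species: str | None = None) -> np.ndarray:
    """Per-draw exponent of area-specific rates, 1 - beta (flattened).

    With ``species`` given, uses that species' slope beta + zeta2.
    """
    if species is None:
        return 1.0 - draws.flat(draws.beta)
    j = _species_index(draws, species)
    return 1.0 - draws.flat(draws.species_slope)[:, j]


def prob_isometry(draws: PosteriorDraws, species: str | None = None) -> float:
    """Fraction of draws whose slope is >= 1 (isometric or hyper-allometric)."""
    if species is None:
        slopes = draws.flat(draws.beta)
    else:
        slopes = draws.flat(draws.species_slope)[:, _species_index(draws, species)]
    return float(np.mean(slopes >= 1.0))


def bayes_r2(draws: PosteriorDraws, data: ModelData) -> np.ndarray:
    """Per-draw Bayesian R² on the log scale (flattened).

    R² = Var(fitted) / (Var(fitted) + Var(residual)), with both
    variances empirical over the observations for each draw.  Zero
    fitted variance gives R² = 0.
    """
    la = draws.flat(draws.species_intercept)  # (N_draws, S)
    sl = draws.flat(draws.species_slope)
    idx = data.species_idx
    mu = la[:, idx] + sl[:, idx] * data.ln_area[None, :]
    resid = data.ln_rate[None, :] - mu
    v_fit = mu.var(axis=1)
    v_res = resid.var(axis=1)
    denom = v_fit + v_res
    out = np.where(denom > 0, v_fit / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def predict_rate(
    draws: PosteriorDraws,
    species: str,
    area_cm2: float,
    include_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Posterior (predictive) distribution of the rate at one area.

    Per draw: rate = exp[(ln_alpha + zeta1) + (beta + zeta2) ln area];
    with ``include_noise`` a lognormal residual with SD sigma is added,
    giving the posterior predictive for a new colony.
    """
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    j = _species_index(draws, species)
    mu = (
        draws.flat(draws.species_intercept)[:, j]
        + draws.flat(draws.species_slope)[:, j] * math.log(area_cm2)
    )
    if include_noise:
        rng = np.random.default_rng() if rng is None else rng
        mu = mu + draws.flat(draws.sigma) * rng.standard_normal(mu.size)
    return np.exp(mu)


def _species_index(draws: PosteriorDraws, species: str) -> int:
    try:
        return draws.species.index(species)
    except ValueError:
        raise KeyError(
            f"species {species!r} not in fitted set {list(draws.species)}"
        ) from None
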