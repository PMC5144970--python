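"""Hierarchical Bayesian one-way model with per-genotype variances.

The likelihood is y_i ~ Normal(beta0 + beta_{g(i)}, 1/tau_{g(i)}): every
genotype has its own precision.  Genotype effects get a shrinkage prior
beta_j ~ Normal(0, sigma_beta^2) with a folded-t hyperprior on sigma_beta;
the precisions share a hierarchical Gamma prior

    tau_j ~ Gamma(s_G, r_G),  s_G = m^2 / d^2,  r_G = m / d^2,

so that m is the prior mean and d the prior SD of the tau_j, with vague
Gamma hyperpriors on m and d.  Data are standardized before sampling and
effects are swept to sum to zero each saved iteration, so the intercept is
zero and contrasts are reported back on the original mm/hr scale.

Sampling is Metropolis-within-Gibbs: conjugate normal updates for the
effects, conjugate gamma updates for the precisions, and log-scale
random-walk Metropolis for sigma_beta, m and d with proposal scales adapted
during burn-in only.  A mutant and the control differ "significantly" when
the 95% highest-posterior-density interval of their rescaled effect
difference excludes zero; the hierarchical shrinkage is the only
multiplicity control applied.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import ValidationError

__all__ = [
    "tau_prior_draws",
    "HierarchicalModelSpec",
    "McmcConfig",
    "PosteriorDraws",
    "ContrastResult",
    "standardize",
    "sample_posterior",
    "hpd_interval",
    "compute_contrast",
    "convergence_diagnostics",
]

log = logging.getLogger(__name__)


def tau_prior_draws(m: float, d: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draws of tau under the (m, d) parameterization of its Gamma prior.

    Gamma(shape m^2/d^2, rate m/d^2), i.e. prior mean m and prior SD d.
    """
    if m <= 0 or d <= 0:
        raise ValidationError("m and d must be positive")
    shape = m**2 / d**2
    rate = m / d**2
    return rng.gamma(shape, 1.0 / rate, size)


def _gamma_mode1_sd10_params() -> tuple[float, float]:
    # shape s, rate r with mode (s-1)/r = 1 and SD sqrt(s)/r = 10
    r = (1.0 + math.sqrt(1.0 + 400.0)) / 200.0
    return 1.0 + r, r


_S_VAGUE, _R_VAGUE = _gamma_mode1_sd10_params()


@dataclass(frozen=True)
class HierarchicalModelSpec:
    """Hyperconstants and structural switches for the hierarchical model."""

    nu_beta: float = 2.0       # folded-t df for the sigma_beta prior
    A_beta: float = 1.0        # folded-t scale (standardized response scale)
    s_m: float = _S_VAGUE
    r_m: float = _R_VAGUE
    s_d: float = _S_VAGUE
    r_d: float = _R_VAGUE
    pool_variances: bool = False        # force a single common tau
    fix_sigma_beta: float | None = None  # freeze the shrinkage scale
    likelihood: bool = True             # False = sample from the prior only

    def __post_init__(self) -> None:
        for name in ("nu_beta", "A_beta", "s_m", "r_m", "s_d", "r_d"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"hyperconstant {name} must be positive")


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 5
    burn_in: int = 10_000
    n_saved: int = 2_000   # draws kept per chain
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.burn_in, self.n_saved, self.thin) < 1:
            raise ValidationError("all MCMC settings must be positive")


@dataclass
class PosteriorDraws:
    """Saved MCMC draws, shaped (chain, draw[, genotype])."""

    genotypes: list[str]
    beta_std: np.ndarray        # sum-to-zero effects, standardized scale
    beta0_std: np.ndarray
    tau: np.ndarray
    sigma_beta: np.ndarray
    m: np.ndarray
    d: np.ndarray
    y_mean: float
    y_sd: float
    config: McmcConfig
    spec: HierarchicalModelSpec
    flagged: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def beta_rescaled(self) -> np.ndarray:
        """Effects on the original mm/hr scale."""
        return self.beta_std * self.y_sd

    def effect_draws(self, genotype: str) -> np.ndarray:
        try:
            j = self.genotypes.index(genotype)
        except ValueError:
            raise ValidationError(f"unknown genotype {genotype!r}") from None
        return self.beta_rescaled[:, :, j].reshape(-1)


@dataclass
class ContrastResult:
    mutant: str
    control: str
    mean_diff: float
    hpd_low: float
    hpd_high: float
    significant: bool


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Center and scale to unit SD (n-1 denominator); returns (z, mean, sd)."""
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValidationError("cannot standardize a constant vector")
    mean = float(np.mean(y))
    sd = float(np.std(y, ddof=1))
    return (y - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# densities used by the Metropolis steps
# ---------------------------------------------------------------------------

def _log_gamma_pdf(x: float, shape: float, rate: float) -> float:
    return shape * math.log(rate) - math.lgamma(shape) + (shape - 1.0) * math.log(x) - rate * x


def _log_folded_t(sigma: float, nu: float, scale: float) -> float:
    return -0.5 * (nu + 1.0) * math.log1p((sigma / scale) ** 2 / nu)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def _run_chain(z, codes, n_groups, spec, cfg, chain):
    rng = np.random.default_rng([cfg.seed, chain, 20240915])
    n_j = np.bincount(codes, minlength=n_groups).astype(float)
    S_j = np.bincount(codes, weights=z, minlength=n_groups)

    beta0 = 0.0
    beta = (S_j / np.maximum(n_j, 1.0)) if spec.likelihood else np.zeros(n_groups)
    tau = np.ones(n_groups)
    sigma_beta = spec.fix_sigma_beta if spec.fix_sigma_beta is not None else 1.0
    m_par, d_par = 1.0, 1.0
    step = {"sigma_beta": 0.5, "m": 0.5, "d": 0.5}
    accept = {k: 0 for k in step}
    proposed = {k: 0 for k in step}
    window = 50

    n_iter = cfg.burn_in + cfg.n_saved * cfg.thin
    out_beta = np.empty((cfg.n_saved, n_groups))
    out_beta0 = np.empty(cfg.n_saved)
    out_tau = np.empty((cfg.n_saved, n_groups))
    out_sig = np.empty(cfg.n_saved)
    out_m = np.empty(cfg.n_saved)
    out_d = np.empty(cfg.n_saved)
    saved = 0

    for it in range(n_iter):
        adapting = it < cfg.burn_in
        s_G = m_par**2 / d_par**2
        r_G = m_par / d_par**2

        if spec.likelihood:
            # beta0 | rest (flat prior)
            prec0 = float(np.sum(n_j * tau))
            mean0 = float(np.sum(tau * (S_j - n_j * beta))) / prec0
            beta0 = rng.normal(mean0, 1.0 / math.sqrt(prec0))
            # beta_j | rest (conjugate normal with N(0, sigma_beta^2) prior)
            prec = n_j * tau + 1.0 / sigma_beta**2
            mean = tau * (S_j - n_j * beta0) / prec
            beta = rng.normal(mean, 1.0 / np.sqrt(prec))
            # tau_j | rest (conjugate gamma)
            resid = z - beta0 - beta[codes]
            ssr = np.bincount(codes, weights=resid**2, minlength=n_groups)
            if spec.pool_variances:
                t = rng.gamma(s_G + 0.5 * z.size, 1.0 / (r_G + 0.5 * float(ssr.sum())))
                tau = np.full(n_groups, t)
            else:
                tau = rng.gamma(s_G + 0.5 * n_j, 1.0 / (r_G + 0.5 * ssr))
        else:
            beta = rng.normal(0.0, sigma_beta, size=n_groups)
            # tiny shapes can underflow gamma draws to exactly 0
            tau = np.maximum(rng.gamma(s_G, 1.0 / r_G, size=n_groups), 1e-300)

        # sigma_beta | beta: log-scale random walk under the folded-t prior
        if spec.fix_sigma_beta is None:
            ss_beta = float(np.sum(beta**2))

            def logpost_sigma(s):
                return (
                    -n_groups * math.log(s)
                    - 0.5 * ss_beta / s**2
                    + _log_folded_t(s, spec.nu_beta, spec.A_beta)
                    + math.log(s)  # Jacobian of the log transform
                )

            for _ in range(3):
                prop = sigma_beta * math.exp(step["sigma_beta"] * rng.normal())
                proposed["sigma_beta"] += 1
                if math.log(rng.random()) < logpost_sigma(prop) - logpost_sigma(sigma_beta):
                    sigma_beta = prop
                    accept["sigma_beta"] += 1

        # joint (sigma_beta, beta) scale move: random walks on sigma_beta
        # alone get trapped in the funnel at small sigma_beta when few
        # genotypes inform it; rescaling both together restores mixing.
        # For gamma = exp(eps): accept with  L(gamma*beta)/L(beta) *
        # p(gamma*sigma)/p(sigma) * gamma  (prior normal terms cancel).
        if spec.fix_sigma_beta is None and spec.likelihood:
            gamma = math.exp(0.3 * rng.normal())
            resid_prop = z - beta0 - gamma * beta[codes]
            ssr_prop = np.bincount(codes, weights=resid_prop**2, minlength=n_groups)
            resid_cur = z - beta0 - beta[codes]
            ssr_cur = np.bincount(codes, weights=resid_cur**2, minlength=n_groups)
            log_acc = (
                -0.5 * float(np.sum(tau * (ssr_prop - ssr_cur)))
                + _log_folded_t(gamma * sigma_beta, spec.nu_beta, spec.A_beta)
                - _log_folded_t(sigma_beta, spec.nu_beta, spec.A_beta)
                + math.log(gamma)
            )
            if math.log(rng.random()) < log_acc:
                beta = gamma * beta
                sigma_beta = gamma * sigma_beta

        # m, d | tau: log-scale random walks on the sufficient statistics
        tau_eff = tau[:1] if spec.pool_variances else tau
        J = tau_eff.size
        sum_log_tau = float(np.sum(np.log(tau_eff)))
        sum_tau = float(np.sum(tau_eff))

        def logpost_md(mv, dv):
            s = mv**2 / dv**2
            r = mv / dv**2
            lp = J * (s * math.log(r) - math.lgamma(s))
            lp += (s - 1.0) * sum_log_tau - r * sum_tau
            lp += _log_gamma_pdf(mv, spec.s_m, spec.r_m)
            lp += _log_gamma_pdf(dv, spec.s_d, spec.r_d)
            return lp

        cur = logpost_md(m_par, d_par)
        for _ in range(3):  # extra sub-sweeps: m and d mix slowly otherwise
            prop_m = m_par * math.exp(step["m"] * rng.normal())
            proposed["m"] += 1
            proposed["d"] += 1
            if math.log(rng.random()) < logpost_md(prop_m, d_par) - cur + math.log(prop_m / m_par):
                m_par = prop_m
                accept["m"] += 1
                cur = logpost_md(m_par, d_par)
            prop_d = d_par * math.exp(step["d"] * rng.normal())
            if math.log(rng.random()) < logpost_md(m_par, prop_d) - cur + math.log(prop_d / d_par):
                d_par = prop_d
                accept["d"] += 1
                cur = logpost_md(m_par, d_par)

        if adapting and (it + 1) % window == 0:
            for key in step:
                if proposed[key]:
                    rate = accept[key] / proposed[key]
                    step[key] = float(np.clip(step[key] * math.exp(rate - 0.44), 1e-3, 10.0))
                accept[key] = 0
                proposed[key] = 0

        if not adapting and (it - cfg.burn_in + 1) % cfg.thin == 0:
            # identifiability sweep: fold the mean effect into the intercept
            shift = float(np.mean(beta))
            out_beta[saved] = beta - shift
            out_beta0[saved] = beta0 + shift
            out_tau[saved] = tau
            out_sig[saved] = sigma_beta
            out_m[saved] = m_par
            out_d[saved] = d_par
            saved += 1

    return out_beta, out_beta0, out_tau, out_sig, out_m, out_d


def sample_posterior(
    table: pd.DataFrame,
    spec: HierarchicalModelSpec | None = None,
    cfg: McmcConfig | None = None,
    response: str = "rate_mm_per_hr",
    check_convergence: bool = True,
) -> PosteriorDraws:
    """Draw from the joint posterior for one environment cell.

    ``table`` must hold one environmental cell (a single env_param/setting
    combination when those columns are present) with >= 2 genotypes and
    >= 2 non-missing observations per genotype.
    """
    spec = spec or HierarchicalModelSpec()
    cfg = cfg or McmcConfig()
    df = table[table[response].notna()]
    if "missing_flag" in df.columns:
        df = df[df["missing_flag"] == 0]
    for col in ("env_param", "setting"):
        if col in df.columns and df[col].nunique() > 1:
            raise ValidationError(f"table spans multiple {col} values; fit one cell")
    counts = df.groupby("genotype")[response].count()
    if len(counts) < 2:
        raise ValidationError("need >= 2 genotypes")
    if (counts < 2).any():
        bad = sorted(counts[counts < 2].index)
        raise ValidationError(f"genotypes with <2 observations: {bad}")

    genotypes = sorted(counts.index)
    codes = pd.Categorical(df["genotype"], categories=genotypes).codes.astype(int)
    z, y_mean, y_sd = standardize(df[response].to_numpy())

    chains = [
        _run_chain(z, codes, len(genotypes), spec, cfg, chain)
        for chain in range(cfg.n_chains)
    ]
    draws = PosteriorDraws(
        genotypes=list(genotypes),
        beta_std=np.stack([c[0] for c in chains]),
        beta0_std=np.stack([c[1] for c in chains]),
        tau=np.stack([c[2] for c in chains]),
        sigma_beta=np.stack([c[3] for c in chains]),
        m=np.stack([c[4] for c in chains]),
        d=np.stack([c[5] for c in chains]),
        y_mean=y_mean,
        y_sd=y_sd,
        config=cfg,
        spec=spec,
    )
    if check_convergence and cfg.n_chains >= 2:
        diag = convergence_diagnostics(draws)
        draws.diagnostics = diag
        if not diag["pass"]:
            draws.flagged = True
            warnings.warn(
                f"MCMC convergence diagnostics failed "
                f"(max rhat {diag['max_rhat']:.3f}, min ess {diag['min_ess']:.0f})"
            )
    return draws


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ``ceil(mass * n)`` sorted draws.

    Ties resolve to the interval with the lowest start.
    """
    samples = np.sort(np.asarray(samples, dtype=float).ravel())
    n = samples.size
    if n < 100:
        raise ValidationError("need >= 100 draws for an HPD interval")
    if not 0.0 < mass < 1.0:
        raise ValidationError("mass must lie in (0, 1)")
    k = math.ceil(mass * n)
    widths = samples[k - 1 :] - samples[: n - k + 1]
    i = int(np.argmin(widths))
    return float(samples[i]), float(samples[i + k - 1])


def compute_contrast(
    draws: PosteriorDraws, mutant: str, control: str, mass: float = 0.95
) -> ContrastResult:
    """Mutant-minus-control effect difference on the mm/hr scale.

    Negative means the mutant grows slower than the control; significant
    means the HPD interval of the difference excludes zero.
    """
    diff = draws.effect_draws(mutant) - draws.effect_draws(control)
    low, high = hpd_interval(diff, mass)
    return ContrastResult(
        mutant=mutant,
        control=control,
        mean_diff=float(np.mean(diff)),
        hpd_low=low,
        hpd_high=high,
        significant=not (low <= 0.0 <= high),
    )


def convergence_diagnostics(
    draws: PosteriorDraws, rhat_max: float = 1.01, ess_min: float = 400.0
) -> dict:
    """Rank-normalized split R-hat and bulk ESS per parameter (via ArviZ)."""
    if draws.beta_std.shape[0] < 2:
        raise ValidationError("R-hat requires >= 2 chains")
    import arviz as az

    data = {
        "beta": draws.beta_std,
        "tau": draws.tau,
        "sigma_beta": draws.sigma_beta,
        "m": draws.m,
        "d": draws.d,
    }
    ds = az.convert_to_dataset(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(ds, method="rank")
        ess_ds = az.ess(ds, method="bulk")
    rhat = {k: np.asarray(v.values) for k, v in rhat_ds.data_vars.items()}
    ess = {k: np.asarray(v.values) for k, v in ess_ds.data_vars.items()}
    max_rhat = float(max(np.max(v) for v in rhat.values()))
    min_ess = float(min(np.min(v) for v in ess.values()))
    return {
        "rhat": rhat,
        "ess": ess,
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "pass": bool(max_rhat < rhat_max and min_ess > ess_min),
    }
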