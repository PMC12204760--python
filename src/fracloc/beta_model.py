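"""Estimation of beta, the cytosolic fraction of total cellular RNA volume.

The measurement model regresses whole-cell FPKM on the nuclear and cytosolic
FPKMs of each transcript with a single mixing coefficient and no intercept::

    fpkm_w(i) = (1 - beta) * fpkm_n(i) + beta * fpkm_c(i) + error(i)
    error(i) ~ StudentT(nu, 0, sigma)

with priors beta ~ Beta(2, 2), nu ~ Gamma(shape=2, rate=0.1) and
sigma ~ Exponential(rate = 1/s) where s is the sample standard deviation of
fpkm_w. The posterior is sampled with NUTS on the unconstrained scale
(logit beta, log nu, log sigma); the point estimate is the mode of a
boundary-reflected KDE of the pooled beta draws.

A box-constrained least-squares baseline (`estimate_beta_constrained_ls`)
is provided for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, expit, gammaln, logit
from scipy.stats import gaussian_kde

from fracloc._nuts import sample_nuts
from fracloc.errors import DegenerateDataError, FormatError

logger = logging.getLogger(__name__)


@dataclass
class BetaModelConfig:
    """Sampler and prior settings (defaults follow the reference analysis)."""

    chains: int = 4
    draws_per_chain: int = 6000
    warmup: int = 2000
    adapt_delta: float = 0.9
    max_treedepth: int = 10
    seed: int = 0
    prior_beta: tuple[float, float] = (2.0, 2.0)
    prior_nu: tuple[float, float] = (2.0, 0.1)  # Gamma(shape, rate)

    def __post_init__(self) -> None:
        if self.warmup >= self.draws_per_chain:
            raise ValueError("warmup must be smaller than draws_per_chain")
        if not 0.0 < self.adapt_delta < 1.0:
            raise ValueError("adapt_delta must be in (0, 1)")
        for name in ("chains", "draws_per_chain", "warmup", "max_treedepth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.prior_beta) <= 0 or min(self.prior_nu) <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")


@dataclass
class BetaPosterior:
    """Posterior summary for beta with raw draws and sampler diagnostics."""

    draws: np.ndarray                 # pooled post-warmup beta draws
    map_estimate: float
    posterior_mean: float
    credible_interval_95: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)
    divergence_count: int = 0
    n_transcripts: int = 0
    config: BetaModelConfig | None = None

    def to_dict(self) -> dict:
        out = {
            "map": self.map_estimate,
            "mean": self.posterior_mean,
            "ci95": list(self.credible_interval_95),
            "diagnostics": self.diagnostics,
            "divergences": self.divergence_count,
            "n_transcripts": self.n_transcripts,
        }
        if self.config is not None:
            out["config"] = {
                "chains": self.config.chains,
                "draws_per_chain": self.config.draws_per_chain,
                "warmup": self.config.warmup,
                "adapt_delta": self.config.adapt_delta,
                "max_treedepth": self.config.max_treedepth,
                "seed": self.config.seed,
            }
        return out


@dataclass
class ConstrainedLSResult:
    """Box-constrained least-squares estimate of beta."""

    beta: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.beta


def _validate_triplet(fpkm_w, fpkm_n, fpkm_c, min_len=1):
    w = np.asarray(fpkm_w, float)
    n = np.asarray(fpkm_n, float)
    c = np.asarray(fpkm_c, float)
    if not (w.shape == n.shape == c.shape) or w.ndim != 1:
        raise FormatError("fpkm vectors must be 1-D and of equal length")
    if w.size < min_len:
        raise FormatError(f"need at least {min_len} transcripts")
    if not (np.isfinite(w).all() and np.isfinite(n).all() and np.isfinite(c).all()):
        raise FormatError("fpkm vectors contain non-finite values")
    if (w < 0).any() or (n < 0).any() or (c < 0).any():
        raise FormatError("fpkm vectors must be non-negative")
    return w, n, c


def _make_logpost(a, d, s, prior_beta, prior_nu):
    """Log posterior and gradient on theta = (logit beta, log nu, log sigma).

    a = fpkm_w - fpkm_n, d = fpkm_c - fpkm_n, so the residual is a - beta*d.
    Includes change-of-variable Jacobians.
    """
    n_obs = a.size
    pb_a, pb_b = prior_beta
    nu_shape, nu_rate = prior_nu

    def logpost(theta):
        x, y, z = theta
        beta = expit(x)
        nu = np.exp(y)
        sigma = np.exp(z)
        e = a - beta * d
        e2 = e * e
        nss = nu * sigma * sigma
        q = nss + e2
        log_term = np.log1p(e2 / nss)

        ll = n_obs * (
            gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(nu * np.pi) - z
        ) - (nu + 1) / 2 * log_term.sum()
        # priors + Jacobians of the transforms
        lp = (
            pb_a * np.log(beta) + pb_b * np.log1p(-beta)   # Beta + logit Jacobian
            + nu_shape * y - nu_rate * nu                   # Gamma + log Jacobian
            + z - sigma / s                                 # Exponential + log Jacobian
        )

        dl_dbeta = (nu + 1) * np.sum(e * d / q)
        dl_dx = dl_dbeta * beta * (1 - beta) + pb_a * (1 - beta) - pb_b * beta

        dl_dnu = (
            n_obs * (0.5 * digamma((nu + 1) / 2) - 0.5 * digamma(nu / 2) - 0.5 / nu)
            - 0.5 * log_term.sum()
            + (nu + 1) / (2 * nu) * np.sum(e2 / q)
        )
        dl_dy = dl_dnu * nu + nu_shape - nu_rate * nu

        dl_dsigma = -n_obs / sigma + (nu + 1) / sigma * np.sum(e2 / q)
        dl_dz = dl_dsigma * sigma + 1 - sigma / s

        return float(ll + lp), np.array([dl_dx, dl_dy, dl_dz])

    return logpost


def _laplace_inv_mass(logpost, x0):
    """Diagonal inverse-mass from curvature at (an approximation of) the mode."""
    from scipy.optimize import minimize

    neg = lambda t: tuple(-v for v in logpost(t))
    try:
        res = minimize(neg, x0, jac=True, method="L-BFGS-B", options={"maxiter": 200})
        xm = res.x
    except Exception:  # pragma: no cover - optimizer hiccups fall back to x0
        xm = x0
    h = 1e-4
    curv = np.empty(xm.size)
    for j in range(xm.size):
        step = np.zeros_like(xm)
        step[j] = h
        _, gp = logpost(xm + step)
        _, gm = logpost(xm - step)
        curv[j] = -(gp[j] - gm[j]) / (2 * h)
    curv = np.where(np.isfinite(curv) & (curv > 1e-10), curv, 1.0)
    # mass = curvature => roughly unit posterior geometry
    return xm, 1.0 / curv


def estimate_beta_bayes(
    fpkm_w, fpkm_n, fpkm_c, config: BetaModelConfig | None = None
) -> BetaPosterior:
    """Sample the posterior of (beta, nu, sigma) and summarize beta.

    Returns pooled post-warmup beta draws, the KDE-mode MAP, posterior mean,
    central 95% interval, split-R-hat/ESS diagnostics and the divergence
    count. A warning is logged if R-hat for beta exceeds 1.01.
    """
    import arviz as az

    if config is None:
        config = BetaModelConfig()
    w, n, c = _validate_triplet(fpkm_w, fpkm_n, fpkm_c, min_len=2)
    if not (w.any() or n.any() or c.any()):
        raise DegenerateDataError("all fpkm values are zero")
    s = float(np.std(w, ddof=1))
    if s == 0:
        raise DegenerateDataError(
            "fpkm_w is constant; the sigma prior scale is undefined"
        )

    a = w - n
    d = c - n
    logpost = _make_logpost(a, d, s, config.prior_beta, config.prior_nu)

    # starting point: constrained-LS beta, moderate nu, robust residual scale
    beta0 = float(np.clip(estimate_beta_constrained_ls(w, n, c).beta, 0.05, 0.95))
    resid = a - beta0 * d
    sigma0 = float(np.median(np.abs(resid)) * 1.4826) or s
    x0 = np.array([logit(beta0), np.log(10.0), np.log(sigma0)])
    x_mode, inv_mass = _laplace_inv_mass(logpost, x0)

    n_kept = config.draws_per_chain - config.warmup
    seed_seq = np.random.SeedSequence(config.seed)
    chain_draws = np.empty((config.chains, n_kept, 3))
    divergences = 0
    for ci, child in enumerate(seed_seq.spawn(config.chains)):
        rng = np.random.default_rng(child)
        start = x_mode + 0.5 * rng.normal(size=3) * np.sqrt(inv_mass)
        chain = sample_nuts(
            logpost,
            start,
            n_warmup=config.warmup,
            n_draws=n_kept,
            rng=rng,
            adapt_delta=config.adapt_delta,
            max_treedepth=config.max_treedepth,
            inv_mass=inv_mass,
        )
        chain_draws[ci] = chain.draws
        divergences += chain.divergences

    beta_chains = expit(chain_draws[:, :, 0])
    diagnostics = {}
    for j, name in enumerate(("beta", "nu", "sigma")):
        arr = chain_draws[:, :, j] if j else beta_chains
        diagnostics[name] = {
            "rhat": float(az.rhat(arr)),
            "ess": float(az.ess(arr)),
        }
    if diagnostics["beta"]["rhat"] > 1.01:
        logger.warning(
            "R-hat for beta is %.4f (> 1.01); treat the estimate with caution",
            diagnostics["beta"]["rhat"],
        )
    if divergences:
        logger.warning("%d divergent transitions after warmup", divergences)

    pooled = beta_chains.reshape(-1)
    lo, hi = np.percentile(pooled, [2.5, 97.5])
    return BetaPosterior(
        draws=pooled,
        map_estimate=map_from_draws(pooled),
        posterior_mean=float(pooled.mean()),
        credible_interval_95=(float(lo), float(hi)),
        diagnostics=diagnostics,
        divergence_count=divergences,
        n_transcripts=int(w.size),
        config=config,
    )


def map_from_draws(draws, grid_size: int = 512) -> float:
    """MAP of beta from MCMC draws: mode of a Gaussian KDE evaluated on a
    uniform grid over [0, 1] with boundary reflection.

    The bandwidth factor is n^(-1/7) rather than Scott's n^(-1/5): mode
    estimation is optimized by a larger bandwidth than density estimation,
    and the oversmoothed rate roughly halves the mode jitter on flat-topped
    distributions at negligible bias for the concentrated posteriors this
    is applied to.
    """
    draws = np.asarray(draws, float)
    if draws.size < 100:
        raise FormatError("need at least 100 draws for a stable density estimate")
    if ((draws <= 0) | (draws >= 1)).any():
        raise FormatError("draws must lie strictly inside (0, 1)")
    if np.std(draws) < 1.0 / grid_size:
        # posterior narrower than the grid spacing: the grid-mode is the median
        return float(np.median(draws))
    kde = gaussian_kde(draws, bw_method=draws.size ** (-1.0 / 7.0))
    grid = np.linspace(0.0, 1.0, grid_size)
    density = kde(grid) + kde(-grid) + kde(2.0 - grid)
    return float(grid[int(np.argmax(density))])


def estimate_beta_constrained_ls(fpkm_w, fpkm_n, fpkm_c) -> ConstrainedLSResult:
    """Least-squares beta under the same no-intercept model, clamped to [0, 1].

    Closed form: beta = clamp(sum((w-n)(c-n)) / sum((c-n)^2), 0, 1). If the
    nuclear and cytosolic vectors coincide the objective is constant in beta;
    0.5 is returned with ``degenerate=True``.
    """
    w, n, c = _validate_triplet(fpkm_w, fpkm_n, fpkm_c, min_len=1)
    d = c - n
    denom = float(np.dot(d, d))
    if denom == 0.0:
        return ConstrainedLSResult(beta=0.5, degenerate=True)
    beta = float(np.clip(np.dot(w - n, d) / denom, 0.0, 1.0))
    return ConstrainedLSResult(beta=beta)
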