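"""Posterior sampling and CMC-uncertainty quantification.

The posterior over the isotherm parameters theta = (gamma0, a, k, c*) is
sampled with an ensemble MCMC sampler (a vectorized mixture of the
affine-invariant stretch move and differential-evolution moves) run in an
unconstrained reparameterization: interval-bounded parameters are mapped to
the real line with a logit transform (through ln c* for the log-uniform CMC
prior), with the Jacobian correction included in the target density.  The
ensemble is initialized by likelihood-weighted importance resampling of a
prior pool (with a Nelder--Mead polish when the weights degenerate), so both
diffuse early-campaign posteriors and sharply concentrated late-campaign
posteriors start near stationarity.  The contract is distributional — any
chain whose stationary law is the posterior is acceptable — and the
ensemble's walkers play the role of chains for the split-R-hat /
effective-sample-size convergence diagnostics.  The sampler is implemented
in-process (vectorized numpy) because the information-gain inner loop runs
thousands of short warm-started re-fits per campaign; its correctness is
cross-checked in the test suite against emcee and against dense-grid
posteriors.

The marginal posterior of the CMC is a Gaussian kernel density estimate on
the c* draws (on ln c* under the log-uniform prior), with a fixed Silverman
bandwidth variant, clipped and renormalized over the prior support.  Its
differential entropy, computed by adaptive quadrature, is the campaign's
uncertainty metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.special import expit, log_expit, ndtr

from .isotherm import PARAM_NAMES, Dataset, NoiseModel, PriorSpec

__all__ = [
    "SamplerSettings",
    "PosteriorSamples",
    "MarginalDensity",
    "DiagnosticReport",
    "sample_posterior",
    "convergence_diagnostics",
    "marginal_cmc_density",
    "differential_entropy",
    "credible_interval",
    "posterior_mode_cmc",
    "ModeResult",
    "split_rhat",
    "effective_sample_size",
]

_LOG_2PI = math.log(2.0 * math.pi)

# Hard convergence threshold: above this the fit is flagged nonconverged.
RHAT_HARD = 1.2
# Pass thresholds for the routine diagnostic report.
RHAT_PASS = 1.05
ESS_PASS = 100.0


# ---------------------------------------------------------------------------
# settings / samples containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration.

    ``n_chains`` is the number of ensemble walkers; each contributes
    ``n_draws`` retained draws after ``n_warmup`` discarded steps, so the
    total sample size is N_s = n_chains * n_draws.  The ensemble move needs
    at least 2 x (number of parameters) = 8 walkers.
    """

    n_chains: int = 32
    n_warmup: int = 1000
    n_draws: int = 400
    seed: int = 0
    init_strategy: str = "prior_draw"  # or "warm_start"
    thin: int = 1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (between-chain diagnostics)")
        if self.n_warmup < 0 or self.n_draws < 1:
            raise ValueError("n_warmup must be >= 0 and n_draws >= 1")
        if self.init_strategy not in ("prior_draw", "warm_start"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class DiagnosticReport:
    rhat: dict[str, float]
    ess: dict[str, float]
    passed: bool

    def to_dict(self) -> dict:
        return {"rhat": dict(self.rhat), "ess": dict(self.ess), "passed": bool(self.passed)}


@dataclass
class PosteriorSamples:
    """MCMC draws of theta with chain labels and convergence diagnostics.

    ``draws`` has shape (N_s, 4) with columns (gamma0, a, k, cmc); ``chain_id``
    labels the walker each row came from (balanced partition).
    """

    draws: np.ndarray
    chain_id: np.ndarray
    diagnostics: DiagnosticReport
    converged: bool = True

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        self.chain_id = np.asarray(self.chain_id, dtype=int)
        if self.draws.ndim != 2 or self.draws.shape[1] != 4:
            raise ValueError("draws must have shape (N_s, 4)")
        if self.draws.shape[0] == 0:
            raise ValueError("draws must be non-empty")
        if self.chain_id.shape[0] != self.draws.shape[0]:
            raise ValueError("chain_id must align with draws")

    @property
    def n_samples(self) -> int:
        return self.draws.shape[0]

    def column(self, parameter: str) -> np.ndarray:
        return self.draws[:, PARAM_NAMES.index(parameter)]

    @property
    def cmc(self) -> np.ndarray:
        return self.column("cmc")

    def by_chain(self) -> np.ndarray:
        """Draws reshaped to (n_chains, n_draws, 4)."""
        chains = np.unique(self.chain_id)
        per = [self.draws[self.chain_id == c] for c in chains]
        n = min(p.shape[0] for p in per)
        return np.stack([p[:n] for p in per])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(PARAM_NAMES))
        df.insert(0, "chain", self.chain_id)
        df.insert(1, "draw", df.groupby("chain").cumcount())
        return df


# ---------------------------------------------------------------------------
# unconstrained reparameterization
# ---------------------------------------------------------------------------


def _cmc_log_space(prior: PriorSpec) -> bool:
    return prior.cmc_prior_kind == "log_uniform"


def theta_to_unconstrained(theta_arr: np.ndarray, prior: PriorSpec) -> np.ndarray:
    """Map theta rows (..., 4) to the unconstrained sampling space."""
    th = np.atleast_2d(np.asarray(theta_arr, dtype=float))
    x = np.empty_like(th)
    x[:, 0] = th[:, 0]

    def logit(u):
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        return np.log(u) - np.log1p(-u)

    a_lo, a_hi = prior.a_bounds
    x[:, 1] = logit((th[:, 1] - a_lo) / (a_hi - a_lo))
    k_lo, k_hi = prior.k_bounds
    x[:, 2] = logit((th[:, 2] - k_lo) / (k_hi - k_lo))
    c_lo, c_hi = prior.cmc_bounds
    if _cmc_log_space(prior):
        u_lo, u_hi = math.log(c_lo), math.log(c_hi)
        x[:, 3] = logit((np.log(th[:, 3]) - u_lo) / (u_hi - u_lo))
    else:
        x[:, 3] = logit((th[:, 3] - c_lo) / (c_hi - c_lo))
    return x if np.asarray(theta_arr).ndim == 2 else x[0]


def unconstrained_to_theta(x: np.ndarray, prior: PriorSpec) -> np.ndarray:
    """Inverse of :func:`theta_to_unconstrained` (vectorized)."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    th = np.empty_like(X)
    th[:, 0] = X[:, 0]
    a_lo, a_hi = prior.a_bounds
    th[:, 1] = a_lo + (a_hi - a_lo) * expit(X[:, 1])
    k_lo, k_hi = prior.k_bounds
    th[:, 2] = k_lo + (k_hi - k_lo) * expit(X[:, 2])
    c_lo, c_hi = prior.cmc_bounds
    if _cmc_log_space(prior):
        u_lo, u_hi = math.log(c_lo), math.log(c_hi)
        th[:, 3] = np.exp(u_lo + (u_hi - u_lo) * expit(X[:, 3]))
    else:
        th[:, 3] = c_lo + (c_hi - c_lo) * expit(X[:, 3])
    return th if np.asarray(x).ndim == 2 else th[0]


def _log_post_unconstrained(
    X: np.ndarray, data: Dataset, prior: PriorSpec, noise: NoiseModel
) -> np.ndarray:
    """Vectorized log target in the unconstrained space (posterior + Jacobian).

    Operates on a (W, 4) batch of walker positions; the uniform-prior
    normalization constants are kept so the value equals
    log_unnormalized_posterior(theta) + log|d theta / d x|.
    """
    X = np.atleast_2d(X)
    th = unconstrained_to_theta(X, prior)
    g0, a, k, cmc = th[:, 0], th[:, 1], th[:, 2], th[:, 3]

    # gamma0 Gaussian prior
    z = (g0 - prior.gamma0_mean) / prior.gamma0_sd
    lp = -0.5 * _LOG_2PI - math.log(prior.gamma0_sd) - 0.5 * z * z

    # uniform priors (constants) + logit Jacobians: log w + log sig + log(1-sig)
    def logit_jac(col, width):
        return math.log(width) + log_expit(col) + log_expit(-col)

    a_lo, a_hi = prior.a_bounds
    k_lo, k_hi = prior.k_bounds
    c_lo, c_hi = prior.cmc_bounds
    lp = lp - math.log(a_hi - a_lo) + logit_jac(X[:, 1], a_hi - a_lo)
    lp = lp - math.log(k_hi - k_lo) + logit_jac(X[:, 2], k_hi - k_lo)
    if _cmc_log_space(prior):
        u_lo, u_hi = math.log(c_lo), math.log(c_hi)
        width = u_hi - u_lo
        # prior on c*: 1/(c* width); Jacobian dc/dx = c* * width * sig(1-sig)
        lp = lp - np.log(cmc) - math.log(width) + np.log(cmc) + logit_jac(X[:, 3], width)
    else:
        lp = lp - math.log(c_hi - c_lo) + logit_jac(X[:, 3], c_hi - c_lo)

    # likelihood
    n = len(data)
    if n:
        c_obs = data.concentrations
        y_obs = data.surface_tensions
        pred = g0[:, None] - a[:, None] * np.log1p(k[:, None] * np.minimum(c_obs[None, :], cmc[:, None]))
        s = noise.sigma
        lp = lp - 0.5 * n * (_LOG_2PI + 2.0 * math.log(s)) - 0.5 * np.sum(((pred - y_obs[None, :]) / s) ** 2, axis=1)
    return np.where(np.isfinite(lp), lp, -np.inf)


def _draw_prior_thetas(prior: PriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    g0 = prior.gamma0_mean + prior.gamma0_sd * rng.standard_normal(n)
    a = rng.uniform(*prior.a_bounds, size=n)
    k_lo, k_hi = prior.k_bounds
    k = rng.uniform(max(k_lo, 1e-9 * k_hi), k_hi, size=n)
    c_lo, c_hi = prior.cmc_bounds
    if _cmc_log_space(prior):
        cmc = np.exp(rng.uniform(math.log(c_lo), math.log(c_hi), size=n))
    else:
        cmc = rng.uniform(c_lo, c_hi, size=n)
    return np.column_stack([g0, a, k, cmc])


# ---------------------------------------------------------------------------
# diagnostics (numpy implementations; arviz is the test oracle)
# ---------------------------------------------------------------------------


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of one parameter from an array of shape (n_chains, n_draws).

    Each chain is split in half; the statistic compares within- to
    between-chain variance.  Zero-variance input yields nan (constant
    everywhere) or +inf (chains constant but unequal), never an exception.
    """
    chains = np.asarray(chains, dtype=float)
    c, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    parts = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m = parts.shape[1]
    within = parts.var(axis=1, ddof=1).mean()
    between = m * parts.mean(axis=1).var(ddof=1)
    if within == 0:
        return float("nan") if between == 0 else float("inf")
    var_hat = (m - 1) / m * within + between / m
    return float(math.sqrt(var_hat / within))


def effective_sample_size(chains: np.ndarray) -> float:
    """Multi-chain effective sample size via Geyer's initial monotone sequence.

    Classic (non-rank-normalized) ESS of the mean, matching
    ``arviz.ess(..., method="mean")`` up to small implementation details.
    """
    chains = np.asarray(chains, dtype=float)
    c, n = chains.shape
    if n < 4:
        return float("nan")
    means = chains.mean(axis=1, keepdims=True)
    within = chains.var(axis=1, ddof=1).mean()
    var_hat = (n - 1) / n * within + chains.mean(axis=1).var(ddof=1) if c > 1 else within
    if var_hat == 0 or within == 0:
        return float("nan")

    # per-chain autocovariance by FFT
    centered = chains - means
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(centered, n=nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, :n].real / n
    mean_acov = acov.mean(axis=0)

    rho = 1.0 - (within - mean_acov) / var_hat
    rho[0] = 1.0
    # Geyer: sums of adjacent pairs, truncated at first negative, monotone
    max_pairs = (n - 1) // 2
    tau = 1.0
    prev = float("inf")
    for t in range(1, max_pairs + 1):
        pair = rho[2 * t - 1] + rho[2 * t] if 2 * t < n else rho[2 * t - 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau += 2.0 * pair
    return float(c * n / tau)


def _split_rhat_multi(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat for a batch of ensembles: (B, C, N, d) -> (B, d)."""
    B, C, N, d = chains.shape
    half = N // 2
    if half < 2:
        return np.full((B, d), np.nan)
    parts = np.concatenate([chains[:, :, :half], chains[:, :, half : 2 * half]], axis=1)
    m = parts.shape[2]
    within = parts.var(axis=2, ddof=1).mean(axis=1)
    between = m * parts.mean(axis=2).var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (m - 1) / m * within + between / m
        rhat = np.sqrt(var_hat / within)
        rhat = np.where(within == 0, np.where(between == 0, np.nan, np.inf), rhat)
    return rhat


def convergence_diagnostics(samples: PosteriorSamples) -> DiagnosticReport:
    """Split-R-hat and ESS per parameter with an overall pass flag."""
    if np.unique(samples.chain_id).size < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    ch = samples.by_chain()  # (C, N, 4)
    rhat, ess = {}, {}
    for i, name in enumerate(PARAM_NAMES):
        rhat[name] = split_rhat(ch[:, :, i])
        ess[name] = effective_sample_size(ch[:, :, i])
    passed = all(
        np.isfinite(r) and r < RHAT_PASS for r in rhat.values()
    ) and all(np.isfinite(e) and e > ESS_PASS for e in ess.values())
    return DiagnosticReport(rhat=rhat, ess=ess, passed=passed)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _run_ensemble_batch(
    log_prob,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    thin: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized ensemble MCMC: stretch and differential-evolution moves.

    Runs ``B`` independent ensembles simultaneously (``x0`` has shape
    (B, W, d); walkers only ever interact within their own ensemble), which
    amortizes the per-step numpy overhead across the many short warm-started
    re-fits of the information-gain inner loop.  Each ensemble is split into
    two half-ensembles updated alternately; a walker update proposes either
    an affine-invariant stretch along a line to a random walker of the other
    half (Hastings factor z^(d-1)) or a symmetric differential-evolution
    jump along the difference of two distinct walkers of the other half
    (with occasional full-length mode-hopping jumps).  Only the thinned
    post-warmup states are retained; returns shape (n_draws, B, W, d).
    """
    x = np.array(x0, dtype=float)
    B, W, d = x.shape
    h = W // 2
    lp = log_prob(x)
    out = np.empty((n_draws, B, W, d))
    g_de = 2.38 / math.sqrt(2 * d)
    a_stretch = 2.0
    n_steps = n_warmup + n_draws * thin
    kept = 0
    for t in range(n_steps):
        for lo, hi, olo, ohi in ((0, h, h, W), (h, W, 0, h)):
            xa = x[:, lo:hi]
            xo = x[:, olo:ohi]
            wa, wo = hi - lo, ohi - olo
            if rng.random() < 0.5:  # stretch move
                j = rng.integers(wo, size=(B, wa))
                xoj = np.take_along_axis(xo, j[:, :, None], axis=1)
                z = ((a_stretch - 1.0) * rng.random((B, wa)) + 1.0) ** 2 / a_stretch
                y = xoj + z[:, :, None] * (xa - xoj)
                log_hastings = (d - 1) * np.log(z)
            else:  # differential evolution
                i1 = rng.integers(wo, size=(B, wa))
                i2 = (i1 + 1 + rng.integers(wo - 1, size=(B, wa))) % wo
                diff = np.take_along_axis(xo, i1[:, :, None], axis=1) - np.take_along_axis(
                    xo, i2[:, :, None], axis=1
                )
                gamma = 1.0 if rng.random() < 0.1 else g_de
                y = xa + gamma * diff + 1e-5 * rng.standard_normal((B, wa, d))
                log_hastings = 0.0
            lpy = log_prob(y)
            accept = np.log(rng.random((B, wa))) < log_hastings + lpy - lp[:, lo:hi]
            xa[accept] = y[accept]
            lp[:, lo:hi][accept] = lpy[accept]
        if t >= n_warmup and (t - n_warmup) % thin == thin - 1:
            out[kept] = x
            kept += 1
    return out[:kept]


# walker-position jitter floors in the unconstrained space (gamma0 lives on
# a ~1e-3 scale, the logit coordinates on a ~1 scale)
_JITTER_FLOOR = np.array([3e-4, 0.05, 0.05, 0.05])


def _profile_candidates(
    data: Dataset, prior: PriorSpec, noise: NoiseModel, n_c: int = 40, n_k: int = 40
) -> np.ndarray:
    """Profile-likelihood candidate parameter vectors on a (c*, k) grid.

    The change point makes the likelihood piecewise-smooth in c*, so local
    optimizers routinely settle in the wrong data segment.  For fixed
    (c*, k), however, the model is linear in (gamma0, a), and the
    gamma0-prior-penalized weighted least-squares profile has a closed form.
    Scanning a [log-]spaced (c*, k) grid therefore produces near-optimal
    representatives of every segment, which seed the ensemble across all
    plausible change-point locations.
    """
    c_lo, c_hi = prior.cmc_bounds
    if prior.cmc_prior_kind == "log_uniform":
        c_grid = np.geomspace(c_lo, c_hi, n_c + 2)[1:-1]
    else:
        c_grid = np.linspace(c_lo, c_hi, n_c + 2)[1:-1]
    k_lo, k_hi = prior.k_bounds
    k_grid = np.geomspace(max(k_lo, 1e-3), k_hi, n_k)

    c_obs = data.concentrations
    y = data.surface_tensions
    u = np.log1p(k_grid[None, :, None] * np.minimum(c_obs[None, None, :], c_grid[:, None, None]))
    wl2 = 1.0 / max(noise.sigma, 1e-12) ** 2
    wp2 = 1.0 / prior.gamma0_sd**2
    # normal equations for y = gamma0 - a*u, weighted rows + gamma0 prior row
    s11 = wl2 * len(data) + wp2
    s12 = -wl2 * u.sum(axis=2)
    s22 = wl2 * (u**2).sum(axis=2)
    b1 = wl2 * y.sum() + wp2 * prior.gamma0_mean
    b2 = -wl2 * (u * y[None, None, :]).sum(axis=2)
    det = s11 * s22 - s12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        g0 = (b1 * s22 - b2 * s12) / det
        a = (s11 * b2 - s12 * b1) / det
    a_lo, a_hi = prior.a_bounds
    eps_a = 1e-6 * (a_hi - a_lo)
    a = np.clip(np.nan_to_num(a, nan=a_lo), a_lo + eps_a, a_hi - eps_a)
    g0 = np.clip(np.nan_to_num(g0, nan=prior.gamma0_mean), 1e-6, None)
    cc, kk = np.meshgrid(c_grid, k_grid, indexing="ij")
    return np.column_stack([g0.ravel(), a.ravel(), kk.ravel(), cc.ravel()])


def _initial_ensemble(
    data: Dataset,
    prior: PriorSpec,
    noise: NoiseModel,
    nwalkers: int,
    rng: np.random.Generator,
    n_pool: int = 256,
) -> np.ndarray:
    """Ensemble initialization by posterior-weighted resampling of candidates.

    The candidate set is the union of prior draws and, when data exist,
    closed-form profile-likelihood optima on a (c*, k) grid (one per
    change-point segment).  Walkers are resampled proportionally to the
    candidates' posterior density and jittered, so diffuse early-campaign
    posteriors get walkers spread over the support while concentrated
    posteriors start in the correct segment.
    """
    th_pool = _draw_prior_thetas(prior, n_pool, rng)
    if len(data):
        th_pool = np.vstack([th_pool, _profile_candidates(data, prior, noise)])
    X = theta_to_unconstrained(th_pool, prior)
    lp = _log_post_unconstrained(X, data, prior, noise)
    w = np.exp(lp - lp.max())
    w_sum = w.sum()
    if not np.isfinite(w_sum) or w_sum <= 0:
        w = np.full(lp.size, 1.0 / lp.size)
    else:
        w /= w_sum
    idx = rng.choice(lp.size, size=nwalkers, p=w)
    x0 = X[idx]
    mean = np.average(X, weights=w, axis=0)
    sd = np.sqrt(np.average((X - mean) ** 2, weights=w, axis=0))
    jitter = np.maximum(0.05 * sd, _JITTER_FLOOR)
    return x0 + jitter * rng.standard_normal(x0.shape)


def sample_posterior(
    data: Dataset,
    prior: PriorSpec,
    noise: NoiseModel,
    settings: SamplerSettings,
    warm_start: Optional[PosteriorSamples] = None,
) -> PosteriorSamples:
    """Draw posterior samples of theta given the dataset.

    The ensemble is initialized by importance resampling of prior draws or,
    when ``settings.init_strategy == "warm_start"``, from a random subset of
    the supplied ``warm_start`` draws with a small jitter (used by the
    information-gain inner loop, where one added point moves the posterior
    little).  Identical seed and inputs give bit-identical draws.  A fit
    whose split-R-hat exceeds 1.2 across the board is returned flagged
    ``converged=False`` rather than raised, so callers decide.
    """
    ndim = 4
    nwalkers = settings.n_chains
    if nwalkers < 4 or nwalkers % 2:
        raise ValueError("the ensemble sampler needs an even n_chains >= 4")
    if settings.init_strategy == "warm_start" and warm_start is None:
        raise ValueError("warm_start samples required for init_strategy='warm_start'")

    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    if settings.init_strategy == "warm_start":
        idx = rng.integers(0, warm_start.n_samples, size=nwalkers)
        x0 = theta_to_unconstrained(warm_start.draws[idx], prior)
        scale = np.maximum(x0.std(axis=0), 1e-6)
        x0 = x0 + 0.05 * scale * rng.standard_normal(x0.shape)
    else:
        x0 = _initial_ensemble(data, prior, noise, nwalkers, rng)

    chain_x = _run_ensemble_batch(
        lambda X: _log_post_unconstrained(X.reshape(-1, ndim), data, prior, noise).reshape(X.shape[:2]),
        x0[None, :, :],
        settings.n_warmup,
        settings.n_draws,
        settings.thin,
        rng,
    )[:, 0]

    n_draws = chain_x.shape[0]
    theta_chains = unconstrained_to_theta(chain_x.reshape(-1, ndim), prior).reshape(chain_x.shape)

    # flatten walker-major so chain_id is balanced and contiguous
    th = np.transpose(theta_chains, (1, 0, 2)).reshape(nwalkers * n_draws, ndim)
    chain_id = np.repeat(np.arange(nwalkers), n_draws)

    samples = PosteriorSamples(
        draws=th,
        chain_id=chain_id,
        diagnostics=DiagnosticReport(rhat={}, ess={}, passed=False),
    )
    diag = convergence_diagnostics(samples)
    finite = [r for r in diag.rhat.values() if np.isfinite(r)]
    # hard failure only when every parameter's diagnostic is beyond the
    # threshold (non-finite means zero spread: degenerate but defined)
    samples.converged = any(r < RHAT_HARD for r in finite) if finite else True
    samples.diagnostics = diag
    return samples


# ---------------------------------------------------------------------------
# CMC marginal density, entropy, summaries
# ---------------------------------------------------------------------------


@dataclass
class MarginalDensity:
    """KDE of the CMC marginal, clipped and renormalized over the prior support.

    In ``space == "log"`` the density lives on u = ln(c*): ``evaluate``
    takes u and returns probability per log-unit, and ``support`` is
    (ln c*_min, ln c*_max).  In linear space everything is in mol/m^3.
    """

    centers: np.ndarray
    bandwidth: float
    support: tuple[float, float]
    space: str = "linear"
    _norm: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        lo, hi = self.support
        if not hi > lo:
            raise ValueError("support must have positive width")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        h = self.bandwidth
        # analytic mass of the unclipped KDE inside the support
        self._norm = float(np.mean(ndtr((hi - self.centers) / h) - ndtr((lo - self.centers) / h)))
        if self._norm <= 0:
            raise ValueError("KDE has no mass inside the support")

    def evaluate(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.support
        h = self.bandwidth
        z = (t_arr[:, None] - self.centers[None, :]) / h
        p = np.exp(-0.5 * z * z).sum(axis=1) / (self.centers.size * h * math.sqrt(2 * math.pi))
        p /= self._norm
        p[(t_arr < lo) | (t_arr > hi)] = 0.0
        return p if np.ndim(t) else float(p[0])

    __call__ = evaluate

    def density_of_cmc(self, c):
        """Density per mol/m^3 at concentration c, whichever space the KDE uses."""
        c_arr = np.atleast_1d(np.asarray(c, dtype=float))
        if self.space == "linear":
            out = self.evaluate(c_arr)
        else:
            with np.errstate(divide="ignore"):
                u = np.log(c_arr)
            out = np.where(c_arr > 0, self.evaluate(u) / np.maximum(c_arr, 1e-300), 0.0)
        return out if np.ndim(c) else float(np.atleast_1d(out)[0])


def silverman_bandwidth(x: np.ndarray, support_width: float) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5); degenerate spread falls back to
    1e-6 of the support width."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    scale = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    if scale <= 1e-9 * support_width:  # numerically zero spread
        return 1e-6 * support_width
    return 0.9 * scale * n ** (-0.2)


def cmc_density_from_draws(
    cmc: np.ndarray, prior: PriorSpec, space: Optional[str] = None
) -> MarginalDensity:
    """KDE of a CMC sample (1-D array of c* draws); see marginal_cmc_density."""
    cmc = np.asarray(cmc, dtype=float)
    if cmc.size < 10:
        raise ValueError("need at least 10 posterior draws for a KDE")
    if space is None:
        space = "log" if _cmc_log_space(prior) else "linear"
    if space not in ("linear", "log"):
        raise ValueError(f"unknown space {space!r}")
    c_lo, c_hi = prior.cmc_bounds
    if space == "log":
        if c_lo <= 0:
            raise ValueError("log-space KDE needs a positive lower CMC bound")
        centers = np.log(cmc)
        support = (math.log(c_lo), math.log(c_hi))
    else:
        centers = cmc.copy()
        support = (c_lo, c_hi)
    h = silverman_bandwidth(centers, support[1] - support[0])
    return MarginalDensity(centers=centers, bandwidth=h, support=support, space=space)


def marginal_cmc_density(
    samples: PosteriorSamples, prior: PriorSpec, space: Optional[str] = None
) -> MarginalDensity:
    """Gaussian-kernel KDE of the CMC marginal.

    Defaults to log space (KDE on ln c*) under the log-uniform prior and
    linear space under the uniform prior; ``space`` overrides.
    """
    return cmc_density_from_draws(samples.cmc, prior, space=space)


class QuadratureError(RuntimeError):
    pass


def differential_entropy(density: MarginalDensity, *, epsabs: float = 1e-4) -> float:
    """Differential entropy -integral p ln p over the support, in nats.

    Adaptive quadrature with absolute tolerance ``epsabs``; the integrand is
    defined as 0 where p = 0.  Break points at the kernel-center quantiles
    guide the subdivision for sharply peaked densities.
    """
    lo, hi = density.support

    def integrand(t: float) -> float:
        p = density.evaluate(t)
        return -p * math.log(p) if p > 0 else 0.0

    pts = np.unique(np.clip(np.percentile(density.centers, [1, 25, 50, 75, 99]), lo, hi))
    pts = [float(p) for p in pts if lo < p < hi]
    with warnings.catch_warnings():
        warnings.simplefilter("error", integrate.IntegrationWarning)
        try:
            val, abserr = integrate.quad(integrand, lo, hi, epsabs=epsabs, limit=200, points=pts)
        except integrate.IntegrationWarning as exc:  # pragma: no cover - rare
            raise QuadratureError(f"entropy quadrature did not converge: {exc}") from exc
    if not np.isfinite(val):
        raise QuadratureError(f"entropy quadrature returned {val!r} (abserr {abserr!r})")
    return float(val)


def credible_interval(
    samples: PosteriorSamples, parameter: str = "cmc", level: float = 0.90
) -> tuple[float, float]:
    """Equal-tailed credible interval from empirical quantiles (type-7)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    col = samples.column(parameter)
    if col.size == 0:
        raise ValueError("no samples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(col, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


@dataclass(frozen=True)
class ModeResult:
    cmc: float
    multimodal: bool


def posterior_mode_cmc(density: MarginalDensity, n_grid: int = 512) -> ModeResult:
    """Mode of the CMC marginal: dense-grid argmax refined locally.

    Secondary local maxima within 1% of the global maximum (including flat
    densities) set the ``multimodal`` flag; the global argmax is still
    returned.  In log space the mode of p(u) is mapped back with exp.
    """
    lo, hi = density.support
    grid = np.linspace(lo, hi, n_grid)
    p = density.evaluate(grid)
    i = int(np.argmax(p))
    pmax = p[i]

    # count connected near-maximal regions (robust to KDE micro-wiggles):
    # several disjoint regions within 1% of the maximum -> multimodal; a
    # near-maximal band covering most of the support -> no meaningful mode
    near = p >= 0.99 * pmax
    n_regions = int(np.sum(near[1:] & ~near[:-1]) + near[0])
    flat = bool(np.mean(p >= 0.9 * pmax) > 0.5)
    multimodal = n_regions > 1 or flat

    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(lambda t: -density.evaluate(t), bounds=(a, b), method="bounded")
    t_star = float(res.x) if res.success and -res.fun >= pmax else float(grid[i])
    value = math.exp(t_star) if density.space == "log" else t_star
    return ModeResult(cmc=value, multimodal=multimodal)
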