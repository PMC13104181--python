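"""Expected-information-gain (EIG) design of the next measurement.

The design criterion is the expected reduction in the differential entropy of
the CMC marginal posterior from one additional surface-tension measurement at
candidate concentration c'.  It is estimated by nested Monte Carlo:

    1. draw theta^(j) from the current posterior samples,
    2. simulate gamma'_obs ~ N(gamma(c'; theta^(j)), sigma^2),
    3. re-sample the posterior on D united with (c', gamma'_obs)
       (warm-started, reduced sampler settings),
    4. compute the entropy of the new CMC marginal,

and EIG(c') = S[p(c*|D)] - mean_j S[p(c*|D + (c', gamma'_j))].  The candidate
maximizing the EIG over an exhaustive [log-]uniform grid (optionally locally
refined) is selected.  Common random numbers — reusing the same (theta^(j),
noise-quantile) pairs across candidates — reduce the variance of EIG
*differences* between candidates, which is what the argmax consumes.

A discrete two-hypothesis toy EIG (`brute_force_eig_discrete`, exact by
enumeration, and `nested_mc_eig_discrete`, the same nested-MC structure
without MCMC) provides an independently checkable miniature of the estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .isotherm import Dataset, IsothermParams, NoiseModel, PriorSpec, evaluate_isotherm
from .posterior import (
    RHAT_HARD,
    PosteriorSamples,
    SamplerSettings,
    _log_post_unconstrained,
    _run_ensemble_batch,
    _split_rhat_multi,
    cmc_density_from_draws,
    differential_entropy,
    marginal_cmc_density,
    theta_to_unconstrained,
    unconstrained_to_theta,
)

__all__ = [
    "DesignGrid",
    "EIGSettings",
    "EIGProfile",
    "SelectionResult",
    "expected_information_gain",
    "eig_profile",
    "select_next_concentration",
    "brute_force_eig_discrete",
    "nested_mc_eig_discrete",
]


@dataclass(frozen=True)
class DesignGrid:
    """Candidate concentrations for the next experiment.

    Spacing matches the CMC prior: uniform candidates for the uniform prior,
    log-spaced for the log-uniform prior.  ``refinement_rounds`` finer local
    grids (at ``refinement_factor`` x resolution) are searched around the
    incumbent after the coarse pass.
    """

    candidates: tuple[float, ...]
    spacing: str = "uniform"
    refinement_rounds: int = 1
    refinement_factor: int = 5

    def __post_init__(self) -> None:
        c = np.asarray(self.candidates, dtype=float)
        if c.size == 0:
            raise ValueError("grid needs at least one candidate")
        if np.any(np.diff(c) <= 0):
            raise ValueError("candidates must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("candidates must be non-negative")
        if self.spacing not in ("uniform", "log"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        if self.refinement_rounds < 0:
            raise ValueError("refinement_rounds must be >= 0")

    @classmethod
    def from_prior(
        cls,
        prior: PriorSpec,
        n_points: int = 20,
        refinement_rounds: int = 1,
        extend: float = 1.0,
    ) -> "DesignGrid":
        """Grid spanning the prior's CMC support (optionally widened by
        ``extend`` x on the upper end), spacing matched to the prior kind."""
        lo, hi = prior.cmc_bounds
        hi = hi * extend
        if prior.cmc_prior_kind == "log_uniform":
            cand = np.geomspace(lo, hi, n_points)
            spacing = "log"
        else:
            cand = np.linspace(lo, hi, n_points)
            spacing = "uniform"
        return cls(tuple(float(x) for x in cand), spacing=spacing, refinement_rounds=refinement_rounds)

    @property
    def span(self) -> tuple[float, float]:
        return self.candidates[0], self.candidates[-1]


@dataclass(frozen=True)
class EIGSettings:
    """Nested-MC budget: ``n_outer`` simulated future measurements per
    candidate, each triggering one warm-started inner posterior re-fit."""

    n_outer: int = 32
    inner_sampler: SamplerSettings = field(
        default_factory=lambda: SamplerSettings(
            n_chains=8, n_warmup=120, n_draws=120, thin=3, init_strategy="warm_start"
        )
    )
    seed: int = 0
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.n_outer < 8:
            raise ValueError("n_outer must be >= 8")


@dataclass
class EIGProfile:
    """Per-candidate EIG estimates with Monte Carlo standard errors."""

    candidates: np.ndarray
    eig: np.ndarray
    mc_standard_error: np.ndarray
    n_outer: np.ndarray
    reference_entropy: float
    n_inner_failures: int = 0

    def __post_init__(self) -> None:
        self.candidates = np.asarray(self.candidates, dtype=float)
        self.eig = np.asarray(self.eig, dtype=float)
        self.mc_standard_error = np.asarray(self.mc_standard_error, dtype=float)
        self.n_outer = np.asarray(self.n_outer, dtype=int)
        if not np.isfinite(self.reference_entropy):
            raise ValueError("reference entropy must be finite")
        if np.any(self.mc_standard_error < 0):
            raise ValueError("standard errors must be non-negative")

    def __len__(self) -> int:
        return self.candidates.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"candidate": self.candidates, "eig": self.eig, "se": self.mc_standard_error}
        )


def _outer_randomness(
    settings: EIGSettings, n_samples: int, candidate_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior-draw indices, noise quantiles, and inner seeds for one candidate.

    With common random numbers the same (draw index, noise quantile, inner
    seed) triplets are reused for every candidate, so EIG differences between
    candidates are not swamped by outer-loop noise.
    """
    salt = 0 if settings.common_random_numbers else candidate_index + 1
    ss = np.random.SeedSequence(entropy=settings.seed, spawn_key=(905, salt))
    rng = np.random.default_rng(ss)
    idx = rng.integers(0, n_samples, size=settings.n_outer)
    z = rng.standard_normal(settings.n_outer)
    inner_seeds = rng.integers(0, 2**31 - 1, size=2 * settings.n_outer)
    return idx, z, inner_seeds


_LOG_2PI = math.log(2.0 * math.pi)


def _inner_refit_entropies(
    samples: PosteriorSamples,
    data: Dataset,
    prior: PriorSpec,
    noise: NoiseModel,
    candidate: float,
    gammas: np.ndarray,
    inner: SamplerSettings,
    seed: int,
    space: Optional[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started posterior re-fits for one candidate, batched.

    Each of the ``len(gammas)`` simulated outcomes gets its own ensemble; all
    ensembles advance in one vectorized run (they never interact).  Returns
    (entropies, converged mask); entropies of non-converged ensembles are
    still computed but the mask lets the caller redraw/exclude them.
    """
    B = gammas.size
    W = inner.n_chains
    if W < 4 or W % 2:
        raise ValueError("inner sampler needs an even n_chains >= 4")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # importance-resample the current posterior draws with the simulated
    # point's likelihood as weight: the walkers then start (approximately)
    # from the augmented posterior, so the short chains only need to
    # decorrelate, not contract
    th_all = samples.draws
    pred_all = th_all[:, 0] - th_all[:, 1] * np.log1p(
        th_all[:, 2] * np.minimum(float(candidate), th_all[:, 3])
    )
    logw = -0.5 * ((pred_all[None, :] - np.asarray(gammas)[:, None]) / noise.sigma) ** 2
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    idx = np.empty((B, W), dtype=int)
    for b in range(B):
        idx[b] = rng.choice(samples.n_samples, size=W, p=w[b])
    x0 = theta_to_unconstrained(samples.draws[idx.ravel()], prior).reshape(B, W, 4)
    scale = np.maximum(x0.reshape(-1, 4).std(axis=0), 1e-6)
    x0 = x0 + 0.05 * scale * rng.standard_normal(x0.shape)

    s = noise.sigma
    c_new = float(candidate)
    g_new = np.asarray(gammas, dtype=float)

    def log_prob(X: np.ndarray) -> np.ndarray:  # X: (B, W, 4)
        lp = _log_post_unconstrained(X.reshape(-1, 4), data, prior, noise).reshape(X.shape[:2])
        th = unconstrained_to_theta(X.reshape(-1, 4), prior).reshape(X.shape)
        pred = th[..., 0] - th[..., 1] * np.log1p(th[..., 2] * np.minimum(c_new, th[..., 3]))
        return lp - 0.5 * (_LOG_2PI + 2.0 * math.log(s)) - 0.5 * ((pred - g_new[:, None]) / s) ** 2

    draws_x = _run_ensemble_batch(log_prob, x0, inner.n_warmup, inner.n_draws, inner.thin, rng)
    n_draws = draws_x.shape[0]
    theta = unconstrained_to_theta(draws_x.reshape(-1, 4), prior).reshape(draws_x.shape)
    chains = np.transpose(theta, (1, 2, 0, 3))  # (B, W, n_draws, 4)
    rhat = _split_rhat_multi(chains)
    finite = np.isfinite(rhat)
    ok = np.where(
        finite.any(axis=1),
        (np.where(finite, rhat, np.inf) < RHAT_HARD).any(axis=1),
        True,
    )
    entropies = np.empty(B)
    for b in range(B):
        cmc = chains[b, :, :, 3].ravel()
        entropies[b] = differential_entropy(cmc_density_from_draws(cmc, prior, space=space))
    return entropies, ok


def expected_information_gain(
    candidate: float,
    samples: PosteriorSamples,
    data: Dataset,
    prior: PriorSpec,
    noise: NoiseModel,
    settings: EIGSettings,
    *,
    reference_entropy: Optional[float] = None,
    candidate_index: int = 0,
    space: Optional[str] = None,
    failures_out: Optional[list] = None,
) -> tuple[float, float]:
    """Nested-MC estimate of the EIG at one candidate concentration.

    For j = 1..n_outer: draw theta_j from the posterior samples, simulate a
    measurement outcome at the candidate, re-fit the posterior on the
    augmented data (warm-started, reduced settings), and compute the new CMC
    entropy; the EIG is the current entropy minus the mean of the new
    entropies.  Returns (estimate, standard error of the mean), both in
    nats.  Re-fits that fail the hard convergence check are redrawn once
    with a fresh seed, then excluded.
    """
    if candidate < 0:
        raise ValueError("candidate concentration must be >= 0")
    if reference_entropy is None:
        reference_entropy = differential_entropy(marginal_cmc_density(samples, prior, space=space))

    idx, z, inner_seeds = _outer_randomness(settings, samples.n_samples, candidate_index)
    theta = samples.draws[idx]
    pred = theta[:, 0] - theta[:, 1] * np.log1p(theta[:, 2] * np.minimum(candidate, theta[:, 3]))
    gammas = pred + noise.sigma * z

    inner = replace(settings.inner_sampler, init_strategy="warm_start")
    ent, ok = _inner_refit_entropies(
        samples, data, prior, noise, candidate, gammas, inner, int(inner_seeds[0]), space
    )
    if not ok.all():  # one redraw for the failed replicates, then exclusion
        ent2, ok2 = _inner_refit_entropies(
            samples, data, prior, noise, candidate, gammas[~ok], inner, int(inner_seeds[1]), space
        )
        ent[~ok] = ent2
        ok[~ok] = ok2
    if not ok.any():
        # Every replicate tripped the diagnostic — typical for very diffuse
        # posteriors where short chains cannot certify mixing even though the
        # warm-started draws remain usable.  Fall back to all replicates
        # rather than aborting the campaign.
        warnings.warn(
            f"EIG at c'={candidate:g}: no inner re-fit passed the convergence check; "
            "using all replicates",
            RuntimeWarning,
            stacklevel=2,
        )
        ok = np.ones_like(ok)
    if failures_out is not None:
        failures_out.append(int((~ok).sum()))
    kept = ent[ok]
    eig = reference_entropy - float(kept.mean())
    se = float(kept.std(ddof=1) / math.sqrt(kept.size)) if kept.size > 1 else float("inf")
    return eig, se


def eig_profile(
    grid: DesignGrid,
    samples: PosteriorSamples,
    data: Dataset,
    prior: PriorSpec,
    noise: NoiseModel,
    settings: EIGSettings,
    *,
    space: Optional[str] = None,
    candidates: Optional[Sequence[float]] = None,
) -> EIGProfile:
    """EIG evaluated at every candidate of the grid (exhaustive search)."""
    cand = np.asarray(grid.candidates if candidates is None else candidates, dtype=float)
    ref = differential_entropy(marginal_cmc_density(samples, prior, space=space))
    eig = np.empty(cand.size)
    se = np.empty(cand.size)
    failures: list[int] = []
    for i, c in enumerate(cand):
        eig[i], se[i] = expected_information_gain(
            float(c),
            samples,
            data,
            prior,
            noise,
            settings,
            reference_entropy=ref,
            candidate_index=i,
            space=space,
            failures_out=failures,
        )
    return EIGProfile(
        candidates=cand,
        eig=eig,
        mc_standard_error=se,
        n_outer=np.full(cand.size, settings.n_outer),
        reference_entropy=ref,
        n_inner_failures=sum(failures),
    )


@dataclass(frozen=True)
class SelectionResult:
    concentration: float
    no_information: bool = False
    profiles: tuple[EIGProfile, ...] = ()


def _local_refined_candidates(grid: DesignGrid, incumbent: float) -> np.ndarray:
    """A finer grid (same spacing rule) around the incumbent, bounded by its
    neighbors in the coarse grid; never leaves the original span."""
    cand = np.asarray(grid.candidates)
    i = int(np.argmin(np.abs(cand - incumbent)))
    lo = cand[max(i - 1, 0)]
    hi = cand[min(i + 1, cand.size - 1)]
    n = 2 * grid.refinement_factor + 1
    if grid.spacing == "log" and lo > 0:
        fine = np.geomspace(lo, hi, n)
    else:
        fine = np.linspace(lo, hi, n)
    return fine


def select_next_concentration(
    profile: EIGProfile,
    grid: DesignGrid,
    *,
    evaluator=None,
) -> SelectionResult:
    """Pick the EIG-maximizing candidate; optionally refine locally.

    Ties break toward the lower concentration.  If every EIG estimate is
    indistinguishable from zero within 2 standard errors, the incumbent is
    returned with the ``no_information`` flag set.  ``evaluator`` is a
    callable (candidate array) -> EIGProfile used for the refinement rounds;
    without it the coarse-grid argmax is returned directly.
    """
    if len(profile) == 0:
        raise ValueError("empty EIG profile")
    profiles = [profile]

    def argmax_low_tie(p: EIGProfile) -> float:
        best = np.max(p.eig)
        ties = np.flatnonzero(p.eig >= best - 1e-15)
        return float(p.candidates[ties[0]])

    incumbent = argmax_low_tie(profile)
    informative = np.any(profile.eig > 2.0 * profile.mc_standard_error)
    if not informative:
        return SelectionResult(incumbent, no_information=True, profiles=tuple(profiles))

    if evaluator is not None:
        for _ in range(grid.refinement_rounds):
            fine = _local_refined_candidates(grid, incumbent)
            fine_profile = evaluator(fine)
            profiles.append(fine_profile)
            refined = argmax_low_tie(fine_profile)
            if np.max(fine_profile.eig) >= np.max(profile.eig) - 1e-15:
                incumbent = refined
    lo, hi = grid.span
    incumbent = float(np.clip(incumbent, lo, hi))
    return SelectionResult(incumbent, no_information=False, profiles=tuple(profiles))


# ---------------------------------------------------------------------------
# discrete two-hypothesis toys: exact EIG by enumeration + nested-MC twin
# ---------------------------------------------------------------------------


def _label_entropy(weights: np.ndarray, labels: np.ndarray) -> float:
    """Shannon entropy of the c*-label distribution implied by hypothesis
    weights (hypotheses sharing a c* value pool their mass)."""
    w = np.zeros(0)
    uniq = np.unique(labels)
    w = np.array([weights[labels == u].sum() for u in uniq])
    w = w[w > 0]
    return float(-np.sum(w * np.log(w)))


def brute_force_eig_discrete(
    hypotheses: Sequence[IsothermParams],
    weights: Sequence[float],
    candidate: float,
    noise: NoiseModel,
    measurement_grid: np.ndarray,
) -> float:
    """Exact EIG for a finite hypothesis set, by direct summation.

    The outcome space is discretized on ``measurement_grid`` (spacing at most
    sigma/4, spanning at least +-6 sigma around every predicted surface
    tension).  For each outcome the exact hypothesis posterior is formed by
    Bayes' rule and the expected posterior entropy of the CMC label is
    accumulated, weighted by the outcome's marginal probability.
    """
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    grid = np.asarray(measurement_grid, dtype=float)
    dy = np.diff(grid)
    if np.any(dy > noise.sigma / 4 + 1e-15):
        raise ValueError("measurement grid spacing must be at most sigma/4")
    preds = np.array([evaluate_isotherm(h, candidate) for h in hypotheses])
    if grid[0] > preds.min() - 6 * noise.sigma or grid[-1] < preds.max() + 6 * noise.sigma:
        raise ValueError("measurement grid must span +-6 sigma around all predictions")
    labels = np.array([h.cmc for h in hypotheses])

    h0 = _label_entropy(w, labels)
    s = noise.sigma
    # likelihood matrix: outcomes x hypotheses
    lik = np.exp(-0.5 * ((grid[:, None] - preds[None, :]) / s) ** 2) / (s * math.sqrt(2 * math.pi))
    joint = lik * w[None, :]
    p_y = joint.sum(axis=1)
    post = np.divide(joint, p_y[:, None], out=np.zeros_like(joint), where=p_y[:, None] > 0)

    ent = np.zeros(grid.size)
    for u in np.unique(labels):
        pw = post[:, labels == u].sum(axis=1)
        nz = pw > 0
        ent[nz] -= pw[nz] * np.log(pw[nz])
    # trapezoid weights over the outcome line
    wts = np.empty(grid.size)
    wts[1:-1] = (grid[2:] - grid[:-2]) / 2
    wts[0] = (grid[1] - grid[0]) / 2
    wts[-1] = (grid[-1] - grid[-2]) / 2
    expected_posterior_entropy = float(np.sum(p_y * ent * wts) / np.sum(p_y * wts))
    return h0 - expected_posterior_entropy


def nested_mc_eig_discrete(
    hypotheses: Sequence[IsothermParams],
    weights: Sequence[float],
    candidate: float,
    noise: NoiseModel,
    n_outer: int,
    seed: int,
) -> tuple[float, float]:
    """Nested-MC EIG on the discrete toy: sample a hypothesis, simulate an
    outcome, update the hypothesis posterior exactly, and average the label
    entropies — the same outer structure as the continuous estimator, with
    the MCMC inner step replaced by the closed-form discrete update.

    Returns (estimate, standard error).
    """
    w = np.asarray(weights, dtype=float)
    preds = np.array([evaluate_isotherm(h, candidate) for h in hypotheses])
    labels = np.array([h.cmc for h in hypotheses])
    h0 = _label_entropy(w, labels)
    rng = np.random.default_rng(seed)
    hyp_idx = rng.choice(w.size, size=n_outer, p=w)
    y = preds[hyp_idx] + noise.sigma * rng.standard_normal(n_outer)
    s = noise.sigma
    lik = np.exp(-0.5 * ((y[:, None] - preds[None, :]) / s) ** 2)
    post = lik * w[None, :]
    post /= post.sum(axis=1, keepdims=True)
    ents = np.array([_label_entropy(post[j], labels) for j in range(n_outer)])
    eig = h0 - float(ents.mean())
    se = float(ents.std(ddof=1) / math.sqrt(n_outer))
    return eig, se
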