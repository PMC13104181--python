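# Methods

`cmcbed` determines the critical micelle concentration (CMC) of a surfactant
by adaptive Bayesian experimental design over sequential surface-tension
measurements.  This note records the model, the estimators, the numerical
choices, and what the synthetic test bed does and does not demonstrate.

## The surface-tension isotherm model

The measured surface tension of an aqueous surfactant solution at bulk
concentration `c` [mol/m³] is modeled as a change-point curve,

```
gamma(c; theta) = gamma0 - a·ln(1 + k·c)        for c <  c*
                  gamma0 - a·ln(1 + k·c*)       for c >= c*
```

with `theta = (gamma0, a, k, c*)`: the pure-solvent surface tension `gamma0`
[N/m], a surface-pressure scale `a` [N/m] tied to the molecular
cross-section at the interface, the Langmuir adsorption constant `k`
[m³/mol], and the CMC `c*` [mol/m³].  Below the CMC the descending branch is
the Langmuir–Szyszkowski isotherm (natural logarithm; the magnitudes of `a`
and `k` used throughout require `ln`, not `log10`); above it the interface
is saturated and the curve is flat.  Measurements are conditionally
independent and homoskedastic,

```
gamma_obs | theta, c  ~  Normal(gamma(c; theta), sigma²),   sigma = 0.001 N/m,
```

with `sigma` a known constant calibrated to tensiometer repeatability
(triplicate-averaged readings); inferring `sigma` is out of scope.

Units are fixed: mol/m³ (numerically equal to mM) and N/m.  File readers
convert mN/m and mol/L only when asked explicitly; a surface-tension column
with values above 1 is rejected as almost certainly mN/m.

## Priors

* `gamma0 ~ Normal(gamma0_obs, sigma²)` — informative, centered on the
  measured pure-water value (default 0.0718 N/m, sd 0.001 N/m).
* `a ~ Uniform(0.001, 0.1)` N/m and `k ~ Uniform(0, 10000]` m³/mol —
  deliberately diffuse.  The `k` interval is open at 0 because `k = 0`
  yields a flat isotherm with a non-identifiable CMC.
* `c*`: `Uniform(c*_min, c*_max)` when the order of magnitude is known
  (OTG-like preset: [0, 30] mol/m³), or log-uniform — uniform in `ln c*` —
  when it is not (Triton-X-100-like preset: [0.001, 10] mol/m³).

Out-of-support parameter vectors get log-density −∞ rather than an
exception, so samplers reject them naturally.

A consequence worth knowing: with `k` allowed up to 10⁴, a large-`k`/small-`a`
parameter combination produces a slow, nearly flat logarithmic decline that
can mimic a plateau over a limited concentration window.  Sparse datasets
without low-concentration coverage therefore support a genuine ridge of
high-`c*` solutions; this is a property of the model class under the diffuse
prior, not a sampler artifact (it is reproduced by exact grid integration).
Measuring at low concentrations — which the information-gain criterion
favors early — is what kills this ridge.

## Posterior sampling

The unnormalized posterior is prior × likelihood; the evidence is never
computed.  Sampling uses an in-package vectorized ensemble MCMC sampler:

* **Reparameterization.**  Interval-bounded parameters map to the real line
  by logit transforms (through `ln c*` for the log-uniform prior), with
  Jacobian corrections in the target.  `gamma0` is sampled directly.
* **Moves.**  Each step updates two half-ensembles alternately with a 50/50
  mixture of the affine-invariant stretch move (Hastings factor z^(d−1))
  and differential-evolution moves (difference-vector jumps, 10% of them
  full-length for mode hopping).  Any MCMC with the correct stationary law
  would do; this combination handles the curved `(a, k)` ridge well and is
  implemented as a batched numpy loop because the design criterion
  (below) requires thousands of short re-fits per campaign.  The test suite
  cross-checks it against emcee on the identical target and against a
  dense-grid posterior (total variation < 0.05 on a reduced problem).
* **Initialization.**  Walkers are resampled from a candidate pool weighted
  by posterior density.  The pool combines prior draws with closed-form
  profile-likelihood optima on a `(c*, k)` grid: for fixed `(c*, k)` the
  model is linear in `(gamma0, a)`, so the penalized least-squares profile
  is exact and cheap, and it places candidates in *every* change-point
  segment — local optimizers routinely get trapped in the wrong segment of
  the piecewise-smooth likelihood.
* **Defaults.**  32 walkers × 400 retained draws after 1000 warmup steps
  (N_s = 12800).  Walkers play the role of chains in the diagnostics:
  split-R̂ and autocorrelation-based effective sample size per parameter
  (pass thresholds R̂ < 1.05, ESS > 100; these are reporting thresholds).
  A fit is flagged non-converged only when *every* parameter's R̂ exceeds
  1.2: with two or three data points the `(a, k)` ridge mixes slowly
  (R̂ up to ≈1.4) while the CMC marginal — the only quantity the campaign
  consumes — is well mixed, and flagging on any single parameter would
  reject most legitimate early-campaign fits.
* **Determinism.**  All randomness flows from `numpy` `SeedSequence`s;
  identical seeds give bit-identical draws.

## CMC marginal, entropy, and summaries

The CMC marginal is a Gaussian-kernel KDE on the `c*` draws — on `ln c*`
under the log-uniform prior, where the posterior can span four decades —
with the fixed Silverman variant `0.9·min(sd, IQR/1.34)·N_s^(−1/5)` and a
fallback bandwidth of 10⁻⁶ × support width for zero-spread samples.  The
KDE is clipped to the prior support and renormalized there analytically
(no reflection; the small edge bias is accepted and identical across the
entropy differences the design loop consumes).

Campaign uncertainty is the differential entropy `−∫ p ln p` over the
support, by adaptive quadrature (absolute tolerance 10⁻⁴ nats, break points
at the kernel-center quantiles so sharp peaks are never missed).  Under the
log-uniform prior all campaign entropies live in `ln c*` space;
reports also carry the linear-space entropy for transparency.  Point
summaries: equal-tailed credible intervals from type-7 (linear
interpolation) empirical quantiles, and the KDE mode from a dense-grid
argmax with bounded local refinement.  Several disjoint near-maximal
regions (within 1% of the maximum), or a near-maximal band covering most of
the support, set a multimodality flag.

## Expected information gain and design

The next measurement concentration maximizes the expected information gain
(EIG) about the CMC — the expected entropy reduction of the CMC marginal,
equal to the mutual information between the CMC and the future observation.
The nested Monte Carlo estimator, for candidate `c'`:

1. draw `theta_j` from the current posterior samples (j = 1..n_outer),
2. simulate `gamma'_j ~ Normal(gamma(c'; theta_j), sigma²)`,
3. re-fit the posterior on the augmented dataset,
4. compute the new CMC entropy;

EIG(c') = current entropy − mean of the new entropies, with the standard
error of that mean attached.  Numerical choices that make this affordable
and stable:

* **Batched inner re-fits.**  All `n_outer` re-fits for a candidate run as
  one vectorized multi-ensemble MCMC (ensembles never interact), amortizing
  the per-step overhead.
* **Warm starts via importance resampling.**  Inner walkers are resampled
  from the current posterior draws *weighted by the simulated point's
  likelihood*, so they start approximately from the augmented posterior.
  Without this, short chains started from the broader current posterior
  systematically overestimate the new entropy and bias the criterion
  *against* informative candidates.
* **Inner settings.**  8 walkers, 80 warmup steps, 120 draws thinned by 3
  by default (thinning keeps the split-R̂ gate meaningful on short chains).
  Re-fits flagged non-converged are redrawn once with a fresh seed, then
  excluded (counted on the profile).  If every replicate is flagged —
  typical for very diffuse early posteriors where short chains cannot
  certify mixing even though the warm-started draws remain usable — the
  estimate falls back to all replicates with a warning rather than
  aborting the campaign.
* **Common random numbers.**  The same (posterior-draw index, noise
  quantile, inner seed) triplets are reused across candidates, shrinking
  the variance of EIG *differences*, which is what the argmax consumes.

The search is an exhaustive grid over the prior's CMC support — uniformly
spaced for the uniform prior, log-spaced for the log-uniform one (20 points
by default) — followed by one local refinement round at 5× resolution
between the incumbent's neighbors (never leaving the original span).  Ties
break toward the lower concentration; if no candidate's EIG exceeds twice
its standard error the selection is flagged "no information".

## Campaign loop

A campaign starts from two manual measurements at the extremes of the CMC
prior support: pure water at `c = 0` (pinning `gamma0`) and the stock at
`c*_max` (pinning the plateau level).  Each iteration then re-fits the
posterior, computes the EIG profile, measures at the selected
concentration (simulated oracle or interactive CLI), re-fits, and records
the decision.  Stopping: a configured 90%-CI width threshold (checked
first) or the experiment budget (default 9 total, i.e. 2 initialization +
7 adaptive).  Seeds for iteration k derive from (master seed, k) alone, so
replaying or resuming from a saved state reproduces an uninterrupted run
bit-for-bit; states are versioned JSON.

## Oracles and baselines

* **Truth oracle**: simulates from a fixed parameter vector plus noise.
* **Posterior-derived oracle**: draws a parameter vector from a stored
  posterior, then adds noise — its outputs follow the posterior-predictive
  distribution (verified by a Kolmogorov–Smirnov check and the law of
  total variance).
* **Static designs**: n measurements [log-]uniformly spaced across the CMC
  support, fit once; `experiments_to_match_entropy` scans n upward until
  the mean CMC entropy reaches a target.  The expected entropy-versus-n
  curve is non-increasing, and where the per-size Monte Carlo error rivals
  the per-experiment slope the first raw sample-mean crossing is biased
  early; an isotonic (pool-adjacent-violators) option monotonizes the
  scanned curve before the threshold comparison.  When comparing with an
  adaptive campaign at iteration N, the matched static size is N + 2,
  because the two manual initialization points are excluded from the
  adaptive count.
* **Classical fit**: the traditional estimator — least-squares
  Langmuir–Szyszkowski fit on the descending branch, flat line on the
  plateau, branch split chosen by exhaustive residual-sum-of-squares
  search, CMC at the intersection.  A fitted drop below max(3×residual
  scatter, 2 mN/m) is rejected as "no descending branch".  The shallow
  grazing intersection makes this estimator noise-sensitive: its sampling
  spread on 20–24-point synthetic isotherms is ≈10% of the CMC, which is
  why the package reports it only as a cross-check on the Bayesian
  interval.

## Synthetic scenarios and what the tests show

Two shipped scenarios mirror the case-study regimes: an OTG-like truth
(gamma0 = 0.0718 N/m, a = 0.0115 N/m, k = 4 m³/mol, c* = 9.7 mol/m³;
uniform CMC prior on [0, 30]) and a Triton-X-100-like truth (a = 0.008,
k = 450, c* = 0.45; log-uniform prior on [0.001, 10]).  The generator
draws from the exact data model (isotherm + Gaussian noise,
sigma = 0.001 N/m).  Because generator and likelihood share the same model
family, the test bed validates the *inference and design machinery* —
calibration, information accounting, design efficiency — not robustness to
model discrepancy (premicellar aggregation, impurities, Frumkin-type
lateral interactions), which real tensiometry data would probe.

Problem sizes in the shipped test suite and acceptance script are scaled to
a single CPU: campaign checks use 5–11-candidate grids, 8–32 outer
replicates, and the reduced samplers given above; coverage runs 50
campaigns (30 in the acceptance script) with truths drawn from the prior;
the efficiency comparison averages 3 adaptive campaigns (2 in the script)
against a static-design scan with 8 replicates per size.  At these sizes
the adaptive campaign reproduces the qualitative fingerprints of the
method at full scale: a low first pick (≈3 mol/m³ for the OTG-like case),
bisection-like narrowing with occasional backtracking, final 90% intervals
of a few mol/m³ around the true CMC, and a static design needing roughly
1.5–2× as many experiments to match the final entropy.

## Known limitations

* The known-sigma, homoskedastic noise model and the single-isotherm model
  family are assumptions; model averaging, discrepancy terms, and inferred
  noise are out of scope.
* KDE boundary renormalization biases densities near the support edges
  slightly; entropies inherit a small, state-independent bias that cancels
  in EIG differences.
* Under the diffuse `k` prior, datasets without low-concentration coverage
  legitimately leave a high-`c*` ridge; credible intervals then widen (or,
  for truths atypical under the prior, can exclude the truth at the nominal
  10% rate or slightly above).
* The ensemble sampler's `(a, k)` mixing on two-to-three-point datasets is
  slow; the CMC marginal is robust to this, but per-parameter `(a, k)`
  summaries from such early fits should not be over-interpreted.
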