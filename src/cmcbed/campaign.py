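"""Sequential experiment--model--design campaign orchestration.

A campaign starts from two manually designed measurements at the extremes of
the CMC prior support — pure water at c = 0 (pinning gamma0) and a
concentrated stock at the upper bound (pinning the plateau) — then iterates:
fit the posterior on all data, compute the expected-information-gain profile
over the candidate grid, measure at the EIG-optimal concentration, and
re-fit.  The loop stops when the 90% credible interval for the CMC is
narrower than a configured width (if set; checked first) or the experiment
budget is exhausted.

Randomness discipline: one master seed; the seeds of iteration k (posterior
fit, EIG loop, simulated measurement) are derived from (master, k) alone, so
replaying or resuming iteration k never depends on how earlier iterations
consumed randomness.  States serialize to versioned JSON and round-trip
losslessly; a resumed campaign reproduces an uninterrupted one exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .isotherm import Dataset, Measurement, NoiseModel, PriorSpec
from .posterior import (
    PosteriorSamples,
    SamplerSettings,
    credible_interval,
    differential_entropy,
    marginal_cmc_density,
    posterior_mode_cmc,
    sample_posterior,
)
from .design import DesignGrid, EIGProfile, EIGSettings, SelectionResult, eig_profile, select_next_concentration

__all__ = [
    "CampaignConfig",
    "DecisionRecord",
    "CampaignState",
    "CampaignError",
    "initialize_campaign",
    "bed_step",
    "propose_next",
    "record_measurement",
    "check_stopping",
    "entropy_trace",
    "save_state",
    "load_state",
    "run_campaign",
    "build_report",
]

STATE_SCHEMA_VERSION = 1


class CampaignError(RuntimeError):
    pass


@dataclass(frozen=True)
class CampaignConfig:
    prior: PriorSpec
    noise: NoiseModel = NoiseModel()
    sampler: SamplerSettings = SamplerSettings()
    eig: EIGSettings = EIGSettings()
    grid: Optional[DesignGrid] = None
    budget: int = 9
    ci_width_stop: Optional[float] = None
    seed: int = 0
    name: str = "campaign"

    def __post_init__(self) -> None:
        if self.budget < 3:
            raise ValueError("budget must be >= 3 (two initializations + one adaptive)")
        if self.ci_width_stop is not None and self.ci_width_stop <= 0:
            raise ValueError("ci_width_stop must be > 0 when set")
        if self.grid is None:
            object.__setattr__(self, "grid", DesignGrid.from_prior(self.prior))

    @property
    def entropy_space(self) -> str:
        return "log" if self.prior.cmc_prior_kind == "log_uniform" else "linear"


@dataclass
class DecisionRecord:
    iteration: int
    chosen_concentration: float
    profile: EIGProfile
    measurement: Measurement
    post_entropy: float
    post_entropy_linear: float
    ci: tuple[float, float]
    no_information: bool = False


@dataclass
class CampaignState:
    config: CampaignConfig
    data: Dataset
    decisions: list[DecisionRecord] = field(default_factory=list)
    status: str = "running"
    initial_entropy: float = float("nan")
    pending_concentration: Optional[float] = None
    pending_profile: Optional[EIGProfile] = None
    # runtime-only cache of the latest posterior fit (not serialized)
    samples: Optional[PosteriorSamples] = None

    @property
    def iteration(self) -> int:
        return len(self.decisions)

    @property
    def current_entropy(self) -> float:
        return self.decisions[-1].post_entropy if self.decisions else self.initial_entropy

    @property
    def current_ci(self) -> Optional[tuple[float, float]]:
        return self.decisions[-1].ci if self.decisions else None


def _child_seed(master: int, iteration: int, role: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(iteration, role))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31 - 1)


def _fit(state: CampaignState, iteration: int, role: int) -> PosteriorSamples:
    cfg = state.config
    settings = replace(cfg.sampler, seed=_child_seed(cfg.seed, iteration, role))
    samples = sample_posterior(state.data, cfg.prior, cfg.noise, settings)
    state.samples = samples
    return samples


def _entropies(samples: PosteriorSamples, cfg: CampaignConfig) -> tuple[float, float]:
    """(campaign-space entropy, linear-space entropy) of the CMC marginal."""
    s_campaign = differential_entropy(marginal_cmc_density(samples, cfg.prior, space=cfg.entropy_space))
    if cfg.entropy_space == "linear":
        return s_campaign, s_campaign
    s_lin = differential_entropy(marginal_cmc_density(samples, cfg.prior, space="linear"))
    return s_campaign, s_lin


def initialize_campaign(
    config: CampaignConfig,
    gamma_pure_water: Measurement,
    gamma_stock: Measurement,
) -> CampaignState:
    """Start a campaign from the two extreme-concentration measurements.

    The first measurement must be of pure water (c = 0); the second of the
    stock solution at the upper end of the CMC prior support.
    """
    c_hi = config.prior.cmc_bounds[1]
    if gamma_pure_water.concentration != 0.0:
        raise CampaignError(
            "initialization convention: the first measurement must be pure water at c = 0 "
            f"(got c = {gamma_pure_water.concentration})"
        )
    if not math.isclose(gamma_stock.concentration, c_hi, rel_tol=1e-9):
        raise CampaignError(
            "initialization convention: the second measurement must be the stock at the "
            f"upper CMC prior bound c = {c_hi} (got c = {gamma_stock.concentration})"
        )
    m0 = replace_label(gamma_pure_water, 0)
    m1 = replace_label(gamma_stock, 0)
    state = CampaignState(config=config, data=Dataset([m0, m1]))
    samples = _fit(state, 0, 0)
    state.initial_entropy, _ = _entropies(samples, config)
    state.status = check_stopping(state)
    return state


def replace_label(m: Measurement, label: int) -> Measurement:
    return Measurement(m.concentration, m.surface_tension, label=label)


def propose_next(state: CampaignState) -> SelectionResult:
    """Fit the posterior on the current data and pick the EIG-optimal next
    concentration; the recommendation is cached on the state for `record`."""
    if state.status != "running":
        raise CampaignError(f"campaign is not running (status {state.status!r})")
    cfg = state.config
    k = state.iteration + 1
    samples = _fit(state, k, 0)
    eig_settings = replace(cfg.eig, seed=_child_seed(cfg.seed, k, 1))
    space = cfg.entropy_space

    profile = eig_profile(cfg.grid, samples, state.data, cfg.prior, cfg.noise, eig_settings, space=space)

    def evaluator(cands):
        return eig_profile(
            cfg.grid, samples, state.data, cfg.prior, cfg.noise, eig_settings,
            space=space, candidates=cands,
        )

    sel = select_next_concentration(profile, cfg.grid, evaluator=evaluator)
    state.pending_concentration = sel.concentration
    state.pending_profile = sel.profiles[-1] if sel.profiles else profile
    # keep the coarse profile for the record (full-span snapshot)
    state._pending_coarse = profile  # type: ignore[attr-defined]
    state._pending_no_info = sel.no_information  # type: ignore[attr-defined]
    return sel


def record_measurement(state: CampaignState, measurement: Measurement) -> CampaignState:
    """Append a measurement for the pending recommendation, re-fit, record the
    decision, and evaluate the stopping rule."""
    if state.pending_concentration is None:
        raise CampaignError("no pending recommendation; call propose_next (or `next`) first")
    cfg = state.config
    k = state.iteration + 1
    m = replace_label(measurement, k)
    state.data.append(m)
    samples = _fit(state, k, 2)
    s_campaign, s_lin = _entropies(samples, cfg)
    ci = credible_interval(samples, "cmc", 0.90)
    state.decisions.append(
        DecisionRecord(
            iteration=k,
            chosen_concentration=state.pending_concentration,
            profile=getattr(state, "_pending_coarse", state.pending_profile),
            measurement=m,
            post_entropy=s_campaign,
            post_entropy_linear=s_lin,
            ci=ci,
            no_information=getattr(state, "_pending_no_info", False),
        )
    )
    state.pending_concentration = None
    state.pending_profile = None
    state.status = check_stopping(state)
    return state


def bed_step(state: CampaignState, measure: Callable[[float], Measurement]) -> CampaignState:
    """One full feedback-loop iteration: fit, design, measure, re-fit, record.

    ``measure`` maps a concentration to a Measurement (an oracle call or an
    interactive prompt).  If it raises, the state is preserved with status
    ``awaiting_measurement`` and can be resumed.
    """
    sel = propose_next(state)
    try:
        m = measure(sel.concentration)
    except Exception:
        state.status = "awaiting_measurement"
        return state
    return record_measurement(state, m)


def check_stopping(state: CampaignState) -> str:
    """Stopping rule: sufficiently narrow CMC credible interval (checked
    first) or exhausted budget; otherwise running."""
    cfg = state.config
    ci = state.current_ci
    if cfg.ci_width_stop is not None and ci is not None and (ci[1] - ci[0]) <= cfg.ci_width_stop:
        return "stopped_ci"
    if len(state.data) >= cfg.budget:
        return "stopped_budget"
    return "running"


def entropy_trace(state: CampaignState):
    """Table of (N, entropy) after initialization and after each iteration."""
    import pandas as pd

    n0 = 2
    rows = [(n0, state.initial_entropy)]
    for d in state.decisions:
        rows.append((n0 + d.iteration, d.post_entropy))
    return pd.DataFrame(rows, columns=["n", "entropy"])


def run_campaign(
    config: CampaignConfig,
    measure: Callable[[float], Measurement],
    *,
    max_steps: Optional[int] = None,
) -> CampaignState:
    """Closed-loop campaign against a measurement source: initialize at the
    concentration extremes, then iterate until the stopping rule fires."""
    c_hi = config.prior.cmc_bounds[1]
    state = initialize_campaign(config, measure(0.0), measure(c_hi))
    steps = 0
    while state.status == "running":
        state = bed_step(state, measure)
        steps += 1
        if state.status == "awaiting_measurement":
            raise CampaignError("measurement source failed during a closed-loop campaign")
        if max_steps is not None and steps >= max_steps:
            break
    return state


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _profile_to_dict(p: Optional[EIGProfile]) -> Optional[dict]:
    if p is None:
        return None
    return {
        "candidates": [float(x) for x in p.candidates],
        "eig": [float(x) for x in p.eig],
        "se": [float(x) for x in p.mc_standard_error],
        "n_outer": [int(x) for x in p.n_outer],
        "reference_entropy": float(p.reference_entropy),
        "n_inner_failures": int(p.n_inner_failures),
    }


def _profile_from_dict(d: Optional[dict]) -> Optional[EIGProfile]:
    if d is None:
        return None
    return EIGProfile(
        candidates=np.asarray(d["candidates"]),
        eig=np.asarray(d["eig"]),
        mc_standard_error=np.asarray(d["se"]),
        n_outer=np.asarray(d["n_outer"]),
        reference_entropy=d["reference_entropy"],
        n_inner_failures=d.get("n_inner_failures", 0),
    )


def _sampler_to_dict(s: SamplerSettings) -> dict:
    return {
        "n_chains": s.n_chains,
        "n_warmup": s.n_warmup,
        "n_draws": s.n_draws,
        "seed": s.seed,
        "init_strategy": s.init_strategy,
        "thin": s.thin,
    }


def _config_to_dict(cfg: CampaignConfig) -> dict:
    return {
        "name": cfg.name,
        "seed": cfg.seed,
        "budget": cfg.budget,
        "ci_width_stop": cfg.ci_width_stop,
        "prior": {
            "gamma0_mean": cfg.prior.gamma0_mean,
            "gamma0_sd": cfg.prior.gamma0_sd,
            "k_bounds": list(cfg.prior.k_bounds),
            "a_bounds": list(cfg.prior.a_bounds),
            "cmc_bounds": list(cfg.prior.cmc_bounds),
            "cmc_prior_kind": cfg.prior.cmc_prior_kind,
        },
        "noise": {"sigma": cfg.noise.sigma},
        "sampler": _sampler_to_dict(cfg.sampler),
        "eig": {
            "n_outer": cfg.eig.n_outer,
            "seed": cfg.eig.seed,
            "common_random_numbers": cfg.eig.common_random_numbers,
            "inner_sampler": _sampler_to_dict(cfg.eig.inner_sampler),
        },
        "grid": {
            "candidates": [float(x) for x in cfg.grid.candidates],
            "spacing": cfg.grid.spacing,
            "refinement_rounds": cfg.grid.refinement_rounds,
            "refinement_factor": cfg.grid.refinement_factor,
        },
    }


def config_from_dict(d: dict) -> CampaignConfig:
    prior = PriorSpec(
        gamma0_mean=d["prior"]["gamma0_mean"],
        gamma0_sd=d["prior"]["gamma0_sd"],
        k_bounds=tuple(d["prior"]["k_bounds"]),
        a_bounds=tuple(d["prior"]["a_bounds"]),
        cmc_bounds=tuple(d["prior"]["cmc_bounds"]),
        cmc_prior_kind=d["prior"]["cmc_prior_kind"],
    )
    inner = d["eig"]["inner_sampler"]
    return CampaignConfig(
        prior=prior,
        noise=NoiseModel(sigma=d["noise"]["sigma"]),
        sampler=SamplerSettings(**d["sampler"]),
        eig=EIGSettings(
            n_outer=d["eig"]["n_outer"],
            seed=d["eig"]["seed"],
            common_random_numbers=d["eig"]["common_random_numbers"],
            inner_sampler=SamplerSettings(**inner),
        ),
        grid=DesignGrid(
            candidates=tuple(d["grid"]["candidates"]),
            spacing=d["grid"]["spacing"],
            refinement_rounds=d["grid"]["refinement_rounds"],
            refinement_factor=d["grid"]["refinement_factor"],
        ),
        budget=d["budget"],
        ci_width_stop=d["ci_width_stop"],
        seed=d["seed"],
        name=d.get("name", "campaign"),
    )


def _state_to_dict(state: CampaignState) -> dict:
    return {
        "schema_version": STATE_SCHEMA_VERSION,
        "config": _config_to_dict(state.config),
        "status": state.status,
        "initial_entropy": state.initial_entropy,
        "pending_concentration": state.pending_concentration,
        "pending_profile": _profile_to_dict(state.pending_profile),
        "measurements": [
            {"concentration": m.concentration, "surface_tension": m.surface_tension, "label": m.label}
            for m in state.data
        ],
        "decisions": [
            {
                "iteration": d.iteration,
                "chosen_concentration": d.chosen_concentration,
                "profile": _profile_to_dict(d.profile),
                "measurement": {
                    "concentration": d.measurement.concentration,
                    "surface_tension": d.measurement.surface_tension,
                    "label": d.measurement.label,
                },
                "post_entropy": d.post_entropy,
                "post_entropy_linear": d.post_entropy_linear,
                "ci": list(d.ci),
                "no_information": d.no_information,
            }
            for d in state.decisions
        ],
    }


def save_state(state: CampaignState, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_state_to_dict(state), fh, sort_keys=True, indent=2)
        fh.write("\n")


def load_state(path: str) -> CampaignState:
    try:
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise CampaignError(f"cannot load campaign state from {path!r}: {exc}") from exc
    version = d.get("schema_version")
    if version != STATE_SCHEMA_VERSION:
        raise CampaignError(f"unsupported state schema version {version!r}")
    cfg = config_from_dict(d["config"])
    data = Dataset(
        [Measurement(m["concentration"], m["surface_tension"], m["label"]) for m in d["measurements"]]
    )
    decisions = [
        DecisionRecord(
            iteration=x["iteration"],
            chosen_concentration=x["chosen_concentration"],
            profile=_profile_from_dict(x["profile"]),
            measurement=Measurement(
                x["measurement"]["concentration"],
                x["measurement"]["surface_tension"],
                x["measurement"]["label"],
            ),
            post_entropy=x["post_entropy"],
            post_entropy_linear=x["post_entropy_linear"],
            ci=tuple(x["ci"]),
            no_information=x.get("no_information", False),
        )
        for x in d["decisions"]
    ]
    state = CampaignState(
        config=cfg,
        data=data,
        decisions=decisions,
        status=d["status"],
        initial_entropy=d["initial_entropy"],
        pending_concentration=d["pending_concentration"],
        pending_profile=_profile_from_dict(d["pending_profile"]),
    )
    return state


def build_report(state: CampaignState) -> dict:
    """Deterministic JSON-ready campaign summary: final CI, mode, entropy
    trace, and the decision sequence."""
    cfg = state.config
    ci = state.current_ci
    if state.samples is None and len(state.data) >= 2:
        # re-fit with the same child seed the last recorded fit used, so a
        # loaded state reports the identical posterior summary
        _fit(state, state.iteration, 2 if state.decisions else 0)
    mode = None
    if state.samples is not None:
        dens = marginal_cmc_density(state.samples, cfg.prior, space=cfg.entropy_space)
        mr = posterior_mode_cmc(dens)
        mode = {"cmc": mr.cmc, "multimodal": mr.multimodal}
    trace = entropy_trace(state)
    return {
        "name": cfg.name,
        "status": state.status,
        "n_measurements": len(state.data),
        "entropy_space": cfg.entropy_space,
        "initial_entropy": state.initial_entropy,
        "final_entropy": state.current_entropy,
        "cmc_ci_90": list(ci) if ci is not None else None,
        "cmc_mode": mode,
        "entropy_trace": [{"n": int(n), "entropy": float(s)} for n, s in trace.itertuples(index=False)],
        "decisions": [
            {
                "iteration": d.iteration,
                "chosen_concentration": d.chosen_concentration,
                "measured_surface_tension": d.measurement.surface_tension,
                "post_entropy": d.post_entropy,
                "post_entropy_linear": d.post_entropy_linear,
                "ci": list(d.ci),
            }
            for d in state.decisions
        ],
    }
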