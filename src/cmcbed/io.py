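"""File formats, configuration presets, and synthetic-data generation.

Canonical units everywhere: concentration in mol/m^3 (numerically equal to
mM) and surface tension in N/m.  The measurement CSV dialect is

    concentration_mol_m3,surface_tension_N_m,label

with '.' decimals, UTF-8, and an optional integer label column.  Values in
the surface-tension column above 1 almost certainly mean the file is in
mN/m; reading such a file raises unless an explicit unit flag is passed.

Two named configuration presets mirror the package's case studies: "otg"
(uniform CMC prior on [0, 30] mol/m^3) and "triton" (log-uniform on
[0.001, 10] mol/m^3).  The matching synthetic truths place the OTG-like CMC
at 9.7 mol/m^3 and the Triton-like CMC at 0.45 mol/m^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .isotherm import Dataset, IsothermParams, Measurement, NoiseModel, PriorSpec, simulate_measurement
from .posterior import SamplerSettings
from .design import DesignGrid, EIGSettings
from .campaign import CampaignConfig

__all__ = [
    "MeasurementCSVError",
    "ConfigError",
    "read_measurements",
    "write_measurements",
    "load_config",
    "preset_config",
    "SyntheticScenario",
    "preset_scenario",
    "generate_synthetic_dataset",
    "PRESET_NAMES",
]

CSV_COLUMNS = ("concentration_mol_m3", "surface_tension_N_m", "label")
PRESET_NAMES = ("otg", "triton")

# Physical sanity window for lab surface tensions [N/m]; enforced at I/O.
GAMMA_SANITY = (0.0, 0.2)


class MeasurementCSVError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def read_measurements(
    path,
    *,
    surface_tension_unit: str = "N/m",
    concentration_unit: str = "mol/m^3",
) -> Dataset:
    """Read a measurement CSV; lossless inverse of :func:`write_measurements`.

    Unit flags convert mN/m and mol/L explicitly; without them, suspicious
    magnitudes (surface tension > 1) are treated as errors rather than
    silently converted.
    """
    if surface_tension_unit not in ("N/m", "mN/m"):
        raise MeasurementCSVError(f"unsupported surface tension unit {surface_tension_unit!r}")
    if concentration_unit not in ("mol/m^3", "mM", "mol/L"):
        raise MeasurementCSVError(f"unsupported concentration unit {concentration_unit!r}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise MeasurementCSVError(f"{path}: empty file without header") from exc
    missing = [c for c in CSV_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise MeasurementCSVError(f"{path}: missing required column(s) {missing}")
    if "label" not in df.columns:
        df["label"] = None

    measurements = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        c_raw, g_raw = getattr(row, CSV_COLUMNS[0]), getattr(row, CSV_COLUMNS[1])
        try:
            c = float(c_raw)
            g = float(g_raw)
        except (TypeError, ValueError) as exc:
            raise MeasurementCSVError(f"{path}: non-numeric cell on line {i}") from exc
        if not np.isfinite(c) or c < 0:
            raise MeasurementCSVError(f"{path}: negative or non-finite concentration on line {i}")
        if surface_tension_unit == "N/m" and g > 1.0:
            raise MeasurementCSVError(
                f"{path}: surface tension {g} on line {i} looks like mN/m; "
                "pass surface_tension_unit='mN/m' to convert explicitly"
            )
        if surface_tension_unit == "mN/m":
            g = g / 1000.0
        if concentration_unit == "mol/L":
            c = c * 1000.0
        if not (GAMMA_SANITY[0] < g < GAMMA_SANITY[1]):
            raise MeasurementCSVError(
                f"{path}: surface tension {g} N/m on line {i} outside the sanity window {GAMMA_SANITY}"
            )
        label_raw = getattr(row, "label")
        label = None if label_raw is None or (isinstance(label_raw, float) and math.isnan(label_raw)) else int(label_raw)
        measurements.append(Measurement(c, g, label))
    return Dataset(measurements)


def write_measurements(data: Dataset, path) -> None:
    df = pd.DataFrame(
        {
            CSV_COLUMNS[0]: [m.concentration for m in data],
            CSV_COLUMNS[1]: [m.surface_tension for m in data],
            CSV_COLUMNS[2]: [m.label if m.label is not None else "" for m in data],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_PRESET_PRIORS = {
    "otg": PriorSpec(cmc_bounds=(0.0, 30.0), cmc_prior_kind="uniform"),
    "triton": PriorSpec(cmc_bounds=(0.001, 10.0), cmc_prior_kind="log_uniform"),
}

_PRESET_TRUTHS = {
    "otg": IsothermParams(gamma0=0.0718, a=0.0115, k=4.0, cmc=9.7),
    "triton": IsothermParams(gamma0=0.0718, a=0.008, k=450.0, cmc=0.45),
}


def preset_config(name: str, *, seed: int = 0, **overrides) -> CampaignConfig:
    """Named campaign preset: 'otg' or 'triton'."""
    if name not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    prior = _PRESET_PRIORS[name]
    cfg = CampaignConfig(prior=prior, seed=seed, name=name)
    return replace(cfg, **overrides) if overrides else cfg


def load_config(path_or_preset: str, *, seed: Optional[int] = None) -> CampaignConfig:
    """Load a campaign configuration from YAML, or by preset name.

    The YAML may set ``preset: otg|triton`` and override any section
    (prior, noise, sampler, eig, grid, budget, ci_width_stop, seed).  All
    violations are collected and reported together.
    """
    if path_or_preset in PRESET_NAMES:
        return preset_config(path_or_preset, seed=seed if seed is not None else 0)
    with open(path_or_preset, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path_or_preset}: config must be a mapping")

    problems: list[str] = []
    preset = raw.get("preset")
    if preset is not None and preset not in PRESET_NAMES:
        raise ConfigError(f"{path_or_preset}: unknown preset {preset!r}")
    prior_base = _PRESET_PRIORS.get(preset, PriorSpec())

    def section(name) -> dict:
        v = raw.get(name, {}) or {}
        if not isinstance(v, dict):
            problems.append(f"section {name!r} must be a mapping")
            return {}
        return v

    p = section("prior")
    prior_kwargs = dict(
        gamma0_mean=p.get("gamma0_mean", prior_base.gamma0_mean),
        gamma0_sd=p.get("gamma0_sd", prior_base.gamma0_sd),
        k_bounds=tuple(p.get("k_bounds", prior_base.k_bounds)),
        a_bounds=tuple(p.get("a_bounds", prior_base.a_bounds)),
        cmc_bounds=tuple(p.get("cmc_bounds", prior_base.cmc_bounds)),
        cmc_prior_kind=p.get("cmc_prior_kind", prior_base.cmc_prior_kind),
    )
    nz = section("noise")
    sampler_kw = section("sampler")
    eig_kw = dict(section("eig"))
    inner_kw = eig_kw.pop("inner_sampler", {}) or {}
    grid_kw = section("grid")

    prior = noise = sampler = eig = None
    try:
        prior = PriorSpec(**prior_kwargs)
    except (ValueError, TypeError) as exc:
        problems.append(f"prior: {exc}")
    try:
        noise = NoiseModel(**nz)
    except (ValueError, TypeError) as exc:
        problems.append(f"noise: {exc}")
    try:
        sampler = SamplerSettings(**sampler_kw)
    except (ValueError, TypeError) as exc:
        problems.append(f"sampler: {exc}")
    try:
        if inner_kw:
            inner_defaults = {
                "n_chains": 8, "n_warmup": 120, "n_draws": 120,
                "thin": 3, "init_strategy": "warm_start",
            }
            inner = SamplerSettings(**{**inner_defaults, **inner_kw})
            eig = EIGSettings(inner_sampler=inner, **eig_kw)
        else:
            eig = EIGSettings(**eig_kw)
    except (ValueError, TypeError) as exc:
        problems.append(f"eig: {exc}")

    grid = None
    if grid_kw and prior is not None:
        try:
            if "candidates" in grid_kw:
                grid = DesignGrid(
                    candidates=tuple(float(x) for x in grid_kw["candidates"]),
                    spacing=grid_kw.get("spacing", "uniform"),
                    refinement_rounds=grid_kw.get("refinement_rounds", 1),
                    refinement_factor=grid_kw.get("refinement_factor", 5),
                )
            else:
                grid = DesignGrid.from_prior(
                    prior,
                    n_points=grid_kw.get("n_points", 20),
                    refinement_rounds=grid_kw.get("refinement_rounds", 1),
                    extend=grid_kw.get("extend", 1.0),
                )
        except (ValueError, TypeError) as exc:
            problems.append(f"grid: {exc}")

    budget = raw.get("budget", 9)
    ci_width_stop = raw.get("ci_width_stop")
    cfg_seed = seed if seed is not None else raw.get("seed", 0)
    if problems:
        raise ConfigError(f"{path_or_preset}: invalid configuration:\n  - " + "\n  - ".join(problems))
    try:
        return CampaignConfig(
            prior=prior,
            noise=noise,
            sampler=sampler,
            eig=eig,
            grid=grid,
            budget=budget,
            ci_width_stop=ci_width_stop,
            seed=cfg_seed,
            name=raw.get("name", preset or "campaign"),
        )
    except ValueError as exc:
        raise ConfigError(f"{path_or_preset}: invalid configuration: {exc}") from exc


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticScenario:
    """A named in-silico study condition: a ground-truth parameter vector
    inside a prior's support plus the homoskedastic noise level."""

    name: str
    truth: IsothermParams
    prior: PriorSpec
    noise: NoiseModel = NoiseModel()

    def __post_init__(self) -> None:
        from .isotherm import log_prior_density

        if log_prior_density(self.truth, self.prior) == -np.inf:
            raise ValueError("scenario truth must lie inside the prior support")


def preset_scenario(name: str) -> SyntheticScenario:
    """OTG-like (gamma0 0.0718, a 0.0115, k 4.0, c* 9.7, uniform prior) or
    Triton-like (a 0.008, k 450, c* 0.45, log-uniform prior) truth."""
    if name not in PRESET_NAMES:
        raise ConfigError(f"unknown scenario {name!r}; available: {PRESET_NAMES}")
    return SyntheticScenario(name=name, truth=_PRESET_TRUTHS[name], prior=_PRESET_PRIORS[name])


def generate_synthetic_dataset(
    scenario: SyntheticScenario,
    concentrations: Sequence[float],
    seed: int,
) -> Dataset:
    """Noisy measurements from the scenario truth at the given concentrations."""
    rng = np.random.default_rng(seed)
    out = Dataset([])
    for c in concentrations:
        out.append(simulate_measurement(scenario.truth, float(c), scenario.noise, rng))
    return out
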