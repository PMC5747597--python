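"""Synthetic validation-study generator.

The generative model mirrors the alternating measurement protocol: each
subject has a true value per variable (truncated normal across the cohort),
each session adds a subject x session shift, each of the seven positions has
its own latent value (serial biological variation), and each device adds its
own noise.  The test device can carry a constant and/or proportional bias.
A configurable fraction of subjects completes only session 1.

Everything is reproducible from a single seed, and a study generated with
all noise terms at zero reproduces the subjects' true values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from scipy import stats

from .model import (
    N_POSITIONS,
    ParticipantProfile,
    SessionSeries,
    Sex,
    StudyDataset,
    Variable,
)
from .protocol import validate_device, ProtocolError

__all__ = [
    "VariableModel",
    "SimulationConfig",
    "generate_study",
    "pass_probability",
    "PassProbability",
    "load_scenario",
    "packaged_scenario_path",
    "PACKAGED_SCENARIOS",
]

PACKAGED_SCENARIOS = ("paper_like", "biased_device", "noisy_device")


@dataclass(frozen=True)
class VariableModel:
    """Population model for one variable."""

    mean: float
    sd: float
    trunc_low: float
    trunc_high: float
    within_subject_sd: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.within_subject_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not self.trunc_low < self.trunc_high:
            raise ValueError("invalid truncation range")


def _default_variables() -> dict[str, VariableModel]:
    return {
        "SBP": VariableModel(127.0, 16.0, 90.0, 180.0, 3.0),
        "DBP": VariableModel(74.0, 10.0, 40.0, 130.0, 3.0),
        "HR": VariableModel(71.0, 10.0, 40.0, 180.0, 2.5),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative model for a synthetic validation study."""

    n_subjects: int = 100
    seed: int = 0
    variables: dict[str, VariableModel] = field(default_factory=_default_variables)
    session_effect_sd: float = 2.0
    criterion_noise_sd: float = 1.5
    test_noise_sd: float = 1.5
    test_bias: float = 0.0
    test_proportional_bias: float = 0.0
    position_drift: float = 0.0  # linear per-position change of the latent value
    dropout: float = 0.2
    integer_rounding: bool = True
    generate_profiles: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for name in (
            "session_effect_sd", "criterion_noise_sd", "test_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        for key in self.variables:
            Variable(key)  # raises on unknown labels

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        raw_vars = data.pop("variables", None)
        kwargs = dict(data)
        if raw_vars is not None:
            merged = _default_variables()
            for key, spec in raw_vars.items():
                base = asdict(merged[key]) if key in merged else {}
                base.update(spec)
                merged[key] = VariableModel(**base)
            kwargs["variables"] = merged
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["variables"] = {k: asdict(v) for k, v in self.variables.items()}
        return out

    def replace(self, **kwargs) -> "SimulationConfig":
        data = self.to_dict()
        data.update(kwargs)
        return SimulationConfig.from_dict(data)


def load_scenario(source: Union[str, Path]) -> SimulationConfig:
    """Load a scenario from a YAML file path or a packaged scenario name."""
    path = Path(source)
    if not path.exists() and str(source) in PACKAGED_SCENARIOS:
        path = packaged_scenario_path(str(source))
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def packaged_scenario_path(name: str) -> Path:
    if name not in PACKAGED_SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; available: {PACKAGED_SCENARIOS}")
    return Path(resources.files("bpval") / "scenarios" / f"{name}.yaml")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_study(config: SimulationConfig) -> StudyDataset:
    """Generate a complete synthetic study dataset from the config.

    Subjects are labelled ``S001``...; those hit by dropout have no
    session-2 series.  The number dropping out is the rounded fraction, so
    e.g. 125 subjects at 20% dropout leave exactly 100 completers.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = [f"S{i + 1:03d}" for i in range(n)]

    dataset = StudyDataset(metadata={"generator_seed": config.seed,
                                     "config": config.to_dict()})

    # dropout: which subjects never return for session 2
    n_drop = int(np.floor(config.dropout * n + 0.5))
    dropouts = set(rng.choice(n, size=n_drop, replace=False).tolist())

    positions = np.arange(1, N_POSITIONS + 1)
    drift = config.position_drift * (positions - 1)
    odd = positions % 2 == 1

    for var_name, vm in config.variables.items():
        variable = Variable(var_name)
        true_vals = _truncated_normal(
            rng, vm.mean, vm.sd, vm.trunc_low, vm.trunc_high, n
        )
        for sess in (1, 2):
            shift = rng.normal(0.0, config.session_effect_sd, size=n)
            eps = rng.normal(0.0, vm.within_subject_sd, size=(n, N_POSITIONS))
            eta_c = rng.normal(0.0, config.criterion_noise_sd, size=(n, N_POSITIONS))
            eta_t = rng.normal(0.0, config.test_noise_sd, size=(n, N_POSITIONS))
            latent = true_vals[:, None] + shift[:, None] + eps + drift[None, :]
            readings = np.where(
                odd[None, :],
                latent + eta_c,
                latent
                + config.test_bias
                + config.test_proportional_bias * (true_vals[:, None] - vm.mean)
                + eta_t,
            )
            if config.integer_rounding:
                readings = np.rint(readings)
            for i, pid in enumerate(ids):
                if sess == 2 and i in dropouts:
                    continue
                dataset.add_series(
                    SessionSeries(pid, sess, variable, list(map(float, readings[i])))
                )

    if config.generate_profiles:
        dataset.profiles = _generate_profiles(rng, ids)
    return dataset


def _generate_profiles(
    rng: np.random.Generator, ids: Sequence[str]
) -> dict[str, ParticipantProfile]:
    """Plausible demographics on the scale of a middle-aged volunteer cohort."""
    n = len(ids)
    male = rng.random(n) < 0.37
    age = np.clip(rng.normal(52.0, 19.0, n), 25.0, 90.0)
    height = np.where(male, rng.normal(172.0, 7.0, n), rng.normal(164.5, 7.5, n))
    weight = np.where(male, rng.normal(84.5, 13.0, n), rng.normal(71.5, 13.0, n))
    arm = np.clip(rng.normal(295.0, 25.0, n), 225.0, 320.0)
    return {
        pid: ParticipantProfile(
            participant_id=pid,
            sex=Sex.MALE if male[i] else Sex.FEMALE,
            age=round(float(age[i]), 1),
            weight_kg=round(float(np.clip(weight[i], 45.0, 130.0)), 1),
            height_cm=round(float(np.clip(height[i], 148.0, 195.0)), 1),
            arm_circ_mm=round(float(arm[i])),
        )
        for i, pid in enumerate(ids)
    }


@dataclass(frozen=True)
class PassProbability:
    fraction: float
    n_pass: int
    n_replicates: int
    ci_low: float
    ci_high: float


def pass_probability(
    config: SimulationConfig,
    n_replicates: int = 200,
    variables: Sequence[str] = ("SBP", "DBP", "HR"),
    confidence: float = 0.95,
) -> PassProbability:
    """Fraction of replicate synthetic studies passing the validation protocol.

    Each replicate uses a seed derived from the config seed.  Replicates in
    which too few subjects complete both sessions count as failures.  The
    interval is Clopper-Pearson.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_replicates)
    n_pass = 0
    for rep_seed in seeds:
        dataset = generate_study(config.replace(seed=int(rep_seed)))
        try:
            verdict = validate_device(dataset, variables=variables)
        except ProtocolError:
            continue
        n_pass += verdict.passed
    alpha = 1 - confidence
    lo = (
        0.0 if n_pass == 0
        else float(stats.beta.ppf(alpha / 2, n_pass, n_replicates - n_pass + 1))
    )
    hi = (
        1.0 if n_pass == n_replicates
        else float(stats.beta.ppf(1 - alpha / 2, n_pass + 1, n_replicates - n_pass))
    )
    return PassProbability(
        fraction=n_pass / n_replicates,
        n_pass=n_pass,
        n_replicates=n_replicates,
        ci_low=lo,
        ci_high=hi,
    )
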