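"""Synthetic factorial heat-stress trials.

The generator emulates a controlled-chamber experiment: a panel of cultivars,
each with its own control-condition trait baselines and a tolerance
coefficient tau in [0, 1] (1 = fully tolerant), exposed to a temperature x
relative-humidity x duration factorial during grain filling. Stress is
summarised by a multiplicative index

    S(T, RH, D) = s_T(T) * (1 + w(T) * (RH_ref - RH) / RH_ref) * (D / D_ref)

clipped to [0, 1]: s_T is a monotone non-decreasing severity per temperature
level, w(T) weights the extra damage from drier air (largest at 35 degC,
where transpiration demand outpaces cooling), and damage accumulates with
duration. Traits that decline under stress (grain weight, head rice rate)
respond as baseline * (1 - (1 - tau) * S); chalkiness, which rises under
stress, responds as baseline + (1 - tau) * C_max * S. Replicates add
independent Gaussian noise, truncated at the trait's domain bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .trial import (
    PERCENT_TRAITS,
    RATIO_TRAITS,
    TRAITS,
    TreatmentKey,
    Trial,
    make_trial,
    trial_to_frame,
)


@dataclass(frozen=True)
class CultivarProfile:
    """Control-condition baselines and heat tolerance for one cultivar."""

    name: str
    baselines: Mapping[str, float]  # trait -> control mean
    tolerance: float  # tau in [0, 1]; 1 = unaffected by stress

    def validate(self):
        if not 0.0 <= self.tolerance <= 1.0:
            raise ConfigError(f"{self.name}: tolerance must lie in [0, 1]")
        for trait in TRAITS:
            if trait not in self.baselines:
                raise ConfigError(f"{self.name}: missing baseline for {trait}")
            if self.baselines[trait] <= 0:
                raise ConfigError(f"{self.name}: baseline for {trait} must be > 0")


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic trial.

    Defaults mirror the screening design this package targets: 3 temperature
    levels x 2 RH levels x 2 durations, 3 replicates, with the RH effect
    peaked at 35 degC.
    """

    cultivars: Sequence[CultivarProfile]
    temperature_levels: tuple = (33.0, 35.0, 37.0)
    rh_levels: tuple = (75.0, 85.0)
    duration_levels: tuple = (8.0, 15.0)
    #: monotone severity of each temperature level, in [0, 1]
    temperature_severity: Mapping[float, float] = field(
        default_factory=lambda: {33.0: 0.35, 35.0: 0.55, 37.0: 0.80}
    )
    #: per-temperature weight of the dry-air aggravation
    rh_weight: Mapping[float, float] = field(
        default_factory=lambda: {33.0: 0.6, 35.0: 1.0, 37.0: 0.15}
    )
    rh_ref: float = 85.0
    duration_ref: float = 15.0
    #: chalkiness added at full stress in a fully intolerant cultivar (%)
    chalkiness_scale: float = 40.0
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "grain_weight": 0.35,
            "head_rice_rate": 1.5,
            "chalkiness": 1.2,
        }
    )
    n_replicates: int = 3
    seed: int = 0

    def validate(self):
        if not self.cultivars:
            raise ConfigError("at least one cultivar profile is required")
        for p in self.cultivars:
            p.validate()
        for t in self.temperature_levels:
            if t not in self.temperature_severity:
                raise ConfigError(f"no severity for temperature {t}")
            if t not in self.rh_weight:
                raise ConfigError(f"no RH weight for temperature {t}")
            if self.rh_weight[t] < 0:
                raise ConfigError("rh_weight values must be >= 0")
        sev = [self.temperature_severity[t] for t in sorted(self.temperature_levels)]
        if any(b < a for a, b in zip(sev, sev[1:])):
            raise ConfigError("temperature severity must be non-decreasing in T")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ConfigError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    def treatments(self) -> list[TreatmentKey]:
        return sorted(
            TreatmentKey(t, r, d)
            for t in self.temperature_levels
            for r in self.rh_levels
            for d in self.duration_levels
        )


def stress_index(config: GeneratorConfig, treatment: TreatmentKey) -> float:
    """Closed-form stress index S(T, RH, D), clipped to [0, 1]."""
    if treatment.is_control:
        return 0.0
    s_t = config.temperature_severity[treatment.temperature]
    w = config.rh_weight[treatment.temperature]
    rh_term = 1.0 + w * (config.rh_ref - treatment.rh) / config.rh_ref
    d_term = treatment.duration / config.duration_ref
    return float(np.clip(s_t * rh_term * d_term, 0.0, 1.0))


def expected_cell_mean(
    config: GeneratorConfig,
    profile: CultivarProfile,
    treatment: TreatmentKey,
    trait: str,
) -> float:
    """Noise-free cell mean implied by the response surface."""
    base = float(profile.baselines[trait])
    s = stress_index(config, treatment)
    damage = (1.0 - profile.tolerance) * s
    if trait in RATIO_TRAITS:
        return base * (1.0 - damage)
    return base + (1.0 - profile.tolerance) * config.chalkiness_scale * s


def _cell_rng(seed: int, ci: int, ti: int, trait_i: int) -> np.random.Generator:
    # one independent stream per cultivar x treatment x trait, keyed on the
    # master seed, so generation order cannot change the draws
    return np.random.default_rng(np.random.SeedSequence([seed, ci, ti, trait_i]))


def generate_trial(config: GeneratorConfig, seed: int | None = None) -> Trial:
    """Draw a full replicate-level trial from the response surface."""
    config.validate()
    master = config.seed if seed is None else int(seed)
    treatments = config.treatments()
    rows = []
    for ci, profile in enumerate(config.cultivars):
        keys = treatments + [TreatmentKey.control()]
        for ti, key in enumerate(keys):
            for trait_i, trait in enumerate(TRAITS):
                mu = expected_cell_mean(config, profile, key, trait)
                sd = float(config.noise_sd.get(trait, 0.0))
                rng = _cell_rng(master, ci, ti, trait_i)
                vals = mu + rng.normal(0.0, sd, size=config.n_replicates) if sd > 0 \
                    else np.full(config.n_replicates, mu)
                hi = 100.0 if trait in PERCENT_TRAITS else np.inf
                vals = np.clip(vals, 0.0, hi)
                for rep, v in enumerate(vals, start=1):
                    rows.append(
                        {
                            "cultivar": profile.name,
                            "temperature_c": key.temperature,
                            "rh_pct": key.rh,
                            "duration_d": key.duration,
                            "is_control": key.is_control,
                            "replicate": rep,
                            "trait": trait,
                            "value": float(v),
                        }
                    )
    return make_trial(trial_to_frame(rows))


def six_cultivar_preset(seed: int = 0) -> GeneratorConfig:
    """A screening-trial preset: six indica cultivars spanning tolerance.

    One cultivar (HT1) is strongly heat tolerant (tau = 0.9); the other five
    spread over [0.2, 0.6]. Baselines are typical for mid-season indica rice:
    thousand-grain weight 23-28 g, head rice rate 55-68 %, control
    chalkiness 2-6 %.
    """
    profiles = (
        CultivarProfile("HT1", {"grain_weight": 24.5, "head_rice_rate": 62.0,
                                "chalkiness": 3.0}, 0.90),
        CultivarProfile("CV2", {"grain_weight": 27.0, "head_rice_rate": 58.0,
                                "chalkiness": 4.5}, 0.60),
        CultivarProfile("CV3", {"grain_weight": 25.5, "head_rice_rate": 65.0,
                                "chalkiness": 2.5}, 0.50),
        CultivarProfile("CV4", {"grain_weight": 23.0, "head_rice_rate": 55.0,
                                "chalkiness": 6.0}, 0.40),
        CultivarProfile("CV5", {"grain_weight": 28.0, "head_rice_rate": 68.0,
                                "chalkiness": 3.5}, 0.30),
        CultivarProfile("CV6", {"grain_weight": 26.0, "head_rice_rate": 60.0,
                                "chalkiness": 5.0}, 0.20),
    )
    return GeneratorConfig(cultivars=profiles, seed=seed)


def config_to_yaml(config: GeneratorConfig, path: str | Path) -> None:
    doc = {
        "cultivars": [
            {"name": p.name, "baselines": dict(p.baselines),
             "tolerance": p.tolerance}
            for p in config.cultivars
        ],
        "temperature_levels": list(config.temperature_levels),
        "rh_levels": list(config.rh_levels),
        "duration_levels": list(config.duration_levels),
        "temperature_severity": {str(k): v for k, v in
                                 config.temperature_severity.items()},
        "rh_weight": {str(k): v for k, v in config.rh_weight.items()},
        "rh_ref": config.rh_ref,
        "duration_ref": config.duration_ref,
        "chalkiness_scale": config.chalkiness_scale,
        "noise_sd": dict(config.noise_sd),
        "n_replicates": config.n_replicates,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    doc = yaml.safe_load(Path(path).read_text())
    profiles = tuple(
        CultivarProfile(c["name"], c["baselines"], float(c["tolerance"]))
        for c in doc["cultivars"]
    )
    cfg = GeneratorConfig(
        cultivars=profiles,
        temperature_levels=tuple(float(t) for t in doc["temperature_levels"]),
        rh_levels=tuple(float(r) for r in doc["rh_levels"]),
        duration_levels=tuple(float(d) for d in doc["duration_levels"]),
        temperature_severity={float(k): float(v) for k, v in
                              doc["temperature_severity"].items()},
        rh_weight={float(k): float(v) for k, v in doc["rh_weight"].items()},
        rh_ref=float(doc["rh_ref"]),
        duration_ref=float(doc["duration_ref"]),
        chalkiness_scale=float(doc["chalkiness_scale"]),
        noise_sd={k: float(v) for k, v in doc["noise_sd"].items()},
        n_replicates=int(doc["n_replicates"]),
        seed=int(doc["seed"]),
    )
    cfg.validate()
    return cfg
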