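"""TOML configuration, scenario presets and validation.

A run config has up to four tables::

    scenario = "fig1"          # optional preset name
    seed = 1
    output_dir = "out"

    [payoff]    # B0 B1 B2 K1 K11 K12
    [learning]  # sigma alpha_w alpha_theta T w_init theta_init clamp_actions
    [group]     # g, q (true qualities), d (biases, optional) — for nash/learn
    [evo]       # N g quality_values quality_weights mu mut_sd G d_init fitness_floor

Preset values override package defaults; file values override the preset;
command-line options override the file.  Unknown keys are rejected.
Presets carry only values printed in the source scenario descriptions;
everything else is a package default and is listed as such in the
provenance block written next to the outputs.
"""

from __future__ import annotations

import copy
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .actor_critic import LearningConfig
from .errors import ConfigError
from .evolution import EvoConfig
from .game_core import GroupComposition, PayoffParams

__all__ = ["RunConfig", "GroupSpec", "PRESETS", "load_config", "config_from_dict"]


@dataclass(frozen=True)
class GroupSpec:
    """A single group for the `nash` and `learn` commands."""

    q: tuple[float, ...]
    d: tuple[float, ...] | None = None

    def composition(self) -> GroupComposition:
        d = self.d if self.d is not None else tuple(0.0 for _ in self.q)
        return GroupComposition.from_bias(self.q, d)

    @property
    def g(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one command invocation."""

    payoff: PayoffParams
    learning: LearningConfig
    group: GroupSpec | None = None
    evo: EvoConfig | None = None
    scenario: str | None = None
    seed: int = 0
    output_dir: str = "out"
    preset_keys: tuple[str, ...] = field(default=(), compare=False)


_FIG1_PAYOFF = {"B0": 1.0, "B1": 4.0, "B2": -2.0, "K1": 1.0, "K11": 1.0, "K12": -1.0}
_FIG1_LEARNING = {
    "sigma": 0.05,
    "alpha_w": 0.04,
    "alpha_theta": 0.002,
    "w_init": 1.0,
    "theta_init": 0.2,
}
_FIVE_SET = [0.0, 0.25, 0.5, 0.75, 1.0]


def _fig_evo(**kw: Any) -> dict[str, Any]:
    base: dict[str, Any] = {"N": 24000, "g": 2}
    base.update(kw)
    return base


#: Scenario presets.  Values here are the reference scenario settings; keys
#: not present (e.g. T, G) fall back to package defaults and are flagged as
#: artifact defaults in the provenance block.
PRESETS: dict[str, dict[str, Any]] = {
    "fig1": {
        "payoff": dict(_FIG1_PAYOFF),
        "learning": dict(_FIG1_LEARNING),
        "group": {"q": [0.0, 1.0]},
    },
    "fig2": {
        "payoff": dict(_FIG1_PAYOFF),
        "learning": dict(_FIG1_LEARNING),
        "evo": _fig_evo(quality_values=[0.0, 1.0], mu=0.0, mut_sd=0.0, G=1),
    },
    "fig3a": {
        "payoff": dict(_FIG1_PAYOFF),
        "learning": dict(_FIG1_LEARNING),
        "evo": _fig_evo(quality_values=[1.0], mu=0.05, mut_sd=0.04),
    },
    "fig3b": {
        "payoff": dict(_FIG1_PAYOFF),
        "learning": dict(_FIG1_LEARNING),
        "evo": _fig_evo(quality_values=list(_FIVE_SET), mu=0.001, mut_sd=0.04),
    },
    "fig4-g2": {
        "payoff": dict(_FIG1_PAYOFF),
        "learning": dict(_FIG1_LEARNING),
        "evo": _fig_evo(quality_values=list(_FIVE_SET), mu=0.001, mut_sd=0.04, g=2),
    },
    "fig4-g3": {
        "payoff": dict(_FIG1_PAYOFF),
        "learning": dict(_FIG1_LEARNING),
        "evo": _fig_evo(quality_values=list(_FIVE_SET), mu=0.001, mut_sd=0.04, g=3),
    },
    "fig4-g5": {
        "payoff": dict(_FIG1_PAYOFF),
        "learning": dict(_FIG1_LEARNING),
        "evo": _fig_evo(quality_values=list(_FIVE_SET), mu=0.001, mut_sd=0.04, g=5),
    },
}

_SCHEMA: dict[str, set[str]] = {
    "": {"scenario", "seed", "output_dir", "payoff", "learning", "group", "evo"},
    "payoff": {"B0", "B1", "B2", "K1", "K11", "K12"},
    "learning": {
        "sigma",
        "alpha_w",
        "alpha_theta",
        "T",
        "w_init",
        "theta_init",
        "clamp_actions",
    },
    "group": {"g", "q", "d"},
    "evo": {
        "N",
        "g",
        "quality_values",
        "quality_weights",
        "mu",
        "mut_sd",
        "G",
        "d_init",
        "fitness_floor",
        "warm_start",
    },
}


def _check_keys(data: dict[str, Any]) -> None:
    bad: list[str] = []
    for key, value in data.items():
        if key not in _SCHEMA[""]:
            bad.append(key)
        elif isinstance(value, dict):
            allowed = _SCHEMA.get(key, set())
            bad.extend(f"{key}.{k}" for k in value if k not in allowed)
    if bad:
        raise ConfigError("unknown configuration keys: " + ", ".join(sorted(bad)))


def _dotted_keys(data: dict[str, Any]) -> tuple[str, ...]:
    keys: list[str] = []
    for key, value in data.items():
        if isinstance(value, dict):
            keys.extend(f"{key}.{k}" for k in value)
        else:
            keys.append(key)
    return tuple(sorted(keys))


def _merge(base: dict[str, Any], override: dict[str, Any]) -> dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Validate a merged config dict and build the typed config."""
    _check_keys(data)
    scenario = data.get("scenario")
    if scenario is not None:
        if scenario not in PRESETS:
            raise ConfigError(
                f"unknown scenario {scenario!r}; available: {', '.join(sorted(PRESETS))}"
            )
        preset = PRESETS[scenario]
        merged = _merge(preset, {k: v for k, v in data.items() if k != "scenario"})
        preset_keys = _dotted_keys(preset)
    else:
        merged = data
        preset_keys = ()

    if "payoff" not in merged:
        raise ConfigError("missing [payoff] table")
    payoff = PayoffParams(**merged["payoff"])
    learning = LearningConfig(**merged.get("learning", {}))

    group = None
    if "group" in merged:
        gtab = dict(merged["group"])
        q = tuple(float(v) for v in gtab["q"])
        if "g" in gtab and int(gtab["g"]) != len(q):
            raise ConfigError("group.g inconsistent with length of group.q")
        d = gtab.get("d")
        if d is not None:
            d = tuple(float(v) for v in d)
            if len(d) != len(q):
                raise ConfigError("group.d must match group.q in length")
        group = GroupSpec(q=q, d=d)

    evo = None
    if "evo" in merged:
        etab = dict(merged["evo"])
        etab["quality_values"] = tuple(etab.get("quality_values", ()))
        if etab.get("quality_weights") is not None:
            etab["quality_weights"] = tuple(etab["quality_weights"])
        # Evolutionary runs default to longer interactions (T=3000) so that
        # fitness is dominated by converged play; an explicit learning.T wins.
        evo_ltab = dict(merged.get("learning", {}))
        evo_ltab.setdefault("T", 3000)
        evo = EvoConfig(learning=LearningConfig(**evo_ltab), **etab)

    return RunConfig(
        payoff=payoff,
        learning=learning,
        group=group,
        evo=evo,
        scenario=scenario,
        seed=int(merged.get("seed", 0)),
        output_dir=str(merged.get("output_dir", "out")),
        preset_keys=preset_keys,
    )


def load_config(
    path: str | Path | None = None,
    scenario: str | None = None,
    seed: int | None = None,
    output_dir: str | None = None,
) -> RunConfig:
    """Read a TOML config file and apply command-line overrides."""
    data: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            data = tomllib.loads(path.read_text())
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"could not parse {path}: {exc}") from exc
    if scenario is not None:
        data["scenario"] = scenario
    if seed is not None:
        data["seed"] = seed
    if output_dir is not None:
        data["output_dir"] = output_dir
    if not data:
        raise ConfigError("no configuration given (need --config and/or --scenario)")
    return config_from_dict(data)


def resolved_dict(config: RunConfig) -> dict[str, Any]:
    """Plain-dict view of a resolved config (for provenance output)."""
    out: dict[str, Any] = {
        "scenario": config.scenario,
        "seed": config.seed,
        "payoff": {k: getattr(config.payoff, k) for k in _SCHEMA["payoff"]},
        "learning": {k: getattr(config.learning, k) for k in _SCHEMA["learning"]},
    }
    if config.group is not None:
        out["group"] = {
            "g": config.group.g,
            "q": list(config.group.q),
            "d": None if config.group.d is None else list(config.group.d),
        }
    if config.evo is not None:
        evo = config.evo
        out["evo"] = {
            "N": evo.N,
            "g": evo.g,
            "quality_values": list(evo.quality_values),
            "quality_weights": None
            if evo.quality_weights is None
            else list(evo.quality_weights),
            "mu": evo.mu,
            "mut_sd": evo.mut_sd,
            "G": evo.G,
            "d_init": evo.d_init,
            "fitness_floor": evo.fitness_floor,
        }
    return out
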