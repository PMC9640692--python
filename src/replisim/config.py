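"""Run configuration: TOML file + command-line overrides + defaults.

A run is described by a model name, engine parameters, the model family's
kinetic constants, and noise settings.  Precedence: CLI overrides > config
file > package defaults.  Unknown keys are rejected by name.
"""

from __future__ import annotations

import ast
import tomllib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

from .params import (
    AITParams,
    CoupledParams,
    EngineParams,
    NoiseParams,
    StepProfile,
    SwitchParams,
)

MODEL_SECTION = {"ait": "ait", "ait_seqa": "ait", "ld": "ld",
                 "lddr": "lddr", "coupled": "coupled"}


class ConfigError(ValueError):
    pass


# engine keys accepted in [engine]; growth may be given either way
_ENGINE_ALIASES = {"growth_rate_per_h", "doubling_time_min"}
_ENGINE_KEYS = {
    "t_c", "t_d_period", "tau_b", "dt", "n_generations",
    "burn_in_generations", "seed", "v_init", "trace_interval",
} | _ENGINE_ALIASES

_PROFILE_SUFFIXES = ("_low", "_high", "_on", "_off")
_PROFILE_FIELDS = {"beta_data", "alpha_d2"}

_PARAM_CLASSES = {"ait": AITParams, "ld": SwitchParams, "lddr": SwitchParams,
                  "coupled": CoupledParams}


@dataclass
class RunConfig:
    """Fully resolved configuration of one run."""

    model: str = "ait"
    engine: EngineParams = field(default_factory=EngineParams)
    model_params: object = field(default_factory=AITParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    outdir: str = "replisim_out"

    def to_dict(self) -> dict:
        def enc(obj):
            d = {}
            for k, v in asdict(obj).items():
                d[k] = v
            return d

        return {
            "model": self.model,
            "engine": enc(self.engine),
            "model_params": enc(self.model_params),
            "noise": enc(self.noise),
            "outdir": self.outdir,
        }


def _parse_value(text: str):
    try:
        return ast.literal_eval(text)
    except (ValueError, SyntaxError):
        return text


def _build_engine(section: dict) -> EngineParams:
    section = dict(section)
    unknown = set(section) - _ENGINE_KEYS
    if unknown:
        raise ConfigError(f"unknown [engine] key(s): {sorted(unknown)}")
    if "growth_rate_per_h" in section and "doubling_time_min" in section:
        raise ConfigError(
            "give either growth_rate_per_h or doubling_time_min, not both"
        )
    kw = {k: v for k, v in section.items() if k not in _ENGINE_ALIASES}
    if "doubling_time_min" in section:
        return EngineParams.from_doubling_time(section["doubling_time_min"], **kw)
    lam_h = section.get("growth_rate_per_h")
    if lam_h is not None:
        return EngineParams.from_growth_rate_per_h(lam_h, **kw)
    return EngineParams(**kw)


def _build_model_params(model: str, section: dict):
    cls = _PARAM_CLASSES[MODEL_SECTION[model]]
    valid = {f.name for f in fields(cls)}
    profile_fields = {f.name for f in fields(cls)
                      if f.name in _PROFILE_FIELDS}
    kw: dict = {}
    profiles: dict[str, dict] = {}
    for key, value in section.items():
        base = None
        for suf in _PROFILE_SUFFIXES:
            if key.endswith(suf) and key[: -len(suf)] in profile_fields:
                base = key[: -len(suf)]
                profiles.setdefault(base, {})[suf[1:]] = value
                break
        if base is not None:
            continue
        if key not in valid:
            raise ConfigError(f"unknown key {key!r} for model {model!r}")
        kw[key] = value
    defaults = cls() if model != "ld" else SwitchParams.ld()
    for base, parts in profiles.items():
        current: StepProfile = getattr(defaults, base)
        kw[base] = StepProfile(
            low=parts.get("low", current.low),
            high=parts.get("high", current.high),
            on=parts.get("on", current.on),
            off=parts.get("off", current.off),
        )
    if model == "ld":
        return SwitchParams.ld(**kw)
    if model == "ait":
        kw.setdefault("seqa_mode", "origin_block_only")
    elif model == "ait_seqa":
        kw["seqa_mode"] = "synthesis_block"
    try:
        return cls(**kw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(
    path: str | Path | None = None,
    overrides: dict | list | tuple = (),
    model: str | None = None,
) -> RunConfig:
    """Resolve a RunConfig from file, overrides and defaults.

    ``overrides`` is a mapping or a list of ``"section.key=value"``
    strings (CLI form); override values win over file values.
    """
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)

    if isinstance(overrides, dict):
        items = list(overrides.items())
    else:
        items = []
        for entry in overrides:
            if "=" not in entry:
                raise ConfigError(f"override {entry!r} is not of form section.key=value")
            key, _, value = entry.partition("=")
            items.append((key.strip(), _parse_value(value.strip())))
    for dotted, value in items:
        if dotted in ("model", "outdir"):
            data[dotted] = value
            continue
        if "." not in dotted:
            raise ConfigError(f"override key {dotted!r} must be section.key")
        section, _, key = dotted.partition(".")
        data.setdefault(section, {})[key] = value

    model = model or data.pop("model", None) or "ait"
    if model not in MODEL_SECTION:
        raise ConfigError(
            f"unknown model {model!r}; expected one of {sorted(MODEL_SECTION)}"
        )
    outdir = data.pop("outdir", "replisim_out")

    known_sections = {"engine", "noise"} | set(MODEL_SECTION.values())
    unknown = set(data) - known_sections
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    for section in set(MODEL_SECTION.values()) - {MODEL_SECTION[model]}:
        if section in data and section != MODEL_SECTION[model]:
            data.pop(section)  # sections for other models are ignored

    engine = _build_engine(data.get("engine", {}))
    model_params = _build_model_params(model, data.get(MODEL_SECTION[model], {}))
    noise_section = dict(data.get("noise", {}))
    valid_noise = {f.name for f in fields(NoiseParams)}
    bad = set(noise_section) - valid_noise
    if bad:
        raise ConfigError(f"unknown [noise] key(s): {sorted(bad)}")
    noise = NoiseParams(**noise_section)
    return RunConfig(model=model, engine=engine, model_params=model_params,
                     noise=noise, outdir=outdir)
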