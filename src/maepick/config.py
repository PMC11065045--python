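"""Run configuration: YAML loading with strict key checking.

A run config nests one section per component (``sim``, ``mae``,
``train``, ``loss``, ``pick``) plus a global ``seed``.  Unknown or
misspelled keys are rejected with the full key path; every CLI run
writes a fully-resolved snapshot next to its outputs so any artifact can
be regenerated from snapshot + seed alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .losses import LossConfig
from .mae import MaeConfig
from .pick import PickConfig
from .simulate import SimParams
from .train import TrainPlan

_SECTIONS = {
    "sim": SimParams,
    "mae": MaeConfig,
    "train": TrainPlan,
    "loss": LossConfig,
    "pick": PickConfig,
}


@dataclass
class RunConfig:
    sim: SimParams = field(default_factory=SimParams)
    mae: MaeConfig = field(default_factory=MaeConfig)
    train: TrainPlan = field(default_factory=TrainPlan)
    loss: LossConfig = field(default_factory=LossConfig)
    pick: PickConfig = field(default_factory=PickConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed),
                       sim=replace(self.sim, seed=int(seed)),
                       train=replace(self.train, seed=int(seed)))


def _build_section(cls, data: dict, path: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config section '{path}' must be a mapping")
    valid = {f.name for f in fields(cls)}
    for key in data:
        if key not in valid:
            raise ValueError(f"unknown config key '{path}.{key}' "
                             f"(valid keys: {sorted(valid)})")
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        try:
            if f.type in ("int", int):
                val = int(val)
            elif f.type in ("float", float):
                val = float(val)
        except (TypeError, ValueError):
            raise ValueError(f"config key '{path}.{f.name}' has invalid value {val!r}")
        if isinstance(val, list):
            val = tuple(val)
        coerced[f.name] = val
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section '{path}': {exc}") from None


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config merged over the documented defaults.

    An empty (or absent) file yields all defaults; unknown keys raise a
    configuration error naming the offending key path.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data = loaded
    if overrides:
        for k, v in overrides.items():
            data.setdefault(k, {})
            if isinstance(v, dict):
                data[k] = {**data[k], **v}
            else:
                data[k] = v
    kwargs = {}
    for key, val in data.items():
        if key == "seed":
            kwargs["seed"] = int(val)
        elif key in _SECTIONS:
            kwargs[key] = _build_section(_SECTIONS[key], val, key)
        else:
            raise ValueError(f"unknown config key '{key}' "
                             f"(valid top-level keys: {sorted(_SECTIONS) + ['seed']})")
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write a fully-resolved config snapshot as YAML."""
    path = Path(path)

    def _plain(x):
        if isinstance(x, dict):
            return {k: _plain(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [_plain(v) for v in x]
        return x

    path.write_text(yaml.safe_dump(_plain(asdict(cfg)), sort_keys=False))
    return path
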