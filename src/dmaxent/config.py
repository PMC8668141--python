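"""Declarative run configuration (YAML/JSON) shared by the CLI subcommands."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import ModelSpec, ValidityError
from .protocols import DriveProtocol

__all__ = ["RunConfig", "load_config", "dump_config", "build_model",
           "build_protocol"]

_PROTOCOL_KINDS = ("constant", "step", "square_wave", "smooth_periodic")

_DEFAULTS = dict(
    sigma0=0.1,
    horizon=40.0,
    n_out=81,
    dt=0.01,
    n_traj=3000,
    seed=0,
    fpe_cells=400,
    rtol=1e-8,
    atol=1e-10,
    snapshot_times=[],
    methods=["dme", "fpe"],
    outdir="out",
    ramp_fraction=0.5,
)

_KNOWN_KEYS = {"model", "protocol", "initial"} | set(_DEFAULTS)
_KNOWN_PROTOCOL_KEYS = {"kind", "levels", "switch_time", "period",
                        "ramp_fraction"}


@dataclass
class RunConfig:
    """Validated, fully-resolved run configuration.

    Force levels are in each model's natural parameterization: (mu, beta)
    for the OU model, (r, lambda, m) for the island model.
    """

    model: str
    protocol_kind: str
    levels: list
    initial: list
    switch_time: float = 0.0
    period: float | None = None
    ramp_fraction: float = 0.5
    sigma0: float = 0.1
    horizon: float = 40.0
    n_out: int = 81
    dt: float = 0.01
    n_traj: int = 3000
    seed: int = 0
    fpe_cells: int = 400
    rtol: float = 1e-8
    atol: float = 1e-10
    snapshot_times: list = field(default_factory=list)
    methods: list = field(default_factory=lambda: ["dme", "fpe"])
    outdir: str = "out"

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_raw(raw: dict) -> None:
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "model" not in raw:
        raise ValueError("config must set 'model' (ou | island)")
    if raw["model"] not in ("ou", "island"):
        raise ValueError(f"unknown model {raw['model']!r}")
    proto = raw.get("protocol")
    if not isinstance(proto, dict):
        raise ValueError("config must contain a 'protocol' mapping")
    unknown_p = sorted(set(proto) - _KNOWN_PROTOCOL_KEYS)
    if unknown_p:
        raise ValueError(f"unknown protocol keys: {unknown_p}")
    if proto.get("kind") not in _PROTOCOL_KINDS:
        raise ValueError(f"protocol kind must be one of {_PROTOCOL_KINDS}")
    levels = proto.get("levels")
    if not levels or not all(isinstance(l, (list, tuple)) for l in levels):
        raise ValueError("protocol.levels must be a list of force vectors")


def _validate_forces(model_name: str, levels, initial) -> None:
    d = 2 if model_name == "ou" else 3
    for vec in list(levels) + [initial]:
        if len(vec) != d:
            raise ValueError(
                f"{model_name} forces need {d} entries, got {list(vec)}")
        if model_name == "ou" and vec[1] <= 0:
            raise ValidityError(f"beta = {vec[1]} must be positive")
        if model_name == "island":
            r, lam, m = vec
            if lam <= 0:
                raise ValidityError(f"lambda = {lam} must be positive")
            if m <= 0.5:
                raise ValidityError(
                    f"m = {m} <= 1/2: DME requires strong migration (m > 1/2)")


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    _validate_raw(raw)
    proto = raw["protocol"]
    levels = [list(map(float, l)) for l in proto["levels"]]
    initial = list(map(float, raw.get("initial", levels[0])))
    _validate_forces(raw["model"], levels, initial)
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items()
                              if k not in ("protocol", "initial")}}
    return RunConfig(
        model=raw["model"],
        protocol_kind=proto["kind"],
        levels=levels,
        initial=initial,
        switch_time=float(proto.get("switch_time", 0.0)),
        period=(float(proto["period"]) if proto.get("period") is not None
                else None),
        ramp_fraction=float(proto.get("ramp_fraction",
                                      merged["ramp_fraction"])),
        sigma0=float(merged["sigma0"]),
        horizon=float(merged["horizon"]),
        n_out=int(merged["n_out"]),
        dt=float(merged["dt"]),
        n_traj=int(merged["n_traj"]),
        seed=int(merged["seed"]),
        fpe_cells=int(merged["fpe_cells"]),
        rtol=float(merged["rtol"]),
        atol=float(merged["atol"]),
        snapshot_times=list(merged["snapshot_times"]),
        methods=list(merged["methods"]),
        outdir=str(merged["outdir"]),
    )


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))


def build_model(cfg: RunConfig) -> ModelSpec:
    if cfg.model == "ou":
        from .ou import ou_model
        return ou_model(cfg.sigma0)
    from .island import island_model
    return island_model()


def _to_alpha(cfg: RunConfig, vec) -> np.ndarray:
    if cfg.model == "ou":
        from .ou import alpha_from_natural
        return alpha_from_natural(*vec)
    return np.asarray(vec, dtype=float)


def build_protocol(cfg: RunConfig) -> DriveProtocol:
    """Engine-coordinate protocol from the natural-parameter config."""
    levels = [_to_alpha(cfg, l) for l in cfg.levels]
    kind = cfg.protocol_kind
    if kind == "constant":
        return DriveProtocol.constant(levels[0])
    if kind == "step":
        if len(levels) < 2:
            raise ValueError("step protocol needs two levels")
        return DriveProtocol.step(levels[0], levels[1], cfg.switch_time)
    if cfg.period is None:
        raise ValueError(f"{kind} protocol needs a period")
    if kind == "square_wave":
        n_periods = int(np.ceil(cfg.horizon / cfg.period)) + 1
        return DriveProtocol.square_wave(levels[0], levels[1], cfg.period,
                                         n_periods=n_periods)
    return DriveProtocol.smooth_periodic(levels[0], levels[1], cfg.period,
                                         cfg.ramp_fraction)


def initial_alpha(cfg: RunConfig) -> np.ndarray:
    return _to_alpha(cfg, cfg.initial)
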