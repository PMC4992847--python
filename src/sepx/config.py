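"""Run configuration: TOML/JSON parsing, validation and echoing.

A run is fully reproducible from its echoed configuration: every default is
made explicit in the echo, each model parameter is tagged with its
provenance (``fixture`` for built-in values, ``user`` for overrides), and
the package contains no randomness anywhere.

Schema (TOML shown; JSON mirrors it)::

    model = "pwl2d"

    [params]            # optional parameter overrides
    tau_w = 10.0

    [numerics]          # optional
    dt = 0.01
    t_end = 100.0

    [[protocol]]        # optional, repeated
    kind = "step"       # dc | step | ramp | impulse | clamp
    t0 = 0.0
    t1 = 5.0
    amp = 2.0

Unknown top-level keys, unknown model names, unknown parameters, malformed
protocol segments and non-positive dt are all rejected with specific
messages.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .dynamics import DEFAULT_DT, DEFAULT_T_END, Segment, StimulusProtocol
from .exceptions import ConfigError
from .models import MODEL_NAMES, NeuronModel, get_model

__all__ = ["RunConfig", "load_config"]

_TOP_KEYS = {"model", "params", "numerics", "protocol"}
_NUMERIC_KEYS = {"dt", "t_end", "settle"}
_SEGMENT_KEYS = {"kind", "t0", "t1", "amp", "i0", "i1", "q", "v_c", "width"}


@dataclass
class RunConfig:
    model_name: str
    overrides: dict = field(default_factory=dict)
    dt: float = DEFAULT_DT
    t_end: float = DEFAULT_T_END
    settle: float = 200.0
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol.none)

    def build_model(self) -> NeuronModel:
        return get_model(self.model_name, **self.overrides)

    def echo(self) -> dict:
        """Fully explicit configuration with per-parameter provenance."""
        model = self.build_model()
        params = {
            k: {
                "value": v,
                "provenance": "user" if k in self.overrides else "fixture",
            }
            for k, v in model.params().items()
        }
        return {
            "model": self.model_name,
            "params": params,
            "numerics": {"dt": self.dt, "t_end": self.t_end, "settle": self.settle},
            "protocol": [
                {k: getattr(s, k) for k in _SEGMENT_KEYS} for s in self.protocol.segments
            ],
        }


def _parse_file(path: Path) -> dict:
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    if path.suffix.lower() == ".toml":
        return tomllib.loads(text.decode())
    # sniff: JSON objects start with '{'
    stripped = text.decode().lstrip()
    if stripped.startswith("{"):
        return json.loads(stripped)
    return tomllib.loads(text.decode())


def load_config(path) -> RunConfig:
    """Load and validate a TOML or JSON run configuration."""
    path = Path(path)
    try:
        raw = _parse_file(path)
    except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a table/object")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(
            f"{path}: unknown top-level keys {sorted(unknown)}; "
            f"allowed: {sorted(_TOP_KEYS)}"
        )
    name = raw.get("model")
    if not isinstance(name, str) or name not in MODEL_NAMES:
        raise ConfigError(
            f"{path}: missing or unknown model {name!r}; "
            f"available: {', '.join(MODEL_NAMES)}"
        )
    overrides = dict(raw.get("params", {}))

    numerics = dict(raw.get("numerics", {}))
    bad = set(numerics) - _NUMERIC_KEYS
    if bad:
        raise ConfigError(f"{path}: unknown numerics keys {sorted(bad)}")
    dt = float(numerics.get("dt", DEFAULT_DT))
    if dt <= 0:
        raise ConfigError(f"{path}: dt must be positive, got {dt}")
    t_end = float(numerics.get("t_end", DEFAULT_T_END))
    settle = float(numerics.get("settle", 200.0))

    segments = []
    for i, seg in enumerate(raw.get("protocol", [])):
        if not isinstance(seg, dict):
            raise ConfigError(f"{path}: protocol[{i}] must be a table/object")
        bad = set(seg) - _SEGMENT_KEYS
        if bad:
            raise ConfigError(f"{path}: protocol[{i}] unknown keys {sorted(bad)}")
        if "kind" not in seg:
            raise ConfigError(f"{path}: protocol[{i}] missing 'kind'")
        try:
            segments.append(Segment(**seg))
        except (TypeError, ConfigError) as exc:
            raise ConfigError(f"{path}: protocol[{i}]: {exc}") from exc
    protocol = StimulusProtocol(segments)
    protocol.validate()

    cfg = RunConfig(
        model_name=name,
        overrides=overrides,
        dt=dt,
        t_end=t_end,
        settle=settle,
        protocol=protocol,
    )
    cfg.build_model()  # validates overrides and fixture invariants
    return cfg
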