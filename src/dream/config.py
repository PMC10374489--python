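"""Run configuration: defaults < config file < command-line flags.

Config files are flat key-value YAML (scalars only).  The resolved
configuration is echoed as comment lines into every output file, so any
result can be traced back to the exact parameters and seed that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class RunConfig:
    subcommand: str
    params: dict[str, Any] = field(default_factory=dict)
    version: str = ""

    def header_lines(self) -> list[str]:
        """Deterministic provenance lines for output-file headers."""
        items = " ".join(f"{k}={self.params[k]}" for k in sorted(self.params))
        return [f"dream v{self.version} subcommand={self.subcommand}", f"config: {items}"]


def _coerce(key: str, value: Any, default: Any) -> Any:
    """Check/convert a value against the type of its default."""
    if default is None or value is None:
        return value
    want = type(default)
    if want is bool:
        if isinstance(value, bool):
            return value
        raise TypeError(f"config key {key!r}: expected bool, got {value!r}")
    if want is float and isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if want is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise TypeError(f"config key {key!r}: expected int, got {value!r}")
        return value
    if want is str:
        if not isinstance(value, str):
            raise TypeError(f"config key {key!r}: expected str, got {value!r}")
        return value
    if not isinstance(value, want):
        raise TypeError(f"config key {key!r}: expected {want.__name__}, got {value!r}")
    return value


def read_config_file(path: str | Path) -> dict[str, Any]:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise TypeError("config file must be a flat key-value mapping")
    for k, v in data.items():
        if isinstance(v, (dict, list)):
            raise TypeError(f"config key {k!r}: nested values are not allowed")
    return dict(data)


def resolve_config(
    subcommand: str,
    defaults: Mapping[str, Any],
    file: str | Path | None = None,
    flags: Mapping[str, Any] | None = None,
    version: str = "",
) -> RunConfig:
    """Merge defaults, an optional config file and explicit flags (flags win).

    Keys absent from ``defaults`` are unknown and rejected; values are
    type-checked against the default's type.
    """
    params = dict(defaults)
    for source in (read_config_file(file) if file else {}, dict(flags or {})):
        for key, value in source.items():
            if key not in params:
                raise KeyError(f"unknown config key {key!r}")
            params[key] = _coerce(key, value, defaults[key])
    return RunConfig(subcommand=subcommand, params=params, version=version)
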