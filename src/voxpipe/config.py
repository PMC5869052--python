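"""INI configuration parsing with explicit defaults and strict keys.

A run is described by the sections ``[system]``, ``[network]``,
``[training]``, ``[inference]`` plus one section per data source (any other
section name).  Parsing fills in every documented default, applies CLI
overrides (``section.key=value``) on top of file values, and rejects
unknown keys outright — a misspelled key is an error, not a warning.  The
fully resolved configuration can be rendered back to INI text; that text is
embedded in every checkpoint so a run can be recreated from the checkpoint
alone.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Any, Mapping


class ConfigError(RuntimeError):
    pass


def _parse_bool(v: str) -> bool:
    if str(v).lower() in ("1", "true", "yes", "on"):
        return True
    if str(v).lower() in ("0", "false", "no", "off"):
        return False
    raise ConfigError(f"not a boolean: {v!r}")


def _parse_ints(v) -> tuple[int, ...]:
    if isinstance(v, (tuple, list)):
        return tuple(int(x) for x in v)
    return tuple(int(x) for x in str(v).replace(",", " ").split())


def _parse_floats(v) -> tuple[float, ...]:
    if isinstance(v, (tuple, list)):
        return tuple(float(x) for x in v)
    return tuple(float(x) for x in str(v).replace(",", " ").split())


# (default, converter); a default of REQUIRED marks a mandatory key
REQUIRED = object()

_SYSTEM = {
    "action": (REQUIRED, str),
    "model_dir": (REQUIRED, str),
    "seed": (42, int),
}
_NETWORK = {
    "name": ("segnet", str),
    "n_classes": (2, int),
    "depth": (2, int),
    "growth": (8, int),
    "blocks_per_level": (2, int),
    "skip_channels": (8, int),
}
_TRAINING = {
    "lr": (1e-3, float),
    "iterations": (100, int),
    "loss": ("dice", str),
    "batch_size": (1, int),
    "save_every": (100, int),
    "sampler": ("uniform", str),
    "spatial_window_size": ((16, 16, 16), _parse_ints),
    "normalization": ("meanvar", str),
    "augmentation": (False, _parse_bool),
    "rotation_range_deg": ((-10.0, 10.0), _parse_floats),
    "scaling_range_pct": ((90.0, 110.0), _parse_floats),
    "flip_axes": ((), _parse_ints),
    "starting_checkpoint": ("", str),
}
_INFERENCE = {
    "checkpoint": ("", str),
    "sampler": ("grid", str),
    "spatial_window_size": ((16, 16, 16), _parse_ints),
    "border": ((0, 0, 0), _parse_ints),
    "output_dir": ("", str),
    "output_kind": ("label", str),
    "save_probabilities": (False, _parse_bool),
    "normalization": ("meanvar", str),
    # linear_interpolation action
    "n_steps": (8, int),
    "noise_dim": (100, int),
    "conditioning_shape": ((), _parse_ints),  # () = no conditioning image
}
_DATA = {
    "path_to_search": ("", str),
    "filename_contains": ("", str),
    "csv_file": ("", str),
    "interp_order": (-1, int),  # -1: derive from section role
    "subjects": ("", str),      # optional whitespace-separated subject filter
}

_EVALUATION = {
    "metrics": ("", str),        # whitespace-separated; "" = default set
    "labels": ("", str),         # "" = every nonzero label in the reference
    "distance_units": ("voxels", str),
    "seg_dir": ("", str),
}

_SCHEMAS: dict[str, dict] = {
    "system": _SYSTEM,
    "network": _NETWORK,
    "training": _TRAINING,
    "inference": _INFERENCE,
    "evaluation": _EVALUATION,
}


@dataclass
class ConfigSpec:
    """A fully resolved run configuration."""

    system: dict[str, Any]
    network: dict[str, Any]
    training: dict[str, Any]
    inference: dict[str, Any]
    evaluation: dict[str, Any] = field(default_factory=dict)
    data: dict[str, dict[str, Any]] = field(default_factory=dict)

    @property
    def seed(self) -> int:
        return int(self.system["seed"])

    @property
    def model_dir(self) -> Path:
        return Path(self.system["model_dir"])

    def resolved_text(self) -> str:
        """Render the configuration, including every default, as INI text."""
        cp = configparser.ConfigParser()
        for name, values in [
            ("system", self.system), ("network", self.network),
            ("training", self.training), ("inference", self.inference),
            ("evaluation", self.evaluation),
        ] + [(k, v) for k, v in self.data.items()]:
            cp[name] = {
                k: " ".join(str(x) for x in v) if isinstance(v, (tuple, list))
                else str(v)
                for k, v in values.items()
            }
        out = StringIO()
        cp.write(out)
        return out.getvalue()


def _resolve_section(name: str, schema: dict, raw: Mapping[str, str]) -> dict[str, Any]:
    unknown = set(raw) - set(schema)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
    out: dict[str, Any] = {}
    for key, (default, conv) in schema.items():
        if key in raw:
            try:
                out[key] = conv(raw[key])
            except ConfigError:
                raise
            except Exception as exc:
                raise ConfigError(f"bad value for [{name}] {key}: {raw[key]!r} ({exc})") from exc
        elif default is REQUIRED:
            raise ConfigError(f"missing mandatory key [{name}] {key}")
        else:
            out[key] = default
    return out


def parse_config(
    path: str | Path | None = None,
    cli_overrides: Mapping[str, str] | None = None,
    text: str | None = None,
) -> ConfigSpec:
    """Parse an INI file (or raw text), fill defaults, apply overrides.

    ``cli_overrides`` keys are ``"section.key"``; overrides win over file
    values.  Every data section must name a source (``path_to_search`` with
    ``filename_contains``, or ``csv_file``).
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keep key case
    if text is not None:
        cp.read_string(text)
    elif path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        cp.read(path, encoding="utf-8")
    else:
        raise ConfigError("either a path or config text is required")

    raw: dict[str, dict[str, str]] = {s: dict(cp[s]) for s in cp.sections()}
    for override, value in (cli_overrides or {}).items():
        if "." not in override:
            raise ConfigError(f"override {override!r} must look like section.key")
        section, key = override.split(".", 1)
        raw.setdefault(section, {})[key] = str(value)

    if "system" not in raw:
        raise ConfigError("missing mandatory section [system]")
    resolved: dict[str, dict[str, Any]] = {}
    data: dict[str, dict[str, Any]] = {}
    for section, values in raw.items():
        if section in _SCHEMAS:
            resolved[section] = _resolve_section(section, _SCHEMAS[section], values)
        else:
            entry = _resolve_section(section, _DATA, values)
            if not entry["csv_file"] and not (
                entry["path_to_search"] and entry["filename_contains"]
            ):
                raise ConfigError(
                    f"data section [{section}] needs csv_file or "
                    f"path_to_search + filename_contains"
                )
            data[section] = entry
    for section in ("network", "training", "inference", "evaluation"):
        resolved.setdefault(
            section, _resolve_section(section, _SCHEMAS[section], {})
        )
    action = resolved["system"]["action"]
    if action in ("train", "inference", "evaluation") and not data:
        raise ConfigError(f"action {action!r} requires at least one data section")
    return ConfigSpec(
        system=resolved["system"],
        network=resolved["network"],
        training=resolved["training"],
        inference=resolved["inference"],
        evaluation=resolved["evaluation"],
        data=data,
    )
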