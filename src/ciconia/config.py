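"""Flat key=value run configuration.

One file configures a whole run; every analysis threshold defaults to the
study's published value and is overridable by a dotted key, e.g.::

    sim.n_individuals_per_group=6
    sim.group.delayed.mean_climb_rate=1.4
    seg.smooth_window_s=15
    mig.propensity_min_km=200

The resolved configuration is serialised into the output directory so a
run is reproducible from its artefacts alone.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import fields, is_dataclass

from .pipeline import RunConfig


def parse_config_file(path) -> dict[str, str]:
    """Parse ``key=value`` lines; '#' starts a comment; blanks ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def _coerce(current, raw: str):
    if isinstance(current, bool):
        if raw.lower() in ("1", "true", "yes"):
            return True
        if raw.lower() in ("0", "false", "no"):
            return False
        raise ValueError(f"expected boolean, got {raw!r}")
    if isinstance(current, int) and not isinstance(current, bool):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    if isinstance(current, dt.date):
        return dt.date.fromisoformat(raw)
    if isinstance(current, tuple):
        return tuple(float(x) for x in raw.split(","))
    return raw


def apply_overrides(config: RunConfig, overrides: dict[str, str]) -> RunConfig:
    """Apply dotted-key overrides in place (and return the config)."""
    for key, raw in overrides.items():
        parts = key.split(".")
        obj = config
        # group params live under sim.group.<label>.<field>
        if len(parts) >= 4 and parts[0] == "sim" and parts[1] == "group":
            label = parts[2]
            try:
                obj = config.sim.group_params[label]
            except KeyError:
                raise ValueError(f"unknown group label in config key: {key}") from None
            parts = parts[3:]
        while len(parts) > 1:
            if not hasattr(obj, parts[0]):
                raise ValueError(f"unknown config key: {key}")
            obj = getattr(obj, parts[0])
            parts = parts[1:]
        attr = parts[0]
        if not is_dataclass(obj) or attr not in {f.name for f in fields(obj)}:
            raise ValueError(f"unknown config key: {key}")
        setattr(obj, attr, _coerce(getattr(obj, attr), raw))
    return config


def dump_config(config: RunConfig, path) -> None:
    """Serialise the resolved configuration as flat key=value lines."""
    lines = [
        f"seed={config.seed}",
        f"out_dir={config.out_dir}",
        f"gap_threshold_s={config.gap_threshold_s}",
    ]
    for f in fields(config.sim):
        if f.name == "group_params":
            continue
        lines.append(f"sim.{f.name}={_fmt(getattr(config.sim, f.name))}")
    for label, gp in config.sim.group_params.items():
        for f in fields(gp):
            lines.append(f"sim.group.{label}.{f.name}={_fmt(getattr(gp, f.name))}")
    for prefix, obj in (("seg", config.seg), ("mig", config.mig)):
        for f in fields(obj):
            lines.append(f"{prefix}.{f.name}={_fmt(getattr(obj, f.name))}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _fmt(v) -> str:
    if isinstance(v, tuple):
        return ",".join(str(x) for x in v)
    if isinstance(v, dt.date):
        return v.isoformat()
    return str(v)
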