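"""Flat key-value configuration files (diff-able provenance).

One ``key = value`` pair per line, ``#`` comments.  A minimal file names a
variant and a platelet count; everything else has documented defaults::

    variant = S.I
    n_nps = 8

Unknown keys are rejected with the list of valid keys, so typos never
silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from . import units
from .integrate import PRESETS, RunConfig
from .topology import VARIANTS, SystemSpec, spec_for_variant

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}

#: key -> (type, default, description)
SCHEMA: dict[str, tuple] = {
    "variant": (str, None, "system variant, one of " + "/".join(VARIANTS)),
    "n_nps": (int, None, "number of platelets (0-16)"),
    "n_beads": (int, None, "chain length Nb (variant default if omitted)"),
    "bead_charge": (float, None, "per-bead charge Zb in e"),
    "k_theta": (float, None, "chain angular force constant, kBT/rad^2"),
    "rim_on": (bool, True, "keep the +6 rim charge on the platelets"),
    "box_nm": (float, 100.0, "cubic box edge, nm"),
    "n_shells": (int, 5, "platelet lattice shells (5 = 91 sites)"),
    "temperature_K": (float, units.DEFAULT_TEMPERATURE, "thermostat target, K"),
    "dielectric": (float, units.DEFAULT_DIELECTRIC, "relative permittivity"),
    "seed": (int, 0, "RNG seed for placement, velocities, thermostat"),
    "timestep_fs": (float, 10.0, "integration timestep, fs"),
    "n_steps": (int, 100_000, "number of MD steps"),
    "output_stride": (int, 1000, "steps between recorded frames"),
    "thermostat_tau_ps": (float, 0.1, "v-rescale coupling time, ps (<=0: NVE)"),
    "method": (str, "bruteforce_minimum_image", "electrostatics route"),
    "preset": (str, None, "size preset: desk or full (overrides box/steps)"),
}
REQUIRED = ("variant", "n_nps")


class ConfigError(ValueError):
    pass


def _parse_value(key: str, raw: str):
    typ = SCHEMA[key][0]
    try:
        if typ is bool:
            return _BOOL[raw.strip().lower()]
        return typ(raw.strip())
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"key {key!r}: cannot parse {raw.strip()!r} as {typ.__name__}") from exc


def parse_text(text: str) -> dict:
    """Parse config text into a validated key-value dict."""
    values: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in SCHEMA:
            raise ConfigError(
                f"line {lineno}: unknown key {key!r}; valid keys: {', '.join(sorted(SCHEMA))}"
            )
        values[key] = _parse_value(key, raw)
    missing = [k for k in REQUIRED if k not in values]
    if missing:
        raise ConfigError(
            f"missing required keys: {', '.join(missing)}; "
            f"valid keys: {', '.join(sorted(SCHEMA))}"
        )
    return values


def read_config(path: Union[str, Path]) -> tuple[SystemSpec, RunConfig, dict]:
    """Read a config file into (SystemSpec, RunConfig, raw values)."""
    text = Path(path).read_text()
    values = parse_text(text)
    return resolve(values)


def resolve(values: dict) -> tuple[SystemSpec, RunConfig, dict]:
    """Turn a validated key-value dict into spec and run config."""
    v = {k: values.get(k, SCHEMA[k][1]) for k in SCHEMA}
    preset = v["preset"]
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        p = PRESETS[preset]
        if "box_nm" not in values:
            v["box_nm"] = p["box_length"]
        if "n_steps" not in values:
            v["n_steps"] = p["n_steps"]
        if "output_stride" not in values:
            v["output_stride"] = p["output_stride"]
    try:
        spec = spec_for_variant(
            v["variant"],
            n_nps=v["n_nps"],
            n_beads=v["n_beads"],
            bead_charge=v["bead_charge"],
            k_theta=v["k_theta"],
            box_length=v["box_nm"],
            n_shells=v["n_shells"],
            rim_on=v["rim_on"],
            temperature=v["temperature_K"],
            dielectric=v["dielectric"],
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    tau = v["thermostat_tau_ps"]
    run = RunConfig(
        n_steps=v["n_steps"],
        timestep_fs=v["timestep_fs"],
        temperature=v["temperature_K"],
        thermostat_coupling_ps=None if tau is not None and tau <= 0 else tau,
        seed=v["seed"],
        output_stride=v["output_stride"],
    )
    return spec, run, v


def write_config(values: dict, path: Union[str, Path]) -> None:
    """Write a key-value dict back to a config file (round-trip safe)."""
    lines = []
    for key in SCHEMA:
        if key in values and values[key] is not None:
            val = values[key]
            if isinstance(val, bool):
                val = "true" if val else "false"
            lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")
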