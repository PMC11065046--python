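"""TOML run configuration: schema, validation, defaults, and round-tripping.

Units convention throughout the package and all outputs: lengths in Angstrom,
times in ns, rates in 1/ns (the experiment *schedule* alone is in seconds).
A config file only needs the keys that differ from the defaults; unknown
sections or keys are rejected by name.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .dynamics import PendulumParams, RotationParams, SpringParams
from .experiment import BurstConfig
from .models import (
    ROTATION_SLOW,
    DyePairModel,
    calibrate_separation,
)
from .photophysics import PhotophysicsParams

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid, unknown, or inconsistent configuration key."""


def _positive(v):
    return v > 0


def _nonnegative(v):
    return v >= 0


def _fraction(v):
    return 0.0 <= v <= 1.0


# section -> key -> (python type, default, validator or None, description)
SCHEMA: dict[str, dict[str, tuple]] = {
    "linker": {
        "n_links": (int, 15, _positive, "number of C-C links"),
        "bond_length_A": (float, 1.54, _positive, "C-C bond length"),
        "bond_angle_deg": (float, 109.5, lambda v: 0 < v <= 180, "C-C-C angle"),
        "single_bond_spring": (float, 1010.0, _positive, "single-bond spring constant"),
    },
    "dynamics": {
        "model": (str, "pendulum", lambda v: v in ("isotropic", "anisotropic", "pendulum"), "translational dye model"),
        "kappa": (str, "dynamic", lambda v: v in ("static", "dynamic"), "orientation-factor mode"),
        "separation_A": (float, 0.0, _nonnegative, "attachment separation; 0 = calibrate so mean efficiency = 0.5"),
        "translational_step_ns": (float, 0.1, _positive, "pendulum Heun step"),
        "relaxation_horizon_ns": (float, 50.0, _positive, "between-event propagation cap"),
        "spring_rate_per_ns": (float, 0.2, _positive, "OU relaxation rate"),
        "spring_sd_A": (float, 4.7, _positive, "per-axis stationary sd (isotropic reference)"),
        "anisotropy_p": (float, 0.1, lambda v: 0 < v <= 1, "soft/stiff variance ratio 1/p"),
        "pendulum_k_r_per_ns": (float, 0.2, _positive, "radial spring rate"),
        "pendulum_k_theta_per_ns": (float, 0.02, _positive, "polar restoring rate"),
        "pendulum_r_eq_A": (float, 18.0, _positive, "equilibrium arm length"),
        "pendulum_sigma_r": (float, 0.6, _positive, "radial volatility A/sqrt(ns)"),
        "pendulum_sigma_theta": (float, 0.6, _positive, "polar volatility A/sqrt(ns)"),
        "pendulum_sigma_phi": (float, 16.0, _positive, "azimuthal volatility A/sqrt(ns)"),
        "pendulum_c_r": (float, 1.0, _positive, "1/r radial drift coefficient A^2/ns"),
    },
    "donor": {
        "rotational_diffusion_rad2_per_ns": (float, ROTATION_SLOW.diffusion, _positive, "dipole rotational diffusion"),
    },
    "acceptor": {
        "rotational_diffusion_rad2_per_ns": (float, ROTATION_SLOW.diffusion, _positive, "dipole rotational diffusion"),
    },
    "photophysics": {
        "k_D_per_ns": (float, 0.25, _positive, "donor de-excitation rate"),
        "k_A_per_ns": (float, 0.5, _positive, "acceptor fluorescence rate"),
        "R0_ref_A": (float, 40.0, _positive, "reference Forster radius (kappa^2 = 2/3)"),
    },
    "experiment": {
        "burst_duration_ns": (float, 1.0e6, _positive, "burst length"),
        "excitation_period_ns": (float, 50.0, _positive, "laser pulse period"),
        "detection_efficiency": (float, 0.005, _fraction, "per-channel detection probability"),
        "bursts_per_second": (float, 1.0, _positive, "burst schedule rate"),
        "total_duration_s": (float, 7.0 * 3600.0, _positive, "experiment length"),
        "min_photons": (int, 10, _nonnegative, "burst exclusion threshold"),
    },
    "analysis": {
        "shift_variant": (str, "printed", lambda v: v in ("printed", "perpendicular"), "dynamic-shift denominator"),
    },
    "run": {
        "master_seed": (int, 0, None, "seed for all named RNG streams"),
    },
}


@dataclass
class RunConfig:
    """Validated configuration; ``sections[section][key]`` holds all values."""

    sections: dict[str, dict[str, object]] = field(default_factory=dict)

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    @property
    def master_seed(self) -> int:
        return self.sections["run"]["master_seed"]

    # -- builders ---------------------------------------------------------

    def photophysics(self) -> PhotophysicsParams:
        p = self.sections["photophysics"]
        return PhotophysicsParams.from_forster_radius(
            p["R0_ref_A"], donor_decay=p["k_D_per_ns"],
            acceptor_decay=p["k_A_per_ns"])

    def burst_config(self) -> BurstConfig:
        e = self.sections["experiment"]
        return BurstConfig(
            burst_duration=e["burst_duration_ns"],
            excitation_period=e["excitation_period_ns"],
            detection_efficiency=e["detection_efficiency"],
            bursts_per_second=e["bursts_per_second"],
            total_duration=e["total_duration_s"],
            min_photons=e["min_photons"],
        )

    def model(self) -> DyePairModel:
        d = self.sections["dynamics"]
        rot_d = RotationParams(
            diffusion=self.sections["donor"]["rotational_diffusion_rad2_per_ns"])
        rot_a = RotationParams(
            diffusion=self.sections["acceptor"]["rotational_diffusion_rad2_per_ns"])
        common = dict(kappa_mode=d["kappa"], donor_rotation=rot_d,
                      acceptor_rotation=rot_a,
                      translational_step=d["translational_step_ns"],
                      relaxation_horizon=d["relaxation_horizon_ns"])
        if d["model"] == "pendulum":
            pend = PendulumParams(
                radial_spring=d["pendulum_k_r_per_ns"],
                polar_spring=d["pendulum_k_theta_per_ns"],
                equilibrium_radius=d["pendulum_r_eq_A"],
                sigma_r=d["pendulum_sigma_r"],
                sigma_theta=d["pendulum_sigma_theta"],
                sigma_phi=d["pendulum_sigma_phi"],
                radial_correction_coefficient=d["pendulum_c_r"],
            )
            model = DyePairModel(kind="pendulum", donor_pendulum=pend,
                                 acceptor_pendulum=pend, separation=50.0,
                                 **common)
        elif d["model"] == "isotropic":
            spring = SpringParams.from_stationary_sd(
                d["spring_sd_A"], d["spring_rate_per_ns"])
            model = DyePairModel(kind="isotropic", donor_spring=spring,
                                 acceptor_spring=spring, separation=50.0,
                                 **common)
        else:
            spring = SpringParams.anisotropic_equal_volume(
                d["spring_sd_A"], d["anisotropy_p"], d["spring_rate_per_ns"],
                stiff_axis=2)
            model = DyePairModel(kind="anisotropic", donor_spring=spring,
                                 acceptor_spring=spring, separation=50.0,
                                 **common)
        sep = d["separation_A"]
        if sep == 0.0:
            sep = calibrate_separation(
                model, self.sections["photophysics"]["R0_ref_A"])
        return model.with_separation(sep)


def _validate(section: str, key: str, value):
    if section not in SCHEMA:
        raise ConfigError(f"unknown config section [{section}]")
    if key not in SCHEMA[section]:
        raise ConfigError(f"unknown key [{section}].{key}")
    typ, _default, check, _desc = SCHEMA[section][key]
    if typ is float and isinstance(value, int) and not isinstance(value, bool):
        value = float(value)
    if not isinstance(value, typ) or isinstance(value, bool):
        raise ConfigError(f"[{section}].{key} must be {typ.__name__}, got {value!r}")
    if check is not None and not check(value):
        raise ConfigError(f"[{section}].{key} = {value!r} violates its constraint")
    return value


def load_config(path: str | Path | None = None, *,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a TOML config; missing keys take their defaults.

    ``overrides`` is a {section: {key: value}} mapping applied after the
    file (used by the CLI for command-line flags).
    """
    raw: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            raw = tomllib.loads(path.read_text())
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"TOML parse error in {path}: {exc}") from exc
    sections = {
        sec: {key: spec[1] for key, spec in keys.items()}
        for sec, keys in SCHEMA.items()
    }
    explicit: set[tuple[str, str]] = set()
    for source in (raw, overrides or {}):
        for sec, keys in source.items():
            if not isinstance(keys, dict):
                raise ConfigError(f"top-level key {sec!r} is not a section")
            for key, value in keys.items():
                sections.setdefault(sec, {})
                sections[sec][key] = _validate(sec, key, value)
                explicit.add((sec, key))
    defaulted = [f"[{sec}].{key}" for sec in SCHEMA for key in SCHEMA[sec]
                 if (sec, key) not in explicit]
    if defaulted:
        logging.getLogger("fretshift").debug(
            "config keys at default values: %s", ", ".join(defaulted))
    return RunConfig(sections=sections)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the full (defaults included) config; load(save(c)) == c."""
    lines = ["# fretshift run configuration",
             "# units: lengths A, times ns, rates 1/ns; schedule in s", ""]
    for sec in SCHEMA:
        lines.append(f"[{sec}]")
        for key in SCHEMA[sec]:
            lines.append(f"{key} = {_toml_value(config.sections[sec][key])}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
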