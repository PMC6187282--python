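"""Structured-text (YAML) run configuration with unit-suffixed keys.

Example::

    geometry:
      width_um: 100
      height_um: 50
      start_radius_mm: 3.0
      spacing_um: 200
      turns: 5
    fluid:
      density_kg_m3: 1000
      viscosity_pa_s: 1.0e-3
    particle:
      diameter_um: 7.2
      density_kg_m3: 1000
    flow:
      rate_ml_h: 0.6
    ensemble:
      n_particles: 100
      seed: 1
      half_channel: false
    stepping:
      dt_s: 1.0e-4

Keys carry their unit as a suffix; values are converted to SI on read.
"""
from __future__ import annotations

from dataclasses import dataclass

import yaml

from .dynamics import StepConfig
from .ensemble import EnsembleConfig
from .geometry import ChannelSpec, FluidProps, ParticleSpec, make_channel

__all__ = ["RunConfig", "load_config", "ConfigError"]

_LENGTH = {"_m": 1.0, "_mm": 1e-3, "_um": 1e-6}
_FLOW = {"_m3_s": 1.0, "_ml_h": 1e-6 / 3600.0, "_ul_min": 1e-9 / 60.0}


class ConfigError(ValueError):
    pass


def _length(block: dict, stem: str) -> float:
    for suffix, factor in _LENGTH.items():
        if stem + suffix in block:
            return float(block[stem + suffix]) * factor
    raise ConfigError(f"missing length key {stem}_<m|mm|um>")


@dataclass(frozen=True)
class RunConfig:
    channel: ChannelSpec
    fluid: FluidProps
    particle: ParticleSpec
    Q: float
    ensemble: EnsembleConfig | None


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        geo = raw["geometry"]
        channel = make_channel(
            _length(geo, "width"),
            _length(geo, "height"),
            _length(geo, "start_radius"),
            _length(geo, "spacing"),
            int(geo["turns"]),
        )
        flu = raw.get("fluid", {})
        fluid = FluidProps(
            density=float(flu.get("density_kg_m3", 1000.0)),
            viscosity=float(flu.get("viscosity_pa_s", 1.0e-3)),
        )
        par = raw.get("particle", {})
        if "diameter_um" in par:
            radius = float(par["diameter_um"]) * 1e-6 / 2
        elif "radius_um" in par:
            radius = float(par["radius_um"]) * 1e-6
        else:
            raise ConfigError("particle needs diameter_um or radius_um")
        particle = ParticleSpec(
            radius=radius, density=float(par.get("density_kg_m3", fluid.density))
        )
        flow = raw["flow"]
        Q = None
        for suffix, factor in _FLOW.items():
            if "rate" + suffix in flow:
                Q = float(flow["rate" + suffix]) * factor
                break
        if Q is None:
            raise ConfigError("flow needs rate_<ml_h|m3_s|ul_min>")
        ens_cfg = None
        if "ensemble" in raw:
            ens = raw["ensemble"]
            stepping = raw.get("stepping", {})
            dt = float(stepping.get("dt_s", 1e-4 if Q < 1e-8 else 1e-5))
            ens_cfg = EnsembleConfig(
                channel=channel,
                fluid=fluid,
                particle=particle,
                Q=Q,
                n_particles=int(ens.get("n_particles", 100)),
                seed=int(ens.get("seed", 0)),
                step=StepConfig(dt=dt),
                half_channel=bool(ens.get("half_channel", False)),
            )
    except KeyError as exc:
        raise ConfigError(f"missing configuration block {exc}") from exc
    return RunConfig(channel=channel, fluid=fluid, particle=particle, Q=Q, ensemble=ens_cfg)
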