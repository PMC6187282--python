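"""Bundled study scenarios.

Two spiral channels are studied:

* the verification spiral — rectangular 100 x 50 um cross-section (aspect
  ratio 2.0), inlet centerline radius 3.0 mm, 200 um turn gap, five turns;
  particle sizes 1.9 and 7.2 um at flow rates 0.3-3.0 mL/h (channel Re
  1.67-16.67);
* the shallow spiral — 600 x 70 um (aspect ratio ~8.6, "9.0"), 3.0 mm
  start radius, 400 um gap, five turns; 2, 10 and 20 um particles at
  40-120 mL/h (channel Re ~50-150).

Scenario ensembles use the superposed plane-Poiseuille lift model; the
default time steps are 1e-4 s for the slow verification channel and 1e-5 s
for the fast shallow channel.
"""
from __future__ import annotations

from dataclasses import dataclass

from .dynamics import StepConfig
from .ensemble import EnsembleConfig, EnsembleResult, run_ensemble
from .flowfield import FieldBank
from .geometry import WATER, ChannelSpec, FluidProps, ParticleSpec, make_channel
from .lift import SuperposedLift

__all__ = [
    "ML_PER_H",
    "verification_channel",
    "shallow_channel",
    "Scenario",
    "VERIFICATION",
    "SHALLOW",
    "build_ensemble_config",
    "run_scenario",
]

#: 1 mL/h in m^3/s.
ML_PER_H = 1e-6 / 3600.0


def verification_channel() -> ChannelSpec:
    """The aspect-ratio-2.0 verification spiral."""
    return make_channel(100e-6, 50e-6, 3.0e-3, 200e-6, 5)


def shallow_channel() -> ChannelSpec:
    """The shallow aspect-ratio-9.0 spiral."""
    return make_channel(600e-6, 70e-6, 3.0e-3, 400e-6, 5)


@dataclass(frozen=True)
class Scenario:
    name: str
    channel: ChannelSpec
    fluid: FluidProps
    particle_diameters: tuple[float, ...]
    flow_rates: tuple[float, ...]  # m^3/s
    dt: float


VERIFICATION = Scenario(
    name="verification_ar2",
    channel=verification_channel(),
    fluid=WATER,
    particle_diameters=(1.9e-6, 7.2e-6),
    flow_rates=tuple(q * ML_PER_H for q in (0.3, 0.6, 1.2, 3.0)),
    dt=1e-4,
)

SHALLOW = Scenario(
    name="shallow_ar9",
    channel=shallow_channel(),
    fluid=WATER,
    particle_diameters=(2.0e-6, 10e-6, 20e-6),
    flow_rates=tuple(q * ML_PER_H for q in (40.0, 60.0, 80.0, 100.0, 120.0)),
    dt=1e-5,
)


def build_ensemble_config(
    scenario: Scenario,
    diameter: float,
    Q: float,
    n_particles: int = 100,
    seed: int = 0,
    half_channel: bool = False,
    particle_density: float | None = None,
    **kwargs,
) -> EnsembleConfig:
    rho_p = scenario.fluid.density if particle_density is None else particle_density
    return EnsembleConfig(
        channel=scenario.channel,
        fluid=scenario.fluid,
        particle=ParticleSpec(radius=diameter / 2, density=rho_p),
        Q=Q,
        n_particles=n_particles,
        seed=seed,
        step=StepConfig(dt=scenario.dt),
        half_channel=half_channel,
        **kwargs,
    )


def run_scenario(
    scenario: Scenario,
    diameter: float,
    Q: float,
    n_particles: int = 100,
    seed: int = 0,
    bank: FieldBank | None = None,
    **kwargs,
) -> EnsembleResult:
    """Convenience one-shot: build fields and lift, run the ensemble."""
    cfg = build_ensemble_config(scenario, diameter, Q, n_particles, seed, **kwargs)
    if bank is None:
        bank = FieldBank(scenario.channel, scenario.fluid, Q)
    lift = SuperposedLift(scenario.channel, scenario.fluid, Q, diameter / 2)
    return run_ensemble(cfg, bank, lift)
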