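"""Leap-frog dynamics with a canonical stochastic velocity-rescaling thermostat.

Positions live on integer steps, velocities on half steps.  Temperature is
controlled by the stochastic velocity-rescaling (canonical-sampling) scheme:
the kinetic energy is relaxed towards its canonical target over a coupling
time tau, with a noise term that makes the sampled ensemble exactly
canonical.  With the thermostat off (tau = None) the integrator is plain
NVE leap-frog, which is symplectic and time-reversible.

Internal units: nm, ps, kBT (at the force-field reference temperature) and
the derived mass unit.  Thermostat temperatures are given in kelvin and are
expressed relative to the force-field reference temperature, so annealing
stages heat the thermal motion while the interaction parameters stay fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import units
from .forcefield import ForceEvaluator, InteractionParams
from .state import SystemState
from .topology import SystemSpec, build_state
from .trajectory import Trajectory


@dataclass
class RunConfig:
    """Parameters of one dynamics run."""

    n_steps: int = 100_000
    timestep_fs: float = 10.0
    temperature: float = units.DEFAULT_TEMPERATURE  # K, thermostat target
    thermostat_coupling_ps: Optional[float] = 0.1  # None -> NVE
    mass: float = units.DEFAULT_MASS  # reduced units, all species
    seed: int = 0
    output_stride: int = 1000
    remove_com_motion: bool = True
    energy_bound: Optional[float] = None  # abort if |E_pot| exceeds (kBT)

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


#: Reduced-scale run presets.  "desk" is explicitly not the full study scale:
#: it shrinks the box and the step count so a workstation (or CI) run
#: finishes in minutes while keeping the same force field.
PRESETS: dict[str, dict] = {
    "desk": {"box_length": 30.0, "n_steps": 200_000, "output_stride": 500},
    "full": {"box_length": 100.0, "n_steps": 10_000_000, "output_stride": 10_000},
}


def maxwell_velocities(
    n: int, temperature: float, mass: float, rng: np.random.Generator,
    reference_temperature: float = units.DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Draw velocities from the Maxwell-Boltzmann distribution (nm/ps)."""
    t_red = temperature / reference_temperature  # kBT units of the force field
    return rng.normal(scale=math.sqrt(t_red / mass), size=(n, 3))


def leapfrog_step(
    positions: np.ndarray,
    half_velocities: np.ndarray,
    forces: np.ndarray,
    mass: Union[float, np.ndarray],
    dt: float,
    box_length: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One leap-frog update; returns (new positions, new half-step velocities).

    v(t+dt/2) = v(t-dt/2) + f(t)/m * dt ; x(t+dt) = x(t) + v(t+dt/2) * dt.
    Positions are wrapped into [0, L).
    """
    v_new = half_velocities + forces / mass * dt
    x_new = np.mod(positions + v_new * dt, box_length)
    return x_new, v_new


def vrescale_factor(
    kinetic: float,
    kinetic_target: float,
    ndof: int,
    dt_over_tau: float,
    rng: np.random.Generator,
) -> float:
    """Stochastic velocity-rescaling factor (canonical sampling).

    Exactly two random variates are drawn per call (one normal, one
    chi-squared with ndof-1 degrees of freedom), so the stream position is
    deterministic per step.  dt_over_tau <= 0 returns 1 (decoupled limit).
    """
    r1 = rng.normal()
    r2 = rng.chisquare(ndof - 1)
    if dt_over_tau <= 0.0 or kinetic <= 0.0:
        return 1.0
    c = math.exp(-dt_over_tau)
    ratio = kinetic_target / (ndof * kinetic)
    a2 = c + (1.0 - c) * ratio * (r1 * r1 + r2) + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ratio)
    return math.sqrt(max(a2, 0.0))


def _resolve_system(system, seed: int) -> SystemState:
    if isinstance(system, SystemSpec):
        return build_state(system, seed=seed)
    return system


def run_simulation(
    system: Union[SystemState, SystemSpec],
    config: Optional[RunConfig] = None,
    params: Optional[InteractionParams] = None,
    method: str = "bruteforce_minimum_image",
    evaluator: Optional[ForceEvaluator] = None,
) -> Trajectory:
    """Propagate the system and record frames every ``output_stride`` steps.

    The returned trajectory carries the final state (with half-step
    velocities) in its metadata under ``"final_state"``, so a run can be
    continued bit-identically by passing that state plus the same config.
    """
    config = config or RunConfig()
    params = params or InteractionParams()
    state = _resolve_system(system, config.seed).copy()
    n = state.n_particles
    rng = np.random.default_rng(config.seed)
    evaluator = evaluator or ForceEvaluator(state, params, method)

    mass = config.mass
    dt = config.timestep_fs * units.FEMTOSECOND
    t_red = config.temperature / params.temperature
    ndof = 3 * n - 3 if config.remove_com_motion else 3 * n
    kin_target = 0.5 * ndof * t_red
    tau = config.thermostat_coupling_ps
    dt_over_tau = 0.0 if tau is None else dt / tau

    pos = np.mod(state.positions, state.box_length)
    if state.velocities is None:
        vel = maxwell_velocities(n, config.temperature, mass, rng, params.temperature)
        vel -= vel.mean(axis=0)
    else:
        vel = state.velocities.copy()

    frames, times, elog = [], [], []

    def record(step: int, rep) -> None:
        kin = 0.5 * mass * float((vel**2).sum())
        frames.append(pos.copy())
        times.append(step * dt)
        elog.append(
            {
                "step": step,
                "time_ps": step * dt,
                **rep.as_dict(),
                "kinetic": kin,
                "temperature_K": 2.0 * kin / (ndof) * params.temperature,
            }
        )

    rep = evaluator(pos)
    record(0, rep)
    for step in range(1, config.n_steps + 1):
        pos, vel = leapfrog_step(pos, vel, rep.forces, mass, dt, state.box_length)
        rep = evaluator(pos)
        if tau is not None:
            kin = 0.5 * mass * float((vel**2).sum())
            vel *= vrescale_factor(kin, kin_target, ndof, dt_over_tau, rng)
        if step % config.output_stride == 0:
            if config.remove_com_motion:
                vel -= vel.mean(axis=0)
            if config.energy_bound is not None and abs(rep.total) > config.energy_bound:
                raise RuntimeError(
                    f"energy diverged at step {step}: E_pot = {rep.total:.3g} kBT "
                    f"(bound {config.energy_bound:.3g}); seed={config.seed}"
                )
            record(step, rep)

    final = state.copy()
    final.positions = pos.copy()
    final.velocities = vel.copy()
    final.masses = np.full(n, mass)
    traj = Trajectory(
        frames=np.stack(frames),
        times=np.array(times),
        box_length=state.box_length,
        species=state.species.copy(),
        charges=state.charges.copy(),
        diameters=state.diameters.copy(),
        molecule=state.molecule.copy(),
        energies=pd.DataFrame(elog),
        metadata={
            "config": config,
            "method": method,
            "seed": config.seed,
            "final_state": final,
            "system_metadata": dict(state.metadata),
        },
    )
    return traj


def anneal_fixture(
    system: Union[SystemState, SystemSpec],
    schedule: Sequence[tuple[float, int]],
    config: Optional[RunConfig] = None,
    params: Optional[InteractionParams] = None,
    method: str = "bruteforce_minimum_image",
) -> SystemState:
    """Simulated-annealing relaxation: run the schedule of (T_kelvin, steps).

    Produces a near-equilibrium low-energy configuration quickly (stages at
    decreasing temperature, thermostatted throughout); fully deterministic
    for a given seed.  Intended for preparing compact/stacked fixtures at
    reduced scale, not for production statistics.
    """
    config = config or RunConfig()
    temps = [t for t, _ in schedule]
    if any(t2 > t1 for t1, t2 in zip(temps, temps[1:])):
        raise ValueError("annealing schedule must have non-increasing temperatures")
    state = _resolve_system(system, config.seed)
    evaluator = None
    for i, (temperature, n_steps) in enumerate(schedule):
        stage_cfg = replace(
            config,
            temperature=temperature,
            n_steps=n_steps,
            seed=config.seed + i,  # distinct, reproducible stream per stage
        )
        if evaluator is None:
            evaluator = ForceEvaluator(state, params, method)
        traj = run_simulation(state, stage_cfg, params, method, evaluator=evaluator)
        state = traj.metadata["final_state"]
    return state
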