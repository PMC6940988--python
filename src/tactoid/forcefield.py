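"""The interaction model: Coulomb + truncated-shifted LJ + bonds + angles.

All species interact through the implicit-solvent Coulomb potential

    u_el(r) = z_i z_j * lambda_B / r        [kBT]

with the Bjerrum length lambda_B set by the temperature and dielectric
constant, and through a strictly repulsive truncated-and-shifted
Lennard-Jones (TLJ) core

    u_tlj(r) = eps * [(sigma_ij/r)^12 - 2 (sigma_ij/r)^6 + 1]   for r < sigma_ij

which vanishes continuously at contact (sigma_ij is the arithmetic mean of
the two particle diameters).  Adjacent beads/sites are held by harmonic
bonds and straight-equilibrium harmonic angles; directly bonded pairs are
excluded from the non-bonded terms by default.

Three electrostatics routes are provided: full minimum-image summation
(exact for an isolated box image), plain truncation at a cutoff, and a
direct Ewald sum for the true periodic lattice energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels, ewald, units
from .state import SystemState

METHODS = ("bruteforce_minimum_image", "cutoff", "ewald")


@dataclass
class InteractionParams:
    """Interaction constants in internal units (nm, kBT)."""

    temperature: float = units.DEFAULT_TEMPERATURE
    dielectric: float = units.DEFAULT_DIELECTRIC
    tlj_strength: float = 1.0  # beta * eps_TLJ
    coulomb_cutoff: float = 6.0  # nm, real-space cutoff (cutoff & ewald methods)
    fourier_spacing: float = 0.6  # nm, nominal reciprocal resolution
    ewald_accuracy: float = 1e-6
    exclude_bonded: bool = True

    @property
    def bjerrum_length(self) -> float:
        return units.bjerrum_length(self.temperature, self.dielectric)


@dataclass
class EnergyReport:
    """Decomposed potential energy (kBT) and per-particle forces (kBT/nm)."""

    electrostatic: float
    excluded_volume: float
    bond: float
    angle: float
    forces: np.ndarray

    @property
    def total(self) -> float:
        return self.electrostatic + self.excluded_volume + self.bond + self.angle

    def as_dict(self) -> dict[str, float]:
        return {
            "electrostatic": self.electrostatic,
            "excluded_volume": self.excluded_volume,
            "bond": self.bond,
            "angle": self.angle,
            "total": self.total,
        }


def coulomb_pair(zi: float, zj: float, r: float, params: Optional[InteractionParams] = None) -> float:
    """Coulomb pair energy z_i z_j lambda_B / r in kBT."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    params = params or InteractionParams()
    return zi * zj * params.bjerrum_length / r


def tlj_pair(r: float, sigma_ij: float, eps_tlj: float = 1.0) -> float:
    """Truncated-shifted LJ energy in kBT; zero at and beyond contact."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r >= sigma_ij:
        return 0.0
    sr6 = (sigma_ij / r) ** 6
    return eps_tlj * (sr6 * sr6 - 2.0 * sr6 + 1.0)


def bond_energy(r: float, b: float, kb: float) -> float:
    """Harmonic bond energy (1/2) kb (r - b)^2 in kBT."""
    if r < 0:
        raise ValueError("bond length must be non-negative")
    return 0.5 * kb * (r - b) ** 2


def angle_energy(theta: float, k_theta: float, theta0: float = math.pi) -> float:
    """Harmonic angle energy (1/2) k_theta (theta - theta0)^2 in kBT."""
    if not 0.0 <= theta <= math.pi + 1e-12:
        raise ValueError("theta must lie in [0, pi]")
    return 0.5 * k_theta * (theta - theta0) ** 2


def _exclusion_table(state: SystemState, params: InteractionParams) -> np.ndarray:
    if params.exclude_bonded:
        return state.exclusion_table()
    return np.full((state.n_particles, 1), -1, dtype=np.int64)


class ForceEvaluator:
    """Reusable energy/force evaluator bound to one topology.

    Precomputes the exclusion table once so the per-step cost inside the
    integrator is just the numba kernels (plus, for the Ewald route, the
    reciprocal-space numpy sum).
    """

    def __init__(
        self,
        state: SystemState,
        params: Optional[InteractionParams] = None,
        method: str = "bruteforce_minimum_image",
    ) -> None:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        self.params = params or InteractionParams()
        self.method = method
        self.box = state.box_length
        self.charges = state.charges
        self.diameters = state.diameters
        self.bonds = state.bonds
        self.bond_r0 = state.bond_r0
        self.bond_k = state.bond_k
        self.angles = state.angles
        self.angle_k = state.angle_k
        self.excl = _exclusion_table(state, self.params)

    def __call__(self, positions: np.ndarray) -> EnergyReport:
        if not np.all(np.isfinite(positions)):
            raise ValueError("positions contain NaN/inf")
        pos = np.mod(positions, self.box)  # wrap, never reject
        p = self.params
        lb = p.bjerrum_length
        if self.method == "ewald":
            _, e_tlj, f_tlj = _kernels.nonbonded(
                pos, self.charges, self.diameters, self.excl, self.box, lb, -1.0,
                p.tlj_strength, False,
            )
            e_el, f_el = ewald.ewald_energy_forces(
                pos, self.charges, self.excl, self.box, lb,
                min(p.coulomb_cutoff, self.box / 2), p.ewald_accuracy,
            )
            f_nb = f_tlj + f_el
        else:
            rc = -1.0 if self.method == "bruteforce_minimum_image" else p.coulomb_cutoff
            e_el, e_tlj, f_nb = _kernels.nonbonded(
                pos, self.charges, self.diameters, self.excl, self.box, lb, rc,
                p.tlj_strength, True,
            )
        e_bond, f_bond = _kernels.bonded(pos, self.bonds, self.bond_r0, self.bond_k, self.box)
        e_angle, f_angle = _kernels.angular(pos, self.angles, self.angle_k, self.box)
        return EnergyReport(
            electrostatic=float(e_el),
            excluded_volume=float(e_tlj),
            bond=float(e_bond),
            angle=float(e_angle),
            forces=f_nb + f_bond + f_angle,
        )


def force_check_report(
    state: SystemState,
    params: Optional[InteractionParams] = None,
    method: str = "bruteforce_minimum_image",
    h: float = 2e-6,
) -> str:
    """Plain-text comparison of analytic forces vs numerical gradients.

    Central differences of the total energy, per particle and component;
    intended as a quick self-diagnostic when altering interaction
    parameters.
    """
    ev = ForceEvaluator(state, params, method)
    rep = ev(state.positions)
    grad = np.zeros_like(state.positions)
    for i in range(state.n_particles):
        for d in range(3):
            for sgn in (+1, -1):
                p = state.positions.copy()
                p[i, d] += sgn * h
                grad[i, d] += sgn * ev(p).total
    grad /= 2.0 * h
    err = np.abs(rep.forces + grad)
    scale = max(np.abs(rep.forces).max(), 1.0)
    lines = [
        f"# force check: method={method}, n={state.n_particles}, h={h:g}",
        f"# max |F| = {np.abs(rep.forces).max():.6g} kBT/nm",
        f"# max abs error = {err.max():.3g} kBT/nm "
        f"(relative {err.max() / scale:.3g})",
        "# particle  max_component_error",
    ]
    for i in range(state.n_particles):
        lines.append(f"{i + 1} {err[i].max():.3g}")
    return "\n".join(lines) + "\n"


def total_energy_forces(
    state: SystemState,
    params: Optional[InteractionParams] = None,
    method: str = "bruteforce_minimum_image",
) -> EnergyReport:
    """Evaluate the full potential energy and analytic forces.

    method:
      * ``bruteforce_minimum_image`` - every pair once at its nearest image
        (no cutoff); the reference for small boxes.
      * ``cutoff`` - Coulomb truncated (not shifted) at ``coulomb_cutoff``.
      * ``ewald`` - direct Ewald summation of the periodic lattice energy.
    """
    return ForceEvaluator(state, params, method)(state.positions)
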