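"""Deterministic test configurations with known geometry.

These builders produce :class:`SystemState` objects for observable tests
and for seeding reduced-scale runs: ideal face-to-face stacks (tactoids),
band-like arrangements, free chains, two-site probes, and a fully
assembled, electroneutral intercalated-stack starting configuration for
annealing.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .state import BEAD, SITE, SystemState
from .topology import (
    NPTopology,
    SystemSpec,
    _assemble_arrays,
    build_nanoplatelet,
    build_polyelectrolyte,
    spec_for_variant,
)


def _platelets_state(
    npt: NPTopology,
    centers: np.ndarray,
    box_length: float,
    rotations: Optional[list[np.ndarray]] = None,
) -> SystemState:
    """Sites-only state for a list of platelet placements (no ions/chain).

    Not electroneutral; intended for static structural analysis only.
    """
    n = npt.n_sites
    positions, bonds, angles = [], [], []
    for ip, center in enumerate(centers):
        rot = np.eye(3) if rotations is None else rotations[ip]
        positions.append(npt.site_positions @ rot.T + center)
        bonds.append(npt.bonds + ip * n)
        angles.append(npt.angles + ip * n)
    m = len(centers)
    return SystemState(
        positions=np.concatenate(positions),
        charges=np.tile(npt.site_charges, m),
        diameters=np.full(m * n, npt.site_diameter),
        species=np.full(m * n, SITE),
        molecule=np.repeat(np.arange(m), n),
        box_length=box_length,
        bonds=np.concatenate(bonds),
        bond_r0=np.full(m * len(npt.bonds), npt.bond_length),
        bond_k=np.full(m * len(npt.bonds), npt.bond_force_constant),
        angles=np.concatenate(angles),
        angle_k=np.full(m * len(npt.angles), npt.angle_force_constant),
        metadata={"fixture": "platelets"},
    )


def ideal_stack(
    n_platelets: int = 4,
    spacing: float = 2.2,
    box_length: float = 30.0,
    npt: Optional[NPTopology] = None,
) -> SystemState:
    """Face-to-face tactoid: parallel platelets at exact mid-plane spacing."""
    npt = npt or build_nanoplatelet()
    z0 = box_length / 2 - spacing * (n_platelets - 1) / 2
    centers = np.array(
        [[box_length / 2, box_length / 2, z0 + i * spacing] for i in range(n_platelets)]
    )
    st = _platelets_state(npt, centers, box_length)
    st.metadata.update(fixture="stack", spacing=spacing)
    return st


def band(
    n_platelets: int = 4,
    spacing: float = 12.0,
    box_length: float = 60.0,
    npt: Optional[NPTopology] = None,
    include_chain: bool = True,
) -> SystemState:
    """Platelets strung collinearly along an extended straight chain.

    Each platelet stands on edge (plane normal along the chain axis) with
    the chain passing through its centre, i.e. every platelet is in direct
    contact with the chain but neighbours are far apart.
    """
    npt = npt or build_nanoplatelet()
    x0 = box_length / 2 - spacing * (n_platelets - 1) / 2
    centers = np.array(
        [[x0 + i * spacing, box_length / 2, box_length / 2] for i in range(n_platelets)]
    )
    rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
    st = _platelets_state(npt, centers, box_length, rotations=[rot] * n_platelets)
    if include_chain:
        length = spacing * (n_platelets - 1) + 4.0
        n_beads = int(length / 0.5) + 1
        chain = free_chain(n_beads=n_beads, box_length=box_length, straight=True)
        st = _merge_states(st, chain)
    st.metadata.update(fixture="band", spacing=spacing)
    return st


def _merge_states(a: SystemState, b: SystemState) -> SystemState:
    """Concatenate two states sharing one box (indices of b are offset)."""
    if a.box_length != b.box_length:
        raise ValueError("box lengths differ")
    off = a.n_particles
    mol_off = int(a.molecule.max()) + 1 if a.n_particles else 0
    return SystemState(
        positions=np.vstack([a.positions, b.positions]),
        charges=np.concatenate([a.charges, b.charges]),
        diameters=np.concatenate([a.diameters, b.diameters]),
        species=np.concatenate([a.species, b.species]),
        molecule=np.concatenate([a.molecule, b.molecule + mol_off]),
        box_length=a.box_length,
        bonds=np.vstack([a.bonds, b.bonds + off]),
        bond_r0=np.concatenate([a.bond_r0, b.bond_r0]),
        bond_k=np.concatenate([a.bond_k, b.bond_k]),
        angles=np.vstack([a.angles, b.angles + off]),
        angle_k=np.concatenate([a.angle_k, b.angle_k]),
        metadata={**a.metadata, **b.metadata},
    )


def free_chain(
    n_beads: int = 50,
    bead_charge: float = 1.0,
    box_length: float = 60.0,
    straight: bool = True,
    seed: int = 0,
    k_theta: float = 0.0,
) -> SystemState:
    """A lone chain, straight (reference geometry) or freely jointed."""
    pet = build_polyelectrolyte(n_beads, bead_charge, angle_force_constant=k_theta)
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_beads, 3))
    center = np.full(3, box_length / 2)
    if straight:
        pos[:, 0] = (np.arange(n_beads) - (n_beads - 1) / 2) * pet.bond_length
        pos += center
    else:
        pos[0] = center
        for i in range(1, n_beads):
            step = rng.normal(size=3)
            pos[i] = pos[i - 1] + step / np.linalg.norm(step) * pet.bond_length
    idx = np.arange(n_beads)
    return SystemState(
        positions=pos,
        charges=np.full(n_beads, bead_charge),
        diameters=np.full(n_beads, pet.bead_diameter),
        species=np.full(n_beads, BEAD),
        molecule=np.zeros(n_beads, dtype=np.int64),
        box_length=box_length,
        bonds=np.column_stack([idx[:-1], idx[1:]]),
        bond_r0=np.full(n_beads - 1, pet.bond_length),
        bond_k=np.full(n_beads - 1, pet.bond_force_constant),
        angles=np.column_stack([idx[:-2], idx[1:-1], idx[2:]]) if n_beads >= 3 else np.empty((0, 3), dtype=np.int64),
        angle_k=np.full(max(n_beads - 2, 0), k_theta),
        metadata={"fixture": "free_chain"},
    )


def two_site(distance: float = 2.2, box_length: float = 30.0) -> SystemState:
    """Two neutral probe sites at an exact separation."""
    half = box_length / 2
    return SystemState(
        positions=np.array([[half, half, half - distance / 2], [half, half, half + distance / 2]]),
        charges=np.zeros(2),
        diameters=np.ones(2),
        species=np.full(2, SITE),
        molecule=np.array([0, 1]),
        box_length=box_length,
        metadata={"fixture": "two_site", "distance": distance},
    )


def _serpentine(n_beads: int, bond_length: float, half_width: float) -> np.ndarray:
    """Boustrophedon filling of a square patch, consecutive points at the
    bond length; returned centred at the origin in the z = 0 plane."""
    per_row = max(2, int(2 * half_width / bond_length))
    pts = []
    row = 0
    while len(pts) < n_beads:
        xs = np.arange(per_row) * bond_length
        if row % 2:
            xs = xs[::-1]
        for x in xs:
            pts.append((x, row * bond_length, 0.0))
            if len(pts) == n_beads:
                break
        row += 1
    pts = np.array(pts)
    return pts - pts.mean(axis=0)


def intercalated_stack(
    spec: Optional[SystemSpec] = None,
    n_platelets: int = 2,
    n_beads: int = 110,
    spacing: float = 3.2,
    box_length: float = 30.0,
    seed: int = 0,
) -> tuple[SystemSpec, SystemState]:
    """Electroneutral starting configuration for a tactoid anneal.

    Parallel platelets at a deliberately loose mid-plane ``spacing`` with
    the chain laid as serpentine layers in the inter-platelet gaps (beads
    split evenly over the gaps) and counterions placed uniformly outside
    the stack region.  The relaxed spacing must then emerge from the force
    field, not from this construction.
    """
    if spec is None:
        spec = spec_for_variant(
            "S.I", n_nps=n_platelets, n_beads=n_beads, box_length=box_length
        )
    npt, pet = spec.np_topology, spec.pe_topology
    rng = np.random.default_rng(seed)
    half = box_length / 2
    m = spec.n_nps
    z0 = half - spacing * (m - 1) / 2
    centers = [np.array([half, half, z0 + i * spacing]) for i in range(m)]
    positions = [npt.site_positions + c for c in centers]

    # chain: serpentine layers midway in each gap, threaded gap to gap
    n_gaps = max(m - 1, 1)
    per_gap = [pet.n_beads // n_gaps + (1 if g < pet.n_beads % n_gaps else 0) for g in range(n_gaps)]
    radius = npt.site_positions[:, 0].max() * 0.8
    chain_parts = []
    for g, nb_g in enumerate(per_gap):
        z = z0 + (g + 0.5) * spacing if m > 1 else half + spacing / 2
        patch = _serpentine(nb_g, pet.bond_length, radius)
        if g % 2:
            patch = patch[::-1]
        chain_parts.append(patch + np.array([half, half, z]))
    chain = np.concatenate(chain_parts)
    positions.append(chain)

    # ions: uniform, rejecting the stack cylinder and hard overlaps
    placed = np.concatenate(positions)
    placed_dia = np.concatenate(
        [np.full(m * npt.n_sites, npt.site_diameter), np.full(pet.n_beads, pet.bead_diameter)]
    )
    n_ions = sum(spec.counterion_counts.values())
    ion_pos = []
    while len(ion_pos) < n_ions:
        trial = rng.uniform(0, box_length, size=3)
        d = np.sqrt(((placed - trial) ** 2).sum(axis=1))
        if np.all(d > 0.5 * (placed_dia + spec.ion_diameter)):
            ion_pos.append(trial)
    positions.append(np.array(ion_pos))

    state = _assemble_arrays(spec, np.concatenate(positions), seed=seed)
    state.metadata.update(fixture="intercalated_stack", initial_spacing=spacing)
    return spec, state


def generate_fixture(kind: str, params: Optional[dict] = None, seed: int = 0):
    """Dispatch to a named fixture builder.

    kinds: ``stack``, ``band``, ``free_chain``, ``two_site``,
    ``intercalated_stack`` (the last returns (spec, state)).
    """
    params = dict(params or {})
    builders = {
        "stack": ideal_stack,
        "band": band,
        "free_chain": free_chain,
        "two_site": two_site,
        "intercalated_stack": intercalated_stack,
    }
    if kind not in builders:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(builders)}")
    if kind in ("free_chain", "intercalated_stack"):
        params.setdefault("seed", seed)
    return builders[kind](**params)
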