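"""Construction of nanoplatelet, polyelectrolyte and full-system topologies.

The nanoplatelet (NP) is a rigid-ish hexagonal monolayer of bonded sites
mimicking a clay platelet: a negatively charged face and a small positive
rim charge.  The polyelectrolyte (PE) is a bead-spring chain with uniform
positive charge per bead.  Explicit monovalent counterions neutralise the
net charge of each macro-species, so every assembled system is exactly
electroneutral.

Charge bookkeeping is expressed through the stoichiometric charge-ratio

    beta = |Np * Zp / (Nb * Zb)|

(total NP net charge over total chain charge) and its complexed analogue
beta_c, which restricts the numerator to platelets actually bound to the
chain.  beta_c > 1 signals an overcharged complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import units
from .state import ANION, BEAD, CATION, SITE, SystemState, minimum_image

# hexagonal axial directions (unit steps of the triangular lattice)
_AXIAL_DIRECTIONS = ((1, 0), (0, 1), (-1, 1))


@dataclass
class NPTopology:
    """One hexagonal platelet: site geometry, charges and bonded terms."""

    site_positions: np.ndarray  # (n, 3) nm, reference geometry (planar, centered)
    site_charges: np.ndarray  # (n,) e
    site_diameter: float  # nm (sigma_site)
    bonds: np.ndarray  # (m, 2) site-index pairs, nearest neighbours
    bond_length: float  # nm, equilibrium nearest-neighbour distance
    angles: np.ndarray  # (k, 3) collinear triplets, theta0 = pi
    interior_mask: np.ndarray = None  # (n,) bool; True = face site, False = perimeter
    bond_force_constant: float = 5000.0  # kBT/nm^2
    angle_force_constant: float = 5000.0  # kBT/rad^2

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def face_charge_total(self) -> float:
        """Total charge of the interior (face) sites, Zface."""
        return float(self.site_charges[self.interior_mask].sum())

    @property
    def rim_charge_total(self) -> float:
        """Total charge of the perimeter ring, Zrim."""
        return float(self.site_charges[~self.interior_mask].sum())

    @property
    def net_charge(self) -> float:
        """Zp = Zface + Zrim."""
        return float(self.site_charges.sum())


@dataclass
class PETopology:
    """Bead-spring polyelectrolyte chain."""

    n_beads: int
    bead_charge: float  # e per bead (fractional values allowed)
    bond_length: float = 0.5  # nm
    bead_diameter: float = 0.4  # nm (sigma_b)
    angle_force_constant: float = 0.0  # kBT/rad^2 (0 = fully flexible)
    bond_force_constant: float = 500.0  # kBT/nm^2

    @property
    def total_charge(self) -> float:
        """Zchain = Nb * Zb."""
        return self.n_beads * self.bead_charge


@dataclass
class SystemSpec:
    """Composition of one simulated system."""

    n_nps: int
    np_topology: NPTopology
    pe_topology: PETopology
    counterion_counts: dict[str, int]  # {"cation": n+, "anion": n-}
    ion_diameter: float = 0.4  # nm
    box_length: float = 100.0  # nm
    temperature: float = units.DEFAULT_TEMPERATURE  # K
    dielectric: float = units.DEFAULT_DIELECTRIC
    variant: Optional[str] = None

    @property
    def total_charge(self) -> float:
        return (
            self.n_nps * self.np_topology.net_charge
            + self.pe_topology.total_charge
            + self.counterion_counts.get("cation", 0)
            - self.counterion_counts.get("anion", 0)
        )

    @property
    def n_particles(self) -> int:
        return (
            self.n_nps * self.np_topology.n_sites
            + self.pe_topology.n_beads
            + sum(self.counterion_counts.values())
        )

    def volume_fraction(self) -> dict[str, float]:
        """Volume fractions from the site/bead/ion sphere volumes."""
        v_box = self.box_length**3
        v_sphere = lambda d: math.pi * d**3 / 6.0  # noqa: E731
        return {
            "np": self.n_nps * self.np_topology.n_sites * v_sphere(self.np_topology.site_diameter) / v_box,
            "pe": self.pe_topology.n_beads * v_sphere(self.pe_topology.bead_diameter) / v_box,
            "ions": sum(self.counterion_counts.values()) * v_sphere(self.ion_diameter) / v_box,
        }


@dataclass
class ChargeRatios:
    """Stoichiometric (beta) and complexed (beta_c) charge ratios."""

    beta: float
    beta_c: float
    n_complexed: float


def _hex_axial_coords(n_shells: int) -> list[tuple[int, int]]:
    """Axial (q, r) coordinates of a centered hexagonal patch of given radius."""
    coords = []
    for q in range(-n_shells, n_shells + 1):
        for r in range(-n_shells, n_shells + 1):
            if abs(q + r) <= n_shells:
                coords.append((q, r))
    return coords


def _hex_shell(q: int, r: int) -> int:
    return (abs(q) + abs(r) + abs(q + r)) // 2


def build_nanoplatelet(
    n_shells: int = 5,
    site_diameter: float = 1.0,
    face_site_charge: float = -1.0,
    corner_site_charge: float = 1.0,
    bond_length: float = 1.0,
    bond_force_constant: float = 5000.0,
    angle_force_constant: float = 5000.0,
) -> NPTopology:
    """Build one hexagonal platelet on a centered hexagonal lattice.

    The patch has 3*n*(n+1)+1 sites for n shells.  Interior sites (all
    shells but the outermost ring) each carry ``face_site_charge``; of the
    outermost ring only the six hexagon corners carry ``corner_site_charge``
    and the remaining perimeter sites are neutral.  With the defaults
    (n_shells=5) this gives 91 sites, 11 sites across, face charge -61,
    rim charge +6 and net charge Zp = -55.

    Bonds connect every nearest-neighbour pair at ``bond_length``; angle
    triplets cover all collinear site triples along the three lattice
    directions with equilibrium angle pi, which together keep the platelet
    planar and rigid at the default force constants.
    """
    if n_shells < 0:
        raise ValueError("n_shells must be >= 0")
    if site_diameter <= 0:
        raise ValueError("site_diameter must be positive")

    coords = _hex_axial_coords(n_shells)
    index = {c: i for i, c in enumerate(coords)}
    n = len(coords)

    positions = np.zeros((n, 3))
    charges = np.zeros(n)
    interior = np.zeros(n, dtype=bool)
    corners = {
        (n_shells, 0),
        (0, n_shells),
        (-n_shells, n_shells),
        (-n_shells, 0),
        (0, -n_shells),
        (n_shells, -n_shells),
    }
    for (q, r), i in index.items():
        positions[i, 0] = bond_length * (q + 0.5 * r)
        positions[i, 1] = bond_length * r * math.sqrt(3.0) / 2.0
        shell = _hex_shell(q, r)
        if n_shells == 0 or shell < n_shells:
            charges[i] = face_site_charge
            interior[i] = True
        elif (q, r) in corners:
            charges[i] = corner_site_charge

    bonds = []
    for (q, r), i in index.items():
        for dq, dr in _AXIAL_DIRECTIONS:
            j = index.get((q + dq, r + dr))
            if j is not None:
                bonds.append((i, j))
    angles = []
    for (q, r), i in index.items():
        for dq, dr in _AXIAL_DIRECTIONS:
            a = index.get((q - dq, r - dr))
            c = index.get((q + dq, r + dr))
            if a is not None and c is not None:
                angles.append((a, i, c))

    return NPTopology(
        site_positions=positions,
        site_charges=charges,
        site_diameter=site_diameter,
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        bond_length=bond_length,
        angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
        interior_mask=interior,
        bond_force_constant=bond_force_constant,
        angle_force_constant=angle_force_constant,
    )


def build_polyelectrolyte(
    n_beads: int,
    bead_charge: float = 1.0,
    angle_force_constant: float = 0.0,
    bond_length: float = 0.5,
    bead_diameter: float = 0.4,
    bond_force_constant: float = 500.0,
) -> PETopology:
    """Bead-spring chain with uniform per-bead charge.

    Fractional ``bead_charge`` (e.g. 0.5, 0.25) models a reduced linear
    charge density at fixed chain length.
    """
    if n_beads < 2:
        raise ValueError("a chain needs at least 2 beads")
    if bead_charge < 0:
        raise ValueError("bead_charge must be >= 0")
    return PETopology(
        n_beads=n_beads,
        bead_charge=bead_charge,
        bond_length=bond_length,
        bead_diameter=bead_diameter,
        angle_force_constant=angle_force_constant,
        bond_force_constant=bond_force_constant,
    )


def stoichiometric_ratio(
    n_nps: int, np_net_charge: float, n_beads: int, bead_charge: float
) -> float:
    """beta = |Np*Zp / (Nb*Zb)|: total NP net charge over total chain charge."""
    chain_charge = n_beads * bead_charge
    if chain_charge == 0:
        raise ValueError("chain charge is zero; beta undefined")
    return abs(n_nps * np_net_charge / chain_charge)


def complexed_ratio(
    n_complexed: float, np_net_charge: float, n_beads: int, bead_charge: float
) -> float:
    """beta_c = |Npc*Zp / (Nb*Zb)|, restricted to complexed platelets."""
    chain_charge = n_beads * bead_charge
    if chain_charge == 0:
        raise ValueError("chain charge is zero; beta_c undefined")
    return abs(n_complexed * np_net_charge / chain_charge)


def charge_ratios(
    n_nps: int,
    n_complexed: float,
    np_net_charge: float,
    n_beads: int,
    bead_charge: float,
) -> ChargeRatios:
    """Bundle beta and beta_c for one system composition.

    ``n_complexed`` may be fractional (a time average); beta_c <= beta
    whenever n_complexed <= n_nps.
    """
    if n_complexed > n_nps:
        raise ValueError("complexed count cannot exceed the platelet count")
    return ChargeRatios(
        beta=stoichiometric_ratio(n_nps, np_net_charge, n_beads, bead_charge),
        beta_c=complexed_ratio(n_complexed, np_net_charge, n_beads, bead_charge),
        n_complexed=n_complexed,
    )


@dataclass(frozen=True)
class Variant:
    """One row of the study's system table."""

    z_face: float
    z_rim: float
    n_beads: int
    bead_charge: float
    k_theta: float
    n_chains: int = 1


#: The six studied system variants.  S.I is the reference (flexible chain
#: charge-matched to the platelets' net charge); S.II varies chain length,
#: S.III linear charge density, S.IV stiffness; S.V matches the face charge
#: of 8 platelets; S.VI additionally removes the rim charge.
VARIANTS: dict[str, Variant] = {
    "S.I": Variant(z_face=-61, z_rim=6, n_beads=440, bead_charge=1.0, k_theta=0.0),
    "S.II": Variant(z_face=-61, z_rim=6, n_beads=440, bead_charge=1.0, k_theta=0.0),
    "S.III": Variant(z_face=-61, z_rim=6, n_beads=440, bead_charge=1.0, k_theta=0.0),
    "S.IV": Variant(z_face=-61, z_rim=6, n_beads=440, bead_charge=1.0, k_theta=0.0),
    "S.V": Variant(z_face=-61, z_rim=6, n_beads=488, bead_charge=1.0, k_theta=0.0),
    "S.VI": Variant(z_face=-61, z_rim=0, n_beads=488, bead_charge=1.0, k_theta=0.0),
}


def spec_for_variant(
    variant: str,
    n_nps: int,
    n_beads: Optional[int] = None,
    bead_charge: Optional[float] = None,
    k_theta: Optional[float] = None,
    box_length: float = 100.0,
    n_shells: int = 5,
    rim_on: bool = True,
    temperature: float = units.DEFAULT_TEMPERATURE,
    dielectric: float = units.DEFAULT_DIELECTRIC,
) -> SystemSpec:
    """Resolve a variant row plus overrides into a full :class:`SystemSpec`.

    Counterions neutralise the *net* charge of each macro-species:
    Np*|Zp| monovalent cations for the platelets and Nb*Zb monovalent
    anions for the chain.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    if not (0 <= n_nps <= 16):
        raise ValueError("n_nps must be within 0-16")
    row = VARIANTS[variant]
    n_beads = row.n_beads if n_beads is None else n_beads
    bead_charge = row.bead_charge if bead_charge is None else bead_charge
    k_theta = row.k_theta if k_theta is None else k_theta

    corner_charge = row.z_rim / 6.0 if rim_on else 0.0
    np_topo = build_nanoplatelet(n_shells=n_shells, corner_site_charge=corner_charge)
    pe_topo = build_polyelectrolyte(n_beads, bead_charge, angle_force_constant=k_theta)

    n_cations = n_nps * abs(np_topo.net_charge)
    n_anions = pe_topo.total_charge
    for name, value in (("cation", n_cations), ("anion", n_anions)):
        if abs(value - round(value)) > 1e-9:
            raise ValueError(
                f"{name} count {value} is not an integer; adjust charges"
            )
    return SystemSpec(
        n_nps=n_nps,
        np_topology=np_topo,
        pe_topology=pe_topo,
        counterion_counts={"cation": int(round(n_cations)), "anion": int(round(n_anions))},
        box_length=box_length,
        temperature=temperature,
        dielectric=dielectric,
        variant=variant,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class PlacementError(RuntimeError):
    """Raised when random insertion cannot resolve hard-core overlaps."""


def _no_overlap(
    pos_new: np.ndarray,
    dia_new: np.ndarray,
    pos_old: np.ndarray,
    dia_old: np.ndarray,
    box: float,
) -> bool:
    if len(pos_old) == 0:
        return True
    dr = minimum_image(pos_new[:, None, :] - pos_old[None, :, :], box)
    dist = np.sqrt((dr**2).sum(axis=-1))
    contact = 0.5 * (dia_new[:, None] + dia_old[None, :])
    return bool(np.all(dist >= contact))


def build_state(spec: SystemSpec, seed: int = 0, max_tries: int = 200) -> SystemState:
    """Place platelets, chain and ions in the box without hard-core overlaps.

    Platelets get random centres and orientations; the chain is grown as a
    freely jointed walk with per-step overlap rejection; ions are inserted
    uniformly.  All randomness comes from ``seed``.
    """
    rng = np.random.default_rng(seed)
    box = spec.box_length
    npt, pet = spec.np_topology, spec.pe_topology

    positions: list[np.ndarray] = []
    diameters: list[np.ndarray] = []

    def placed_arrays():
        if positions:
            return np.concatenate(positions), np.concatenate(diameters)
        return np.empty((0, 3)), np.empty(0)

    # platelets
    for _ in range(spec.n_nps):
        for attempt in range(max_tries):
            center = rng.uniform(0, box, size=3)
            rot = _random_rotation(rng)
            sites = npt.site_positions @ rot.T + center
            dia = np.full(npt.n_sites, npt.site_diameter)
            old_p, old_d = placed_arrays()
            if _no_overlap(sites, dia, old_p, old_d, box):
                positions.append(sites)
                diameters.append(dia)
                break
        else:
            raise PlacementError(f"could not place platelet after {max_tries} tries (seed={seed})")

    # chain: freely jointed walk with overlap rejection
    chain = np.zeros((pet.n_beads, 3))
    for attempt in range(max_tries):
        chain[0] = rng.uniform(0, box, size=3)
        old_p, old_d = placed_arrays()
        ok = True
        for ib in range(1, pet.n_beads):
            for _ in range(max_tries):
                step = rng.normal(size=3)
                step *= pet.bond_length / np.linalg.norm(step)
                trial = chain[ib - 1] + step
                prev = chain[: max(0, ib - 1)]  # skip bonded neighbour
                dia_t = np.array([pet.bead_diameter])
                if _no_overlap(trial[None], dia_t, old_p, old_d, box) and _no_overlap(
                    trial[None], dia_t, prev, np.full(len(prev), pet.bead_diameter), box
                ):
                    chain[ib] = trial
                    break
            else:
                ok = False
                break
        if ok:
            break
    else:
        raise PlacementError(f"could not grow chain after {max_tries} tries (seed={seed})")
    positions.append(chain)
    diameters.append(np.full(pet.n_beads, pet.bead_diameter))

    # ions
    n_cat = spec.counterion_counts.get("cation", 0)
    n_an = spec.counterion_counts.get("anion", 0)
    for _ in range(n_cat + n_an):
        for attempt in range(max_tries):
            trial = rng.uniform(0, box, size=3)
            old_p, old_d = placed_arrays()
            if _no_overlap(trial[None], np.array([spec.ion_diameter]), old_p, old_d, box):
                positions.append(trial[None])
                diameters.append(np.array([spec.ion_diameter]))
                break
        else:
            raise PlacementError(f"could not place ion after {max_tries} tries (seed={seed})")

    return _assemble_arrays(spec, np.concatenate(positions), seed=seed)


def _assemble_arrays(spec: SystemSpec, all_positions: np.ndarray, seed=None) -> SystemState:
    """Combine per-species positions with charges, species codes and topology."""
    npt, pet = spec.np_topology, spec.pe_topology
    n_site = npt.n_sites
    n_cat = spec.counterion_counts.get("cation", 0)
    n_an = spec.counterion_counts.get("anion", 0)

    charges, dia, species, molecule = [], [], [], []
    bonds, bond_r0, bond_k, angles, angle_k = [], [], [], [], []
    offset = 0
    for ip in range(spec.n_nps):
        charges.append(npt.site_charges)
        dia.append(np.full(n_site, npt.site_diameter))
        species.append(np.full(n_site, SITE))
        molecule.append(np.full(n_site, ip))
        bonds.append(npt.bonds + offset)
        bond_r0.append(np.full(len(npt.bonds), npt.bond_length))
        bond_k.append(np.full(len(npt.bonds), npt.bond_force_constant))
        angles.append(npt.angles + offset)
        angle_k.append(np.full(len(npt.angles), npt.angle_force_constant))
        offset += n_site

    nb = pet.n_beads
    charges.append(np.full(nb, pet.bead_charge))
    dia.append(np.full(nb, pet.bead_diameter))
    species.append(np.full(nb, BEAD))
    molecule.append(np.full(nb, spec.n_nps))
    idx = np.arange(nb) + offset
    bonds.append(np.column_stack([idx[:-1], idx[1:]]))
    bond_r0.append(np.full(nb - 1, pet.bond_length))
    bond_k.append(np.full(nb - 1, pet.bond_force_constant))
    if nb >= 3:
        angles.append(np.column_stack([idx[:-2], idx[1:-1], idx[2:]]))
        angle_k.append(np.full(nb - 2, pet.angle_force_constant))
    offset += nb

    mol0 = spec.n_nps + 1
    charges.append(np.ones(n_cat))
    charges.append(-np.ones(n_an))
    dia.append(np.full(n_cat + n_an, spec.ion_diameter))
    species.append(np.full(n_cat, CATION))
    species.append(np.full(n_an, ANION))
    molecule.append(np.arange(n_cat + n_an) + mol0)

    state = SystemState(
        positions=all_positions,
        charges=np.concatenate(charges),
        diameters=np.concatenate(dia),
        species=np.concatenate(species),
        molecule=np.concatenate(molecule),
        box_length=spec.box_length,
        bonds=np.concatenate(bonds) if bonds else np.empty((0, 2), dtype=np.int64),
        bond_r0=np.concatenate(bond_r0) if bond_r0 else np.empty(0),
        bond_k=np.concatenate(bond_k) if bond_k else np.empty(0),
        angles=np.concatenate(angles) if angles else np.empty((0, 3), dtype=np.int64),
        angle_k=np.concatenate(angle_k) if angle_k else np.empty(0),
        metadata={"seed": seed, "variant": spec.variant},
    )
    if abs(state.total_charge) > 1e-9:
        raise ValueError(f"assembled system is not electroneutral: {state.total_charge}")
    return state


def assemble_system(
    variant: str, n_nps: int, seed: int = 0, **overrides
) -> tuple[SystemSpec, SystemState]:
    """Build spec and an overlap-free initial configuration for a variant row."""
    spec = spec_for_variant(variant, n_nps, **overrides)
    return spec, build_state(spec, seed=seed)
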