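"""In-memory representation of one configuration of the full system.

A :class:`SystemState` is a flat, array-of-structs view of every particle
(nanoplatelet sites, polyelectrolyte beads, counterions) together with the
bonded topology (harmonic bonds and angle triplets).  It is the single
currency passed between assembly, the force field, the integrator and the
observable layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# species codes
SITE = 0  # nanoplatelet site
BEAD = 1  # polyelectrolyte bead
CATION = 2
ANION = 3

SPECIES_LABELS = ("site", "bead", "cation", "anion")


@dataclass
class SystemState:
    """Positions, charges and bonded topology of all particles in a cubic box.

    Particles are ordered platelets first (sites of platelet 0, platelet 1,
    ...), then chain beads, then cations, then anions.  ``molecule`` groups
    particles into physical molecules: platelet index 0..Np-1, the chain is
    the next id, each ion its own id.
    """

    positions: np.ndarray  # (N, 3) nm
    charges: np.ndarray  # (N,) e
    diameters: np.ndarray  # (N,) nm
    species: np.ndarray  # (N,) int codes, see SPECIES_LABELS
    molecule: np.ndarray  # (N,) int molecule ids
    box_length: float  # nm
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    bond_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    bond_k: np.ndarray = field(default_factory=lambda: np.empty(0))  # kBT/nm^2
    angles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    angle_k: np.ndarray = field(default_factory=lambda: np.empty(0))  # kBT/rad^2
    velocities: Optional[np.ndarray] = None  # (N, 3) nm/ps, half-step in MD
    masses: Optional[np.ndarray] = None  # (N,) reduced units
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.charges = np.ascontiguousarray(self.charges, dtype=np.float64)
        self.diameters = np.ascontiguousarray(self.diameters, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        self.molecule = np.ascontiguousarray(self.molecule, dtype=np.int64)
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.ascontiguousarray(self.angles, dtype=np.int64).reshape(-1, 3)
        n = len(self.positions)
        for name in ("charges", "diameters", "species", "molecule"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {n}")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def indices_of(self, species_code: int) -> np.ndarray:
        return np.flatnonzero(self.species == species_code)

    @property
    def site_indices(self) -> np.ndarray:
        """Indices of all nanoplatelet sites."""
        return self.indices_of(SITE)

    @property
    def bead_indices(self) -> np.ndarray:
        """Indices of all polyelectrolyte beads."""
        return self.indices_of(BEAD)

    def platelet_site_groups(self) -> list[np.ndarray]:
        """Site indices grouped per platelet, in platelet order."""
        sites = self.site_indices
        if len(sites) == 0:
            return []
        mols = self.molecule[sites]
        return [sites[mols == m] for m in np.unique(mols)]

    def exclusion_table(self, max_neighbors: int = 8) -> np.ndarray:
        """Bonded first-neighbour exclusions as an (N, max_neighbors) table.

        Row i lists the particles bonded to i, padded with -1.  Used by the
        non-bonded kernels to skip directly bonded pairs.
        """
        n = self.n_particles
        table = np.full((n, max_neighbors), -1, dtype=np.int64)
        counts = np.zeros(n, dtype=np.int64)
        for i, j in self.bonds:
            for a, b_ in ((i, j), (j, i)):
                if counts[a] >= max_neighbors:  # pragma: no cover - topology bound
                    raise ValueError("exclusion table overflow; raise max_neighbors")
                table[a, counts[a]] = b_
                counts[a] += 1
        return table

    def wrapped_positions(self) -> np.ndarray:
        """Positions folded into [0, L)^3."""
        return np.mod(self.positions, self.box_length)

    def copy(self) -> "SystemState":
        return replace(
            self,
            positions=self.positions.copy(),
            charges=self.charges.copy(),
            diameters=self.diameters.copy(),
            species=self.species.copy(),
            molecule=self.molecule.copy(),
            bonds=self.bonds.copy(),
            bond_r0=self.bond_r0.copy(),
            bond_k=self.bond_k.copy(),
            angles=self.angles.copy(),
            angle_k=self.angle_k.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            masses=None if self.masses is None else self.masses.copy(),
            metadata=dict(self.metadata),
        )


def minimum_image(dr: np.ndarray, box_length: float) -> np.ndarray:
    """Nearest periodic image of displacement vectors in a cubic box."""
    return dr - box_length * np.round(dr / box_length)
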