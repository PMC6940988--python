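"""Trajectory container: a stack of configuration snapshots plus provenance."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .state import SystemState


@dataclass
class Trajectory:
    """Frames of one run, with constant particle identity across frames."""

    frames: np.ndarray  # (F, N, 3) nm
    times: np.ndarray  # (F,) ps
    box_length: float
    species: np.ndarray  # (N,)
    charges: np.ndarray  # (N,)
    diameters: np.ndarray  # (N,)
    molecule: np.ndarray  # (N,)
    energies: Optional[pd.DataFrame] = None  # one row per recorded frame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        self.times = np.asarray(self.times, dtype=np.float64)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames disagree in length")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_particles(self) -> int:
        return self.frames.shape[1]

    def production_slice(self, equilibration_fraction: float = 0.2) -> np.ndarray:
        """Frames after discarding the initial equilibration fraction."""
        start = int(np.ceil(self.n_frames * equilibration_fraction))
        start = min(start, self.n_frames - 1)
        return self.frames[start:]

    @classmethod
    def from_states(cls, states: list[SystemState], times=None, **kw) -> "Trajectory":
        s0 = states[0]
        return cls(
            frames=np.stack([s.positions for s in states]),
            times=np.arange(len(states), dtype=float) if times is None else times,
            box_length=s0.box_length,
            species=s0.species,
            charges=s0.charges,
            diameters=s0.diameters,
            molecule=s0.molecule,
            **kw,
        )

    def state_at(self, frame: int, template: Optional[SystemState] = None) -> SystemState:
        """Materialise one frame as a SystemState (topology from template)."""
        if template is not None:
            st = template.copy()
            st.positions = self.frames[frame].copy()
            return st
        return SystemState(
            positions=self.frames[frame].copy(),
            charges=self.charges.copy(),
            diameters=self.diameters.copy(),
            species=self.species.copy(),
            molecule=self.molecule.copy(),
            box_length=self.box_length,
        )
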