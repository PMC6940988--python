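"""Reduced-scale study protocols.

End-to-end recipes that chain assembly, annealing, production dynamics and
analysis at desk scale (30 nm box, 10^5-scale step counts).  They follow
the same physics as the full-scale study but are deliberately small enough
to run in minutes on one CPU; the methods note discusses what that scale
change does and does not preserve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fixtures, observables
from .forcefield import InteractionParams
from .integrate import RunConfig, anneal_fixture, run_simulation
from .topology import complexed_ratio, spec_for_variant, stoichiometric_ratio


@dataclass
class StackedPairResult:
    d_bragg: Optional[float]  # nm, from the S_w Bragg peak
    qmax: Optional[float]  # nm^-1
    center_spacing: float  # nm, mean platelet-centre separation (control metric)
    mean_complexed: float
    sf: observables.StructureFactorResult = field(repr=False, default=None)


def stacked_pair_dspacing(
    seed: int = 0,
    n_beads: int = 110,
    box_length: float = 30.0,
    anneal_steps: int = 30_000,
    production_steps: int = 100_000,
    timestep_fs: float = 10.0,
    q_window: tuple[float, float] = (2.0, 4.0),
) -> StackedPairResult:
    """Assemble, anneal and measure a chain-intercalated platelet pair.

    Two platelets, a charge-matched 110-bead chain and the counterions are
    placed at random in the box; annealing (600 -> 298 K) lets the complex
    self-assemble, and the stacking distance then emerges from the force
    field rather than from any constructed geometry.  S_w(q) is computed
    from the site-site g(r) over the 298 K production frames with the
    half-box window, and the d-spacing is 2 pi / q_max of the high-q
    stacking peak.
    """
    from .topology import build_state, spec_for_variant

    spec = spec_for_variant("S.I", n_nps=2, n_beads=n_beads, box_length=box_length)
    state = build_state(spec, seed=seed)
    params = InteractionParams()
    cfg = RunConfig(
        timestep_fs=timestep_fs,
        seed=seed,
        output_stride=500,
        thermostat_coupling_ps=0.1,
    )
    schedule = [
        (600.0, anneal_steps),
        (450.0, anneal_steps),
        (350.0, anneal_steps),
        (298.0, anneal_steps),
    ]
    state = anneal_fixture(state, schedule, cfg, params)

    prod_cfg = RunConfig(
        n_steps=production_steps,
        timestep_fs=timestep_fs,
        temperature=298.0,
        thermostat_coupling_ps=0.1,
        seed=seed + 100,
        output_stride=500,
    )
    traj = run_simulation(state, prod_cfg, params)

    sites = traj.state_at(0).site_indices
    gr = observables.rdf(traj, selection=sites, bin_width=0.02, equilibration_fraction=0.3)
    sf = observables.structure_factor_windowed(
        gr, n_sites=len(sites), volume=box_length**3, r_cut=box_length / 2,
        q_grid=observables.default_q_grid(box_length, n_points=400),
    )
    d = observables.bragg_dspacing(sf, q_window=q_window)

    comp = observables.complexation_probability(traj, equilibration_fraction=0.3)
    final = traj.frames[-1]
    groups = traj.state_at(0).platelet_site_groups()
    centers = [observables._unwrap_cluster(final[g], box_length).mean(axis=0) for g in groups]
    from .state import minimum_image

    spacing = float(np.linalg.norm(minimum_image(centers[1] - centers[0], box_length)))
    return StackedPairResult(
        d_bragg=d,
        qmax=sf.qmax,
        center_spacing=spacing,
        mean_complexed=comp.mean_complexed,
        sf=sf,
    )


def overcharging_sweep(
    seed: int = 0,
    np_values: Sequence[int] = (2, 4, 6, 8),
    n_beads: int = 52,
    n_shells: int = 3,
    box_length: float = 30.0,
    anneal_steps: int = 15_000,
    production_steps: int = 50_000,
) -> pd.DataFrame:
    """Reduced overcharging study: how many platelets stay bound vs added.

    Uses small 3-shell platelets (37 sites, net charge -13) and a chain
    charge-matched to four of them, so beta = 0.25 * Np as in the
    full-scale series.  Each point starts from a fully intercalated stack
    and relaxes at 298 K; excess platelets beyond the overcharged plateau
    are expelled by the net-negative complex.  Columns: np, beta, mean_n,
    beta_c (from the rounded bound count).
    """
    rows = []
    for i, n_p in enumerate(np_values):
        spec = spec_for_variant(
            "S.I", n_nps=n_p, n_beads=n_beads, box_length=box_length, n_shells=n_shells
        )
        run_seed = seed + 1000 * i
        _, state = fixtures.intercalated_stack(
            spec=spec, spacing=3.0, box_length=box_length, seed=run_seed
        )
        cfg = RunConfig(seed=run_seed, output_stride=500, thermostat_coupling_ps=0.1)
        state = anneal_fixture(state, [(400.0, anneal_steps), (298.0, anneal_steps)], cfg)
        prod = RunConfig(
            n_steps=production_steps, seed=run_seed + 1, output_stride=500,
            thermostat_coupling_ps=0.1,
        )
        traj = run_simulation(state, prod)
        comp = observables.complexation_probability(traj, equilibration_fraction=0.3)
        zp = spec.np_topology.net_charge
        rows.append(
            {
                "np": n_p,
                "beta": stoichiometric_ratio(n_p, zp, n_beads, spec.pe_topology.bead_charge),
                "mean_n": comp.mean_complexed,
                "sem_n": comp.sem_complexed,
                "beta_c": comp.beta_c,
            }
        )
    return pd.DataFrame(rows)
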