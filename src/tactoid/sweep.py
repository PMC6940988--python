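"""State-diagram sweeps over the number of added platelets.

For a series Np = 1..16 (or any subset) the sweep emits one summary row
per point with the quantities that span the state diagram: beta, beta_c,
<N>, Rg/Rg0, d_Bragg and the shape label.  Two modes:

* ``analytic`` - no dynamics; only the stoichiometric columns are filled
  (instant, useful for planning and for validating the charge bookkeeping);
* ``dynamics`` - reduced-scale runs per point (desk preset sizes), each
  started from an intercalated stack and relaxed at 298 K.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import fixtures, observables
from .integrate import RunConfig, anneal_fixture, run_simulation
from .topology import spec_for_variant, stoichiometric_ratio

SUMMARY_COLUMNS = ["np", "beta", "beta_c", "mean_n", "rg_norm", "d_bragg", "shape"]


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def sweep_state_diagram(
    variant: str = "S.I",
    np_range: Sequence[int] = range(1, 17),
    output_dir: Optional[Union[str, Path]] = None,
    mode: str = "analytic",
    seed: int = 0,
    n_beads: Optional[int] = None,
    bead_charge: Optional[float] = None,
    k_theta: Optional[float] = None,
    box_length: float = 30.0,
    n_shells: int = 5,
    anneal_steps: int = 10_000,
    production_steps: int = 30_000,
) -> pd.DataFrame:
    """Run or analyse the platelet-number series and emit the summary table.

    An empty ``np_range`` yields an empty table.  In dynamics mode the
    undisturbed-chain reference Rg0 is computed once from a platelet-free
    run of the same chain.
    """
    if mode not in ("analytic", "dynamics"):
        raise ValueError("mode must be 'analytic' or 'dynamics'")
    np_range = list(np_range)
    rows = []
    rg0 = None
    if mode == "dynamics" and np_range:
        rg0 = _reference_rg0(
            variant, n_beads, bead_charge, k_theta, box_length, seed, production_steps
        )
    for i, n_p in enumerate(np_range):
        spec = spec_for_variant(
            variant, n_nps=n_p, n_beads=n_beads, bead_charge=bead_charge,
            k_theta=k_theta, box_length=box_length, n_shells=n_shells,
        )
        zp = spec.np_topology.net_charge
        beta = stoichiometric_ratio(
            n_p, zp, spec.pe_topology.n_beads, spec.pe_topology.bead_charge
        ) if n_p > 0 else 0.0
        row = {c: np.nan for c in SUMMARY_COLUMNS}
        row.update({"np": n_p, "beta": beta, "shape": ""})
        if mode == "dynamics" and n_p > 0:
            row.update(
                _dynamics_point(spec, seed + 1000 * i, anneal_steps, production_steps, rg0)
            )
        rows.append(row)
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "variant": variant, "np_range": np_range, "mode": mode, "seed": seed,
            "n_beads": n_beads, "bead_charge": bead_charge, "k_theta": k_theta,
            "box_length": box_length, "n_shells": n_shells,
        }
        path = output_dir / "summary.csv"
        with open(path, "w") as fh:
            fh.write(f"# tactoid state-diagram sweep; seed={seed}; config_hash={_config_hash(payload)}\n")
            table.to_csv(fh, index=False)
    return table


def _reference_rg0(variant, n_beads, bead_charge, k_theta, box_length, seed, n_steps) -> float:
    """Rg of the undisturbed chain (no platelets), same force field."""
    spec = spec_for_variant(
        variant, n_nps=0, n_beads=n_beads, bead_charge=bead_charge,
        k_theta=k_theta, box_length=box_length,
    )
    from .topology import build_state

    state = build_state(spec, seed=seed)
    cfg = RunConfig(n_steps=n_steps, seed=seed, output_stride=500, thermostat_coupling_ps=0.1)
    traj = run_simulation(state, cfg)
    return observables.radius_of_gyration(traj, equilibration_fraction=0.3).rg


def _dynamics_point(spec, run_seed, anneal_steps, production_steps, rg0) -> dict:
    _, state = fixtures.intercalated_stack(spec=spec, spacing=3.0, seed=run_seed)
    cfg = RunConfig(seed=run_seed, output_stride=500, thermostat_coupling_ps=0.1)
    state = anneal_fixture(state, [(400.0, anneal_steps), (298.0, anneal_steps)], cfg)
    traj = run_simulation(
        state,
        RunConfig(n_steps=production_steps, seed=run_seed + 1, output_stride=500,
                  thermostat_coupling_ps=0.1),
    )
    comp = observables.complexation_probability(traj, equilibration_fraction=0.3)
    gyr = observables.radius_of_gyration(traj, rg0=rg0, equilibration_fraction=0.3)
    sites = traj.state_at(0).site_indices
    d_bragg = np.nan
    if len(sites) >= 2:
        gr = observables.rdf(traj, selection=sites, bin_width=0.02, equilibration_fraction=0.3)
        sf = observables.structure_factor_windowed(
            gr, n_sites=len(sites), volume=traj.box_length**3, r_cut=traj.box_length / 2
        )
        d = observables.bragg_dspacing(sf)
        d_bragg = np.nan if d is None else d
    shape = observables.classify_shape(traj)
    return {
        "beta_c": comp.beta_c,
        "mean_n": comp.mean_complexed,
        "rg_norm": gyr.normalized,
        "d_bragg": d_bragg,
        "shape": shape.label,
    }
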