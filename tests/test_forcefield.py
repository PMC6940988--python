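"""Pair potentials, analytic forces and electrostatics routes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tactoid import (
    InteractionParams,
    angle_energy,
    bjerrum_length,
    bond_energy,
    coulomb_pair,
    tlj_pair,
    total_energy_forces,
)
from tactoid.forcefield import ForceEvaluator
from tactoid.state import SystemState

from .conftest import make_state
from .oracles import ewald_reference, numerical_gradient


class TestPairPotentials:
    def test_bjerrum_length_from_physical_constants(self):
        # e^2 / (4 pi eps0 eps_r kB T) at 298 K, eps_r = 78.3
        assert bjerrum_length(298.0, 78.3) == pytest.approx(0.716, abs=0.002)

    def test_unit_charges_at_bjerrum_length_interact_with_kbt(self):
        lb = bjerrum_length()
        assert coulomb_pair(1, 1, lb) == pytest.approx(1.0)

    def test_coulomb_sign_symmetry(self):
        assert coulomb_pair(1, -1, 1.0) == pytest.approx(-bjerrum_length())
        assert coulomb_pair(-1, -1, 1.0) == pytest.approx(coulomb_pair(1, 1, 1.0))

    def test_coulomb_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            coulomb_pair(1, 1, 0.0)

    def test_tlj_vanishes_at_and_beyond_contact(self):
        assert tlj_pair(1.0, 1.0) == 0.0
        assert tlj_pair(2.0, 1.0) == 0.0
        # continuity approaching contact from below
        assert tlj_pair(1.0 - 1e-9, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_tlj_inside_contact(self):
        expected = (1 / 0.9) ** 12 - 2 * (1 / 0.9) ** 6 + 1  # direct evaluation
        assert tlj_pair(0.9, 1.0, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.777353, abs=1e-6)

    @settings(deadline=None, max_examples=100)
    @given(
        r=st.floats(0.01, 5.0),
        sigma=st.floats(0.1, 2.0),
    )
    def test_tlj_is_strictly_repulsive(self, r, sigma):
        u = tlj_pair(r, sigma)
        assert u >= 0.0
        if r >= sigma:
            assert u == 0.0

    def test_bond_closed_forms(self):
        assert bond_energy(0.5, 0.5, 500.0) == 0.0
        assert bond_energy(0.6, 0.5, 500.0) == pytest.approx(2.5)
        assert bond_energy(7.7, 0.5, 0.0) == 0.0

    def test_angle_closed_forms(self):
        assert angle_energy(math.pi, 40.0) == 0.0
        assert angle_energy(math.pi / 2, 40.0) == pytest.approx(20.0 * (math.pi / 2) ** 2)
        assert angle_energy(1.0, 0.0) == 0.0

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            angle_energy(3.5, 1.0)


def _random_bonded_state(seed, n=12, box=10.0):
    """Charged cluster with bonds and angles, no hard overlaps."""
    rng = np.random.default_rng(seed)
    pos = np.array([[5.0, 5.0, 5.0]])
    while len(pos) < n:
        trial = pos[rng.integers(len(pos))] + rng.normal(scale=0.8, size=3)
        if np.min(np.linalg.norm(pos - trial, axis=1)) > 0.55:
            pos = np.vstack([pos, trial])
    charges = np.array([1.0, -1.0] * (n // 2))
    idx = np.arange(5)
    return SystemState(
        positions=pos,
        charges=charges,
        diameters=np.full(n, 0.5),
        species=np.full(n, 2),
        molecule=np.arange(n),
        box_length=box,
        bonds=np.column_stack([idx[:-1], idx[1:]]),
        bond_r0=np.full(4, 0.6),
        bond_k=np.full(4, 120.0),
        angles=np.column_stack([idx[:-2], idx[1:-1], idx[2:]]),
        angle_k=np.full(3, 35.0),
    )


class TestForcesAndMethods:
    @pytest.mark.parametrize("method", ["bruteforce_minimum_image", "cutoff", "ewald"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_forces_match_numerical_gradient(self, method, seed):
        state = _random_bonded_state(seed)
        params = InteractionParams(coulomb_cutoff=4.0, ewald_accuracy=1e-8)
        ev = ForceEvaluator(state, params, method)
        rep = ev(state.positions)
        grad = numerical_gradient(lambda p: ev(p).total, state.positions, h=2e-6)
        scale = max(np.abs(rep.forces).max(), 1.0)
        assert np.abs(rep.forces + grad).max() / scale < 1e-5

    @pytest.mark.parametrize("method", ["bruteforce_minimum_image", "cutoff", "ewald"])
    def test_net_force_vanishes(self, method):
        state = _random_bonded_state(3)
        rep = total_energy_forces(state, InteractionParams(coulomb_cutoff=4.0), method)
        assert np.abs(rep.forces.sum(axis=0)).max() < 1e-8

    def test_energy_invariant_under_index_exchange(self):
        state = _random_bonded_state(4)
        perm = np.arange(state.n_particles)[::-1].copy()
        inv = np.argsort(perm)
        swapped = SystemState(
            positions=state.positions[perm],
            charges=state.charges[perm],
            diameters=state.diameters[perm],
            species=state.species[perm],
            molecule=state.molecule[perm],
            box_length=state.box_length,
            bonds=inv[state.bonds],
            bond_r0=state.bond_r0,
            bond_k=state.bond_k,
            angles=inv[state.angles],
            angle_k=state.angle_k,
        )
        r1 = total_energy_forces(state)
        r2 = total_energy_forces(swapped)
        assert r1.total == pytest.approx(r2.total, rel=1e-12)
        assert np.allclose(r1.forces[perm], r2.forces)

    def test_cutoff_equals_minimum_image_when_all_pairs_inside(self):
        state = _random_bonded_state(5, box=40.0)  # cluster ~ few nm wide
        params = InteractionParams(coulomb_cutoff=19.0)
        r1 = total_energy_forces(state, params, "bruteforce_minimum_image")
        r2 = total_energy_forces(state, params, "cutoff")
        assert r1.total == r2.total
        assert np.array_equal(r1.forces, r2.forces)

    def test_single_pair_of_unit_charges(self):
        lb = bjerrum_length()
        state = make_state([[5, 5, 5], [5 + lb, 5, 5]], charges=[1, 1], box_length=50.0)
        rep = total_energy_forces(state)
        assert rep.total == pytest.approx(1.0)
        assert np.allclose(rep.forces[0], -rep.forces[1])
        assert rep.forces[0][0] < 0  # repulsion pushes them apart

    def test_straight_chain_reference_geometry_is_strain_free(self):
        from tactoid.fixtures import free_chain

        state = free_chain(n_beads=20, straight=True, k_theta=150.0)
        rep = total_energy_forces(state)
        assert rep.bond == pytest.approx(0.0, abs=1e-20)
        assert rep.angle == pytest.approx(0.0, abs=1e-16)

    def test_nan_positions_rejected(self):
        state = _random_bonded_state(6)
        state.positions[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            total_energy_forces(state)

    def test_outside_box_positions_are_wrapped(self):
        lb = bjerrum_length()
        a = make_state([[5, 5, 5], [5 + lb, 5, 5]], charges=[1, 1], box_length=50.0)
        b = make_state([[55, 5, 5], [5 + lb, 105, 5]], charges=[1, 1], box_length=50.0)
        assert total_energy_forces(a).total == pytest.approx(total_energy_forces(b).total)


class TestEwald:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_reference_sum(self, seed):
        """Production Ewald vs a naive loop-based sum at different alpha."""
        rng = np.random.default_rng(seed)
        n, box = 20, 6.0
        pos = rng.uniform(0, box, (n, 3))
        q = np.array([1.0, -1.0] * (n // 2))
        state = make_state(pos, charges=q, diameters=np.full(n, 0.01), box_length=box)
        params = InteractionParams(coulomb_cutoff=2.9, ewald_accuracy=1e-7)
        ours = total_energy_forces(state, params, "ewald").electrostatic
        ref = ewald_reference(pos, q, box, bjerrum_length(), alpha=1.8, n_kmax=14)
        assert ours == pytest.approx(ref, rel=1e-4)

    def test_alpha_independence_of_internal_sum(self):
        rng = np.random.default_rng(9)
        n, box = 16, 7.0
        pos = rng.uniform(0, box, (n, 3))
        q = np.array([1.0, -1.0] * (n // 2))
        state = make_state(pos, charges=q, diameters=np.full(n, 0.01), box_length=box)
        e1 = total_energy_forces(state, InteractionParams(coulomb_cutoff=3.4, ewald_accuracy=1e-6), "ewald")
        e2 = total_energy_forces(state, InteractionParams(coulomb_cutoff=2.4, ewald_accuracy=1e-9), "ewald")
        assert e1.electrostatic == pytest.approx(e2.electrostatic, rel=1e-5)

    def test_excluded_pairs_carry_no_coulomb_energy(self):
        """A bonded +/- pair contributes nothing electrostatic in any route."""
        pos = np.array([[3.0, 3.0, 3.0], [3.6, 3.0, 3.0]])
        q = np.array([1.0, -1.0])
        bonded = SystemState(
            positions=pos, charges=q, diameters=np.full(2, 0.01),
            species=np.full(2, 2), molecule=np.zeros(2, dtype=int), box_length=6.0,
            bonds=np.array([[0, 1]]), bond_r0=np.array([0.6]), bond_k=np.array([0.0]),
        )
        ref = ewald_reference(pos, q, 6.0, bjerrum_length(), alpha=1.8, n_kmax=14,
                              excluded_pairs=[(0, 1)])
        ours = total_energy_forces(bonded, InteractionParams(coulomb_cutoff=2.9, ewald_accuracy=1e-7), "ewald")
        assert ours.electrostatic == pytest.approx(ref, rel=1e-4)
        assert total_energy_forces(bonded).electrostatic == 0.0

    def test_non_neutral_system_rejected(self):
        state = make_state([[1, 1, 1], [2, 2, 2]], charges=[1.0, 0.0], box_length=6.0)
        with pytest.raises(ValueError, match="neutral"):
            total_energy_forces(state, InteractionParams(coulomb_cutoff=2.9), "ewald")


def test_force_check_report_summarises_gradient_agreement():
    from tactoid.forcefield import force_check_report

    state = _random_bonded_state(8, n=6)
    text = force_check_report(state)
    assert "force check" in text
    # the reported relative error reflects the analytic/numerical agreement
    rel = float(text.splitlines()[2].split("relative")[1].strip(" )"))
    assert rel < 1e-5
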