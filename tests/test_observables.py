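"""Structural observables: closed forms, fixture recovery, classification."""

import math

import numpy as np
import pandas as pd
import pytest

from tactoid import (
    bragg_dspacing,
    classify_shape,
    complexation_probability,
    default_contact_threshold,
    default_q_grid,
    kratky_transform,
    radius_of_gyration,
    rdf,
    structure_factor_direct,
    structure_factor_windowed,
)
from tactoid.fixtures import band, free_chain, ideal_stack, two_site, _merge_states
from tactoid.observables import StructureFactorResult
from tactoid.state import BEAD, SITE, SystemState

from .conftest import make_state
from .oracles import rod_rg_direct


def _sites_and_beads(site_pos, bead_pos, box=30.0):
    n_s, n_b = len(site_pos), len(bead_pos)
    return SystemState(
        positions=np.vstack([site_pos, bead_pos]),
        charges=np.concatenate([np.full(n_s, -1.0), np.ones(n_b)]),
        diameters=np.concatenate([np.ones(n_s), np.full(n_b, 0.4)]),
        species=np.concatenate([np.full(n_s, SITE), np.full(n_b, BEAD)]),
        molecule=np.concatenate([np.zeros(n_s, dtype=int), np.ones(n_b, dtype=int)]),
        box_length=box,
    )


class TestComplexation:
    def test_default_threshold_is_contact_plus_margin(self):
        # R_site + R_bead + 0.7 = 0.5 + 0.2 + 0.7
        assert default_contact_threshold() == pytest.approx(1.4)

    def test_bead_within_threshold_is_always_complexed(self):
        state = _sites_and_beads([[10, 10, 10]], [[11, 10, 10], [15, 15, 15]])
        res = complexation_probability(state)
        assert res.pc_per_bead[0] == 1.0
        assert res.pc_per_bead[1] == 0.0
        assert res.mean_complexed == 1.0

    def test_distant_beads_never_complexed(self):
        state = _sites_and_beads([[10, 10, 10]], [[13, 10, 10], [10, 14, 10]])
        res = complexation_probability(state)
        assert np.all(res.pc_per_bead == 0)
        assert res.mean_complexed == 0.0
        assert res.beta_c == 0.0

    def test_minimum_image_contact_across_boundary(self):
        state = _sites_and_beads([[0.2, 10, 10]], [[29.8, 10, 10]], box=30.0)
        res = complexation_probability(state)
        assert res.pc_per_bead[0] == 1.0

    def test_empty_system_rejected(self):
        chain = free_chain(n_beads=5)
        with pytest.raises(ValueError):
            complexation_probability(chain)


class TestGyration:
    @pytest.mark.parametrize("n", [3, 10, 50])
    def test_straight_rod_closed_form(self, n):
        b = 0.5
        chain = free_chain(n_beads=n, straight=True, box_length=60.0)
        res = radius_of_gyration(chain, selection=np.arange(n))
        expected = math.sqrt(b**2 * (n**2 - 1) / 12.0)
        assert res.rg == pytest.approx(expected, rel=1e-12)
        assert res.rg == pytest.approx(rod_rg_direct(n, b), rel=1e-12)

    def test_coincident_points_have_zero_rg(self):
        state = make_state(np.zeros((4, 3)) + 5.0)
        res = radius_of_gyration(state, selection=np.arange(4), chain_unwrap=False)
        assert res.rg == pytest.approx(0.0, abs=1e-12)

    def test_self_normalisation_is_unity(self):
        chain = free_chain(n_beads=20, straight=False, seed=3)
        res = radius_of_gyration(chain, selection=np.arange(20))
        res2 = radius_of_gyration(chain, selection=np.arange(20), rg0=res.rg)
        assert res2.normalized == pytest.approx(1.0)

    def test_unwrap_across_periodic_boundary(self):
        # straight rod crossing the box edge must keep its true Rg
        n, b, box = 20, 0.5, 10.0
        x = (np.arange(n) * b + box - 2.0) % box
        pos = np.column_stack([x, np.full(n, 5.0), np.full(n, 5.0)])
        state = make_state(pos, box_length=box)
        res = radius_of_gyration(state, selection=np.arange(n))
        assert res.rg == pytest.approx(rod_rg_direct(n, b), rel=1e-12)

    def test_empty_selection_rejected(self):
        chain = free_chain(n_beads=5)
        with pytest.raises(ValueError):
            radius_of_gyration(chain, selection=np.array([], dtype=int))


class TestRdf:
    def test_ideal_gas_is_unity(self, rng):
        """Uniform random points give g(r) = 1 within sampling error."""
        n, box = 1500, 20.0
        state = make_state(rng.uniform(0, box, (n, 3)), box_length=box)
        table = rdf(state, selection=np.arange(n), bin_width=0.5)
        inner = table[table.r > 1.0]  # skip poorly-sampled innermost bins
        assert np.abs(inner.g - 1.0).mean() < 0.05
        assert np.all(table.g >= 0)

    def test_two_sites_single_bin(self):
        state = two_site(distance=2.2)
        table = rdf(state, selection=np.array([0, 1]), bin_width=0.1)
        nonzero = table[table.g > 0]
        assert len(nonzero) == 1
        assert abs(nonzero.r.iloc[0] - 2.2) <= 0.05

    def test_invalid_bin_width_rejected(self):
        state = two_site()
        with pytest.raises(ValueError):
            rdf(state, bin_width=0.0)

    def test_r_max_beyond_half_box_rejected(self):
        state = two_site(box_length=10.0)
        with pytest.raises(ValueError):
            rdf(state, r_max=6.0)


class TestStructureFactor:
    def test_single_site_is_unity(self):
        state = make_state([[5.0, 5.0, 5.0]], diameters=[1.0], box_length=20.0)
        state.species[:] = SITE
        sf = structure_factor_direct(state)
        assert np.allclose(sf.s_values, 1.0)

    def test_two_sites_closed_form(self):
        d = 2.2
        state = two_site(distance=d)
        q = np.linspace(0.1, 10, 300)
        sf = structure_factor_direct(state, q_grid=q)
        expected = 1.0 + np.sin(q * d) / (q * d)
        assert np.allclose(sf.s_values, expected, atol=1e-12)

    def test_low_q_limit_of_pair(self):
        state = two_site(distance=2.2)
        sf = structure_factor_direct(state, q_grid=np.array([1e-8]))
        assert sf.s_values[0] == pytest.approx(2.0)

    def test_windowed_of_flat_gr_is_unity(self):
        r = np.arange(0.01, 10.0, 0.01)
        table = pd.DataFrame({"r": r, "g": np.ones_like(r)})
        sf = structure_factor_windowed(table, n_sites=100, volume=8000.0, r_cut=10.0)
        assert np.allclose(sf.s_values, 1.0, atol=1e-12)

    def test_windowed_route_matches_direct_on_stack(self):
        """g(r)-quadrature S_w agrees with the direct double sum at high q.

        For an isolated cluster g(r) never reaches 1, so the plain
        truncated transform carries a finite-box artifact; the window
        suppresses it, leaving a residual that shrinks as the box grows.
        In a box comfortably larger than the cluster the two routes agree
        to 2% of the S(q) scale for q >> 2 pi / Rc.
        """
        box = 80.0
        st = ideal_stack(n_platelets=4, spacing=2.2, box_length=box)
        sel = np.arange(st.n_particles)
        q = np.geomspace(1.0, 15.0, 120)
        direct = structure_factor_direct(st, q_grid=q)
        gr = rdf(st, selection=sel, bin_width=0.005)
        windowed = structure_factor_windowed(
            gr, n_sites=len(sel), volume=box**3, r_cut=box / 2, q_grid=q
        )
        mask = q > 2.0  # q Rc ~ 80 >> 1
        err = np.abs(windowed.s_values[mask] - direct.s_values[mask])
        assert err.max() / np.abs(direct.s_values[mask]).max() < 0.02

    def test_window_becomes_identity_at_large_cutoff(self):
        """With Rc -> large the window converges to the plain transform."""
        rng = np.random.default_rng(0)
        r = np.arange(0.005, 50.0, 0.005)
        g = 1.0 + np.exp(-((r - 2.0) ** 2) / 0.02) * 0.5  # short-ranged feature
        table = pd.DataFrame({"r": r, "g": g})
        q = np.geomspace(0.5, 10, 50)
        sw = structure_factor_windowed(table, 100, 1000.0, r_cut=49.9, q_grid=q)
        # plain (unwindowed) quadrature of the isotropic transform
        rho = 100 / 1000.0
        plain = 1.0 + 4.0 * np.pi * rho * np.trapezoid(
            (g - 1.0)[None, :] * r[None, :] ** 2 * np.sinc(np.outer(q, r) / np.pi), r, axis=1
        )
        assert np.allclose(sw.s_values, plain, atol=2e-3)


class TestBragg:
    def test_synthetic_peak_position(self):
        q = np.linspace(2.0, 4.0, 501)  # step 0.004 -> includes 2.856 exactly
        s = 1.0 + np.exp(-((q - 2.856) ** 2) / 0.01)
        sf = StructureFactorResult(q_grid=q, s_values=s)
        d = bragg_dspacing(sf)
        assert d == pytest.approx(2.200, abs=5e-4)
        assert sf.qmax == pytest.approx(2.856)

    @pytest.mark.parametrize("d", [1.5, 2.0, 2.2, 2.9, 3.5])
    def test_ideal_stack_recovery_within_grid_step(self, d):
        st = ideal_stack(n_platelets=6, spacing=d, box_length=40.0)
        q = default_q_grid(40.0)
        sf = structure_factor_direct(st, q_grid=q)
        window = (2.0 * np.pi / (d + 0.8), 2.0 * np.pi / (d - 0.5))
        rec = bragg_dspacing(sf, q_window=window)
        assert rec is not None
        qd = 2.0 * np.pi / d
        idx = np.argmin(np.abs(q - qd))
        grid_step = q[min(idx + 1, len(q) - 1)] - q[idx - 1]
        assert abs(sf.qmax - qd) <= grid_step
        assert abs(rec - d) <= abs(2.0 * np.pi / (qd - grid_step) - d) + 1e-9

    def test_monotonic_curve_has_no_peak(self):
        q = np.linspace(2.0, 4.0, 100)
        sf = StructureFactorResult(q_grid=q, s_values=1.0 / q)
        assert bragg_dspacing(sf) is None
        assert sf.qmax is None


class TestKratky:
    def test_flat_s_gives_q_squared(self):
        q = np.linspace(0.0, 5.0, 51)
        sf = StructureFactorResult(q_grid=q, s_values=np.ones_like(q))
        table = kratky_transform(sf)
        assert np.allclose(table.q2s, q**2)
        assert table.q2s.iloc[0] == 0.0  # q = 0 row

    def test_transform_is_invertible(self):
        q = np.linspace(0.5, 5.0, 40)
        s = 1.0 + np.sin(q)
        sf = StructureFactorResult(q_grid=q, s_values=s)
        table = kratky_transform(sf)
        assert np.allclose(table.q2s / q**2, s)


class TestShapeClassifier:
    def test_intercalated_stack_is_compact(self):
        from tactoid.fixtures import intercalated_stack

        _, state = intercalated_stack(spacing=2.4, seed=0)
        res = classify_shape(state)
        assert res.label == "compact_stack"
        assert res.metrics["median_nn_spacing"] < res.thresholds["stack_spacing_max"]

    def test_platelets_along_extended_chain_are_a_band(self):
        state = band(n_platelets=4, spacing=12.0)
        res = classify_shape(state)
        assert res.label == "extended_band"
        assert res.metrics["n_complexed"] == 4

    def test_dispersed_uncomplexed_platelets_are_dissolved(self):
        platelets = band(n_platelets=3, spacing=15.0, box_length=60.0, include_chain=False)
        chain = free_chain(n_beads=10, box_length=60.0)
        chain.positions[:, 2] += 25.0  # move the chain far from every platelet
        state = _merge_states(platelets, chain)
        res = classify_shape(state)
        assert res.label == "dissolved"
        assert res.metrics["n_complexed"] == 0

    def test_chainless_tight_stack_classified_geometrically(self):
        st = ideal_stack(n_platelets=4, spacing=2.2)
        assert classify_shape(st).label == "compact_stack"
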