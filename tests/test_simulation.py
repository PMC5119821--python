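"""Coupled-lattice stepping: discrete operator, conservation, determinism."""

import numpy as np
import pytest

from fibroslab.lattice import (
    FibrosisSpec,
    LatticeGeometry,
    LinkField,
    build_link_field,
    uniform_link_field,
)
from fibroslab.model import FKParameters, MembraneState, reaction_step
from fibroslab.simulation import (
    SimulationConfig,
    StimulusSpec,
    coupling_term,
    run_simulation,
    step_tissue,
)

XI = 10.0  # 1/ms at D = 1 cm^2/s, dx = 100 um


class TestCouplingTerm:
    def test_uniform_field_gives_zero(self, rng):
        geom = LatticeGeometry(12, 10, 3)
        links = uniform_link_field(geom, 0.3, seed=5)
        V = np.full(geom.shape, 0.42)
        np.testing.assert_array_equal(coupling_term(V, links, XI), 0.0)

    def test_isolated_node_receives_nothing(self, rng):
        geom = LatticeGeometry(5, 5, 1)
        links = uniform_link_field(geom, 0.0)
        # cut all links incident to node (0, 2, 2)
        links.lx[0, 2, 1] = links.lx[0, 2, 2] = 0
        links.ly[0, 1, 2] = links.ly[0, 2, 2] = 0
        V = rng.random(geom.shape)
        c = coupling_term(V, links, XI)
        assert c[0, 2, 2] == 0.0

    def test_node_sum_vanishes_by_antisymmetry(self, rng):
        geom = LatticeGeometry(14, 9, 4)
        links = uniform_link_field(geom, 0.4, seed=8)
        V = rng.random(geom.shape)
        c = coupling_term(V, links, XI)
        assert abs(c.sum()) < 1e-10 * np.abs(c).sum()

    def test_consistency_with_continuum_laplacian(self):
        # smooth test field on a fully connected cable: xi * discrete operator
        # approximates D * V'' with O(dx^2) error
        geom = LatticeGeometry(400, 1, 1)
        links = uniform_link_field(geom, 0.0)
        L = geom.nx * geom.dx
        x = np.arange(geom.nx) * geom.dx
        V = np.sin(2 * np.pi * x / L).reshape(geom.shape)
        c = coupling_term(V, links, XI)
        D_ms = 1.0e-3  # cm^2/ms
        exact = -D_ms * (2 * np.pi / L) ** 2 * V
        interior = slice(1, -1)
        err = np.abs(c[0, 0, interior] - exact[0, 0, interior]).max()
        assert err < 1e-2 * np.abs(exact).max()

    def test_sum_V_conserved_under_pure_diffusion(self, rng):
        geom = LatticeGeometry(16, 16, 2)
        links = uniform_link_field(geom, 0.3, seed=11)
        V = rng.random(geom.shape)
        total0 = V.sum()
        for _ in range(200):
            V = V + 0.0165 * coupling_term(V, links, XI)
        assert V.sum() == pytest.approx(total0, abs=1e-9)


class TestStepTissue:
    def test_resting_slab_stays_resting(self):
        geom = LatticeGeometry(20, 20, 2)
        links = uniform_link_field(geom, 0.2, seed=3)
        tau = np.full(geom.shape, 0.25)
        V = np.zeros(geom.shape)
        v = np.ones(geom.shape)
        w = np.ones(geom.shape)
        V2, v2, w2 = step_tissue(V, v, w, links, tau, FKParameters(), 0.0165, XI, n_steps=60)
        assert np.abs(V2).max() < 1e-7  # ~60 steps of ~1e-9/ms drift
        assert (v2 == 1.0).all() and (w2 == 1.0).all()

    def test_kernel_matches_numpy_reference_step(self, rng):
        """One RK2 step of the fused kernel vs a plain numpy implementation.

        The kernel evaluates the slow-inward tanh from a lookup table
        (|error| < 2e-6), so agreement is tight but not bitwise.
        """
        geom = LatticeGeometry(13, 11, 3)
        links = uniform_link_field(geom, 0.35, seed=17)
        tau = np.full(geom.shape, 0.28)
        params = FKParameters(tau_d=0.28)
        V = rng.random(geom.shape)
        v = rng.random(geom.shape)
        w = rng.random(geom.shape)
        dt = 0.0165

        def derivs(s):
            from fibroslab.model import compute_currents, gate_derivatives

            st = MembraneState(*s)
            I_fi, I_so, I_si = compute_currents(st, params)
            dv, dw = gate_derivatives(st, params)
            dV = -(I_fi + I_so + I_si) + coupling_term(s[0], links, XI)
            return dV, dv, dw

        d1 = derivs((V, v, w))
        mid = tuple(a + 0.5 * dt * d for a, d in zip((V, v, w), d1))
        d2 = derivs(mid)
        expect = tuple(a + dt * d for a, d in zip((V, v, w), d2))

        got = step_tissue(V, v, w, links, tau, params, dt, XI, n_steps=1)
        for g, e in zip(got, expect):
            np.testing.assert_allclose(g, e, atol=5e-6)

    def test_two_half_steps_match_one_step_to_third_order(self):
        # RK2 local error is O(dt^3): halving dt twice should land ~8x closer
        geom = LatticeGeometry(10, 1, 1)
        links = uniform_link_field(geom, 0.0)
        tau = np.full(geom.shape, 0.25)
        params = FKParameters()
        V0 = np.linspace(0.2, 0.6, 10).reshape(geom.shape)
        v0 = np.full(geom.shape, 0.8)
        w0 = np.full(geom.shape, 0.9)

        def end(dt, n):
            return step_tissue(V0, v0, w0, links, tau, params, dt, XI, n_steps=n)[0]

        dt = 0.0165
        ref = end(dt / 8, 8)
        e1 = np.abs(end(dt, 1) - ref).max()
        e2 = np.abs(end(dt / 2, 2) - ref).max()
        assert e2 < e1 / 2.5  # comfortably better than first order


class TestRunSimulation:
    def test_deterministic_replay(self):
        geom = LatticeGeometry(40, 40, 2)
        fib = FibrosisSpec(phi=0.6, R0=0.1, border_width=0.0, tau_d_core=0.30, seed=21)
        config = SimulationConfig(geom=geom, fibrosis=fib, t_end=120.0,
                                  stimulus=StimulusSpec(radius=0.08))
        h1 = run_simulation(config)
        h2 = run_simulation(config)
        np.testing.assert_array_equal(h1.first_activation, h2.first_activation)
        np.testing.assert_array_equal(h1.activation_count, h2.activation_count)
        np.testing.assert_array_equal(h1.final_state[0], h2.final_state[0])

    def test_stability_guard(self):
        geom = LatticeGeometry(10, 10, 2)
        config = SimulationConfig(geom=geom, dt=0.02, t_end=10.0)
        with pytest.raises(ValueError, match="stability"):
            config.validate()

    def test_no_flux_reflection_symmetry(self):
        """A center stimulus on a homogeneous monolayer gives an arrival-time
        map symmetric under the lattice reflections."""
        geom = LatticeGeometry(41, 41, 1)
        config = SimulationConfig(
            geom=geom, t_end=80.0,
            stimulus=StimulusSpec(radius=0.05), early_stop=False,
        )
        # center the stimulus by hand: run with a custom mask via monkeypatched
        # corner is awkward; instead exploit corner symmetry: x<->y reflection
        hist = run_simulation(config)
        fa = hist.first_activation[0]
        np.testing.assert_allclose(fa, fa.T, atol=config.dt)

    def test_propagation_failure_is_labeled_not_raised(self):
        # stimulus fully enclosed by removed links cannot excite the rest
        geom = LatticeGeometry(30, 30, 1)
        links = uniform_link_field(geom, 0.0)
        links.lx[:, :, 9] = 0
        links.ly[:, 9, :10] = 0
        config = SimulationConfig(geom=geom, t_end=250.0, stimulus=StimulusSpec(radius=0.05))
        tau = np.full(geom.shape, 0.25)
        hist = run_simulation(config, links=links, tau_d_map=tau)
        outside_block = np.zeros(geom.shape, dtype=bool)
        outside_block[:, 10:, :] = True
        outside_block[:, :, 10:] = True
        assert not np.isfinite(hist.first_activation[outside_block]).any()
        assert hist.quiescent_at is not None

    def test_snapshot_cadence_and_early_stop(self):
        geom = LatticeGeometry(30, 30, 1)
        config = SimulationConfig(geom=geom, t_end=400.0, snapshot_every=2.0,
                                  stimulus=StimulusSpec(radius=0.05))
        hist = run_simulation(config)
        assert hist.quiescent_at is not None  # single wave dies long before 400 ms
        assert hist.snapshots.shape[0] == len(hist.snapshot_times)
        assert np.all(np.diff(hist.snapshot_times) > 0)
        assert hist.snapshot_times[-1] <= hist.quiescent_at
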