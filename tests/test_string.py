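"""String method: path ops, relaxation, reparameterization, convergence."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import root

from stalkpath import (
    ChemicalPotentialField,
    DensityField,
    GridSpec,
    StringConfig,
    StringMFEP,
    StringPath,
    allen_cahn_step,
    initialize_path,
    perpendicular_mu,
    reparameterize,
    replica_distances,
    run_string,
)
from stalkpath.string import DegeneratePathError, default_epsilon
from stalkpath.synthetic import (
    AnalyticFunctionalSpec,
    CurvedDoubleWellLandscape,
    make_analytic_provider,
)


def one_cell_grid():
    return GridSpec((1, 1, 1), (1.0, 1.0, 1.0))


def straight_path(grid, a_vals, b_vals, n):
    return initialize_path(
        DensityField(grid, a_vals), DensityField(grid, b_vals), n
    )


class TestInitializePath:
    def test_middle_replica_is_mean_field(self, small_grid, rng):
        a = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        b = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        p = initialize_path(a, b, 3)
        np.testing.assert_allclose(
            p.replicas[1].values, 0.5 * (a.values + b.values), rtol=1e-14
        )

    def test_identical_endpoints_give_constant_path(self, small_grid, rng):
        a = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        p = initialize_path(a, a.copy(), 5)
        for rep in p.replicas:
            np.testing.assert_array_equal(rep.values, a.values)

    def test_convex_combination_formula(self, small_grid, rng):
        a = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        b = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        n = 24
        p = initialize_path(a, b, n)
        for i, rep in enumerate(p.replicas):
            t = i / (n - 1)
            np.testing.assert_allclose(
                rep.values, (1 - t) * a.values + t * b.values, atol=1e-13
            )
        np.testing.assert_array_equal(p.replicas[0].values, a.values)
        np.testing.assert_array_equal(p.replicas[-1].values, b.values)

    def test_too_few_replicas_rejected(self, small_grid):
        a = DensityField.zeros(small_grid)
        with pytest.raises(ValueError):
            initialize_path(a, a, 2)


class TestAllenCahnStep:
    def test_zero_mu_leaves_path_unchanged(self, small_grid, rng):
        a = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        b = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        p = initialize_path(a, b, 5)
        mu = [ChemicalPotentialField(small_grid, np.zeros(small_grid.shape))
              for _ in range(5)]
        q = allen_cahn_step(p, mu, StringConfig(epsilon=0.1))
        np.testing.assert_array_equal(p.stacked(), q.stacked())

    def test_geometric_convergence_on_quadratic_landscape(self):
        """Scalar recursion m_{k+1} - m* = (1 - eps*a)(m_k - m*)."""
        g = one_cell_grid()
        a, m_star, eps = 2.0, 3.0, 0.1
        provider = make_analytic_provider(
            AnalyticFunctionalSpec(g, family="quadratic", a=a, m1=m_star)
        )
        cfg = StringConfig(epsilon=eps, clip_negative=False)
        m = 5.0
        for _ in range(10):
            path = StringPath(
                [DensityField(g, np.full(g.shape, v)) for v in (m, m, m)]
            )
            mu = [provider.mu(r) for r in path.replicas]
            path = allen_cahn_step(path, mu, cfg)
            m_new = path.replicas[1].values[0, 0, 0]
            assert (m_new - m_star) == pytest.approx(
                (1 - eps * a) * (m - m_star), rel=1e-12
            )
            m = m_new

    def test_matches_elementwise_loop(self, small_grid, rng):
        reps = [DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
                for _ in range(4)]
        p = StringPath(reps)
        mu = [ChemicalPotentialField(small_grid,
                                     rng.normal(0, 1, small_grid.shape))
              for _ in range(4)]
        eps = 0.05
        q = allen_cahn_step(p, mu, StringConfig(epsilon=eps,
                                                clip_negative=False))
        for r_old, m, r_new in zip(p.replicas, mu, q.replicas):
            np.testing.assert_array_equal(
                r_new.values, r_old.values - eps * m.values
            )

    def test_negative_clipping(self, small_grid):
        p = StringPath([DensityField.zeros(small_grid) for _ in range(3)])
        mu = [ChemicalPotentialField(small_grid, np.ones(small_grid.shape))
              for _ in range(3)]
        q = allen_cahn_step(p, mu, StringConfig(epsilon=1.0, clip_negative=True))
        assert (q.stacked() >= 0).all()

    def test_pinned_endpoints_do_not_move(self, small_grid, rng):
        reps = [DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
                for _ in range(4)]
        p = StringPath(reps)
        mu = [ChemicalPotentialField(small_grid, np.ones(small_grid.shape))
              for _ in range(4)]
        q = allen_cahn_step(p, mu, StringConfig(epsilon=0.5,
                                                endpoint_mode="pinned"))
        np.testing.assert_array_equal(q.replicas[0].values, reps[0].values)
        np.testing.assert_array_equal(q.replicas[-1].values, reps[-1].values)
        assert not np.array_equal(q.replicas[1].values, reps[1].values)


class TestReplicaDistances:
    def test_linear_path_equally_spaced(self, small_grid, rng):
        a = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        b = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        d = replica_distances(initialize_path(a, b, 9))
        np.testing.assert_allclose(d, np.full(8, 1 / 8), rtol=1e-12)

    def test_two_replicas_single_unit_segment(self, small_grid, rng):
        a = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        b = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        d = replica_distances(StringPath([a, b]))
        assert d == pytest.approx([1.0])

    def test_matches_hand_normalized_segments(self, small_grid, rng):
        reps = [DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
                for _ in range(5)]
        p = StringPath(reps)
        seg = [
            np.sqrt(((reps[i + 1].values - reps[i].values) ** 2).sum())
            for i in range(4)
        ]
        expect = np.array(seg) / np.sum(seg)
        np.testing.assert_allclose(replica_distances(p), expect, rtol=1e-12)
        assert replica_distances(p).sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_path_raises(self, small_grid):
        a = DensityField.zeros(small_grid)
        with pytest.raises(DegeneratePathError):
            replica_distances(StringPath([a.copy(), a.copy(), a.copy()]))


class TestReparameterize:
    def test_uniform_path_is_fixed_point(self, small_grid, rng):
        a = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        b = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        p = initialize_path(a, b, 11)
        q = reparameterize(p)
        np.testing.assert_allclose(q.stacked(), p.stacked(), atol=1e-10)

    def test_clustered_path_becomes_uniform(self, small_grid, rng):
        a = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        b = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        n = 15
        # replicas clustered near the start: t = u^3
        ts = np.linspace(0, 1, n) ** 3
        reps = [DensityField(small_grid,
                             (1 - t) * a.values + t * b.values) for t in ts]
        q = reparameterize(StringPath(reps))
        d = replica_distances(q)
        assert np.abs(d * (n - 1) - 1).max() < 1e-3
        assert d.sum() == pytest.approx(1.0, abs=1e-12)
        # endpoints bit-identical
        assert np.array_equal(q.replicas[0].values, reps[0].values)
        assert np.array_equal(q.replicas[-1].values, reps[-1].values)

    def test_straight_segment_matches_closed_form_arc_length(self):
        """On a straight path the exact uniform redistribution is linear
        interpolation between the endpoints."""
        g = GridSpec((1, 1, 2), (1.0, 1.0, 2.0))
        a = np.array([[[0.0, 0.0]]])
        b = np.array([[[3.0, 4.0]]])
        n = 9
        ts = np.linspace(0, 1, n) ** 2
        reps = [DensityField(g, (1 - t) * a + t * b) for t in ts]
        q = reparameterize(StringPath(reps))
        for i, rep in enumerate(q.replicas):
            t = i / (n - 1)
            np.testing.assert_allclose(
                rep.values, (1 - t) * a + t * b, atol=1e-3
            )


class TestPerpendicularMu:
    def test_mu_parallel_to_tangent_projects_to_zero(self, small_grid, rng):
        a = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        b = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        p = initialize_path(a, b, 7)
        tangent = b.values - a.values  # straight path: tangent everywhere
        mu = [ChemicalPotentialField(small_grid, 2.5 * tangent)
              for _ in range(7)]
        perp = perpendicular_mu(p, mu)
        for m in perp:
            np.testing.assert_allclose(m.values, 0.0, atol=1e-9)

    def test_orthogonal_mu_unchanged(self, small_grid, rng):
        a = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        b = DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
        p = initialize_path(a, b, 7)
        tangent = (b.values - a.values).ravel()
        v = rng.normal(0, 1, tangent.shape)
        v -= tangent * (v @ tangent) / (tangent @ tangent)
        mu = [ChemicalPotentialField(small_grid, v.reshape(small_grid.shape))
              for _ in range(7)]
        perp = perpendicular_mu(p, mu)
        for m in perp:
            np.testing.assert_allclose(m.values, mu[0].values, atol=1e-9)

    def test_result_is_orthogonal_to_tangent(self, small_grid, rng):
        from stalkpath.string import path_tangents

        reps = [DensityField(small_grid, rng.uniform(0, 5, small_grid.shape))
                for _ in range(6)]
        p = StringPath(reps)
        mu = [ChemicalPotentialField(small_grid,
                                     rng.normal(0, 1, small_grid.shape))
              for _ in range(6)]
        perp = perpendicular_mu(p, mu)
        tans = path_tangents(p)
        for m, t in zip(perp, tans):
            ip = float(m.values.ravel() @ t)
            scale = np.linalg.norm(t) * np.linalg.norm(m.values)
            assert abs(ip) <= 1e-10 * max(scale, 1.0)


class CurvedOracle:
    """Damped-Newton saddle of the curved double-well, independent of the
    string implementation."""

    def __init__(self, land):
        self.land = land

    def saddle(self):
        sol = root(lambda v: self.land.grad_xy(*v), x0=[0.15, 0.05], tol=1e-13)
        assert sol.success
        return sol.x


class TestRunString:
    def test_converges_through_saddle_of_curved_double_well(self):
        land = CurvedDoubleWellLandscape(c=2.0)
        a, b = land.minima
        cfg = StringConfig(epsilon=0.05, max_iterations=3000, tol_disp=1e-7,
                           tol_F=1e-9, clip_negative=False)
        res = StringMFEP(land, start=land.field_from_xy(*a),
                         end=land.field_from_xy(*b), n_replicas=25,
                         config=cfg).fit()
        assert res.converged
        saddle = CurvedOracle(land).saddle()
        xy = land.xy_from_field(res.field_at(res.s_barrier))
        np.testing.assert_allclose(xy, saddle, atol=1e-3)
        barrier_oracle = land.f_xy(*saddle) - land.f_xy(*a)
        assert res.barrier == pytest.approx(barrier_oracle, rel=1e-3)

    def test_ginzburg_landau_barrier_matches_constrained_scan(self):
        """Uniform-phase path of a 20-cell double-well functional: the
        barrier equals the dense scan over the interpolation coordinate."""
        g = GridSpec((1, 1, 20), (1.0, 1.0, 20.0))
        spec = AnalyticFunctionalSpec(g, family="double_well", a=0.05,
                                      m1=0.0, m2=5.0)
        provider = make_analytic_provider(spec)
        start = DensityField(g, np.full(g.shape, spec.m1))
        end = DensityField(g, np.full(g.shape, spec.m2))
        cfg = StringConfig(epsilon=0.1, max_iterations=2000, tol_disp=1e-7,
                           tol_F=1e-10, clip_negative=False)
        res = StringMFEP(provider, start=start, end=end, n_replicas=19,
                         config=cfg).fit()
        # oracle: explicit constrained scan along pointwise interpolation
        ms = np.linspace(spec.m1, spec.m2, 20001)
        f_scan = 20.0 * spec.a * (ms - spec.m1) ** 2 * (ms - spec.m2) ** 2
        barrier_oracle = f_scan.max() - f_scan[0]
        assert res.barrier == pytest.approx(barrier_oracle, rel=1e-3)

    def test_identical_endpoints_converge_immediately(self, rng):
        g = GridSpec((2, 2, 2), (1.0, 1.0, 1.0))
        provider = make_analytic_provider(
            AnalyticFunctionalSpec(g, family="quadratic", a=1.0, m1=2.0)
        )
        well = DensityField(g, np.full(g.shape, 2.0))
        path = StringPath([well.copy() for _ in range(4)])
        out, diag = run_string(path, provider, StringConfig(epsilon=0.1))
        assert len(diag) <= 2
        assert diag.attrs["converged"]
        assert diag["barrier"].abs().max() == 0.0

    def test_deterministic_diagnostics(self):
        land = CurvedDoubleWellLandscape()
        a, b = land.minima
        cfg = StringConfig(epsilon=0.05, max_iterations=40, tol_disp=1e-14,
                           tol_F=1e-14, clip_negative=False)
        runs = []
        for _ in range(2):
            p = initialize_path(land.field_from_xy(*a),
                                land.field_from_xy(*b), 11)
            path, diag = run_string(p, land, cfg)
            runs.append((path.stacked(), diag))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        pd.testing.assert_frame_equal(runs[0][1], runs[1][1])

    def test_free_energy_nonincreasing_under_relaxation(self):
        """With eps below the stability threshold, Allen-Cahn relaxation never
        raises any replica's free energy on the quadratic landscape."""
        g = one_cell_grid()
        provider = make_analytic_provider(
            AnalyticFunctionalSpec(g, family="quadratic", a=2.0, m1=1.0)
        )
        cfg = StringConfig(epsilon=0.4, clip_negative=False)  # eps < 2/a
        vals = [4.0, 3.0, 0.2]
        path = StringPath([DensityField(g, np.full(g.shape, v)) for v in vals])
        energies = [provider.free_energy(r) for r in path.replicas]
        for _ in range(20):
            mu = [provider.mu(r) for r in path.replicas]
            path = allen_cahn_step(path, mu, cfg)
            new = [provider.free_energy(r) for r in path.replicas]
            for e_new, e_old in zip(new, energies):
                assert e_new <= e_old + 1e-12
            energies = new

    def test_mu_perp_decreases_near_convergence(self):
        land = CurvedDoubleWellLandscape()
        a, b = land.minima
        cfg = StringConfig(epsilon=0.05, max_iterations=400, tol_disp=1e-10,
                           tol_F=1e-12, clip_negative=False)
        p = initialize_path(land.field_from_xy(*a), land.field_from_xy(*b), 15)
        _, diag = run_string(p, land, cfg)
        track = diag["max_mu_perp"].to_numpy()
        tail = track[-max(2, len(track) // 10):]
        # non-increasing up to the discretization floor of the residual
        assert (np.diff(tail) <= 1e-6 * track[0]).all()
        assert tail[-1] <= 0.2 * track[0]

    def test_default_epsilon_matches_protocol_constant(self):
        # eps*lambda/dV = 0.03 with lambda = kappa*dV/kBT => eps = 0.03 kBT/kappa
        from stalkpath import thermal_energy

        assert default_epsilon(50.0, 300.0) == pytest.approx(
            0.03 * thermal_energy(300.0) / 50.0, rel=1e-12
        )
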