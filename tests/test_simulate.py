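import numpy as np
import pytest
import scipy.sparse.linalg as spla

from voromesh import mesh as mm
from voromesh import simulate as sim

from conftest import make_chain

AB = {"tip": "B", "cyt": "A"}


def typed_chain(n, tip_first=True):
    chain = make_chain(n)
    for i in range(n):
        chain[i].type = "tip" if (i == 0 and tip_first) else "cyt"
    return chain


class TestBuildRhs:
    def test_all_blocked_rhs_is_zero(self, quad_mesh):
        for s in quad_mesh:
            s.type = "wall"
        model = sim.KineticModel(1.0, 1.0, 10.0, {"wall": "blocked"})
        rhs = sim.build_rhs(quad_mesh, model)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(rhs(0.0, y), np.zeros(4))

    def test_flux_antisymmetry_conserves_mass(self):
        chain = typed_chain(8, tip_first=False)
        model = sim.KineticModel(0.0, 0.0, 7.0, {"cyt": "A"})
        rhs = sim.build_rhs(chain, model)
        rng = np.random.default_rng(3)
        y = rng.uniform(0, 5, 8)
        assert np.dot(rhs.volumes, rhs(0.0, y)) == pytest.approx(0.0, abs=1e-12)

    def test_two_cell_source_term(self, two_cell_mesh):
        # unit areas, contact 1; B cell gets alpha, A cell no flux at C = 0
        two_cell_mesh[0].type = "tip"
        two_cell_mesh[1].type = "cyt"
        model = sim.KineticModel(0.1, 0.1, 50.0, AB, "paper_literal")
        rhs = sim.build_rhs(two_cell_mesh, model)
        np.testing.assert_allclose(rhs(0.0, np.zeros(2)), [0.1, 0.0])

    def test_missing_role_rejected(self, two_cell_mesh):
        two_cell_mesh[0].type = "mystery"
        model = sim.KineticModel(0.1, 0.1, 50.0, AB)
        with pytest.raises(KeyError):
            sim.build_rhs(two_cell_mesh, model)

    def test_distance_normalized_flux_scales_by_centroid_distance(self):
        # two 2x1 cells, centroid distance 2: w = S/d halves the literal flux
        seeds = mm.SeedSet([[1.0, 0.5], [3.0, 0.5]], (0, 0, 4, 1))
        wide = mm.compute_adjacency(mm.build_voronoi_mesh(seeds))
        for s in wide:
            s.type = "cyt"
        y = np.array([1.0, 0.0])
        dn = sim.build_rhs(
            wide, sim.KineticModel(0, 0, 1.0, {"cyt": "A"}, "distance_normalized")
        )
        lit = sim.build_rhs(wide, sim.KineticModel(0, 0, 1.0, {"cyt": "A"}, "paper_literal"))
        np.testing.assert_allclose(dn(0.0, y), lit(0.0, y) / 2.0)


class TestIntegrate:
    def test_uniform_state_stays_constant_without_reactions(self):
        chain = typed_chain(5, tip_first=False)
        rhs = sim.build_rhs(chain, sim.KineticModel(0, 0, 5.0, {"cyt": "A"}))
        traj = sim.integrate(rhs, np.full(5, 2.0), 10.0, atol=1e-12, rtol=1e-10)
        np.testing.assert_allclose(traj.final, 2.0, atol=1e-9)

    def test_mass_conserved_on_mesh(self):
        mesh = mm.compute_adjacency(
            mm.build_voronoi_mesh(mm.generate_hex_seeds((0, 0, 70, 70), 10.0))
        )
        for s in mesh:
            s.type = "cyt"
        rhs = sim.build_rhs(mesh, sim.KineticModel(0, 0, 50.0, {"cyt": "A"}))
        rng = np.random.default_rng(5)
        y0 = rng.uniform(0, 1, len(mesh))
        traj = sim.integrate(rhs, y0, 100.0, rtol=1e-10, atol=1e-12)
        mass = traj.states @ rhs.volumes
        assert np.abs(mass / mass[0] - 1).max() < 1e-6

    def test_nonnegativity(self):
        chain = typed_chain(10)
        rhs = sim.build_rhs(chain, sim.KineticModel(0.1, 0.1, 50.0, AB))
        atol = 1e-10
        traj = sim.integrate(rhs, np.zeros(10), 50.0, rtol=1e-8, atol=atol)
        assert traj.states.min() >= -atol

    def test_blocked_cells_never_change(self):
        chain = make_chain(6)
        types = ["tip", "cyt", "wall", "cyt", "cyt", "cyt"]
        for i, t in enumerate(types):
            chain[i].type = t
        model = sim.KineticModel(0.5, 0.2, 3.0, {**AB, "wall": "blocked"})
        rhs = sim.build_rhs(chain, model)
        y0 = np.array([0, 0, 4.0, 0, 0, 0])
        traj = sim.integrate(rhs, y0, 20.0)
        np.testing.assert_array_equal(traj.states[:, 2], 4.0)
        # the wall splits the chain: nothing leaks past it
        assert traj.final[3:].max() == pytest.approx(0.0, abs=1e-9)

    def test_negative_initial_state_rejected(self):
        chain = typed_chain(3)
        rhs = sim.build_rhs(chain, sim.KineticModel(0.1, 0.1, 1.0, AB))
        with pytest.raises(ValueError):
            sim.integrate(rhs, np.array([-1.0, 0.0, 0.0]), 1.0)


class TestSteadyState:
    def test_two_cell_closed_form(self):
        """Flux balance on two unit cells: C_A = alpha/beta,
        C_B = C_A + alpha V_B / (gamma w)."""
        pair = typed_chain(2)
        rhs = sim.build_rhs(pair, sim.KineticModel(0.1, 0.1, 50.0, AB, "paper_literal"))
        ss = sim.steady_state(rhs, np.zeros(2), tol=1e-12)
        assert abs(ss[1] - 1.0) < 1e-6
        assert abs(ss[0] - 1.002) < 1e-6

    def test_integration_converges_to_steady_state(self):
        pair = typed_chain(2)
        rhs = sim.build_rhs(pair, sim.KineticModel(0.1, 0.1, 50.0, AB, "paper_literal"))
        traj = sim.integrate(rhs, np.zeros(2), 500.0, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(traj.final, [1.002, 1.0], atol=1e-6)

    def test_chain_interior_geometric_decay(self):
        """Interior cells of a source-driven chain decay geometrically with
        the closed-form recurrence root of gamma w (x - 2 + 1/x) = beta V."""
        n = 30
        chain = typed_chain(n)
        alpha, beta, gamma = 0.1, 0.5, 1.0
        rhs = sim.build_rhs(
            chain, sim.KineticModel(alpha, beta, gamma, AB, "paper_literal")
        )
        ss = sim.steady_state(rhs, np.zeros(n), tol=1e-12)
        r = beta * 1.0 / (gamma * 1.0)  # unit V and w
        lam = ((2 + r) - np.sqrt((2 + r) ** 2 - 4)) / 2
        ratios = ss[6:16] / ss[5:15]
        assert np.abs(ratios / lam - 1).max() < 1e-4

    def test_all_blocked_returns_initial(self, quad_mesh):
        for s in quad_mesh:
            s.type = "wall"
        rhs = sim.build_rhs(quad_mesh, sim.KineticModel(1, 1, 1, {"wall": "blocked"}))
        y0 = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(sim.steady_state(rhs, y0, tol=1e-8), y0)

    def test_matches_direct_linear_solve(self):
        """steady_state agrees with the sparse solve of M C = -b (<= 10 cells)."""
        chain = typed_chain(8)
        rhs = sim.build_rhs(
            chain, sim.KineticModel(0.3, 0.4, 2.0, AB, "distance_normalized")
        )
        ss = sim.steady_state(rhs, np.zeros(8), tol=1e-13)
        active = np.isin(rhs.roles, ["A", "B"])
        M = rhs.matrix.tocsc()[np.ix_(active, active)]
        direct = spla.spsolve(M, -rhs.source[active])
        np.testing.assert_allclose(ss[active], direct, atol=1e-8)

    def test_budget_exhaustion_reports_residual(self):
        chain = typed_chain(5)
        rhs = sim.build_rhs(chain, sim.KineticModel(0.1, 0.001, 0.01, AB))
        with pytest.raises(sim.SteadyStateError) as err:
            sim.steady_state(rhs, np.zeros(5), tol=1e-12, t_budget=0.5)
        assert err.value.residual > 0


class TestCompareToImage:
    def _digitized_chain(self):
        chain = typed_chain(6)
        for i, s in enumerate(chain):
            s.properties["F"] = 5.0 - 0.5 * i
        return chain

    def test_identical_fields_zero_error(self):
        chain = self._digitized_chain()
        model = sim.KineticModel(0.1, 0.1, 1.0, AB)
        obs = np.array([s.properties["F"] for s in chain])
        emap = sim.compare_to_image(obs, chain, model, "F")
        assert set(emap.error.values()) == {0.0}
        assert emap.summary == 0.0

    def test_constant_offset(self):
        chain = self._digitized_chain()
        model = sim.KineticModel(0.1, 0.1, 1.0, AB)
        obs = np.array([s.properties["F"] for s in chain])
        emap = sim.compare_to_image(obs + 0.7, chain, model, "F")
        assert all(e == pytest.approx(0.7) for e in emap.error.values())
        assert set(emap.normalized.values()) == {1.0}
        assert emap.summary == pytest.approx(0.7 / 5.0)

    def test_blocked_types_excluded_unless_included(self):
        chain = self._digitized_chain()
        chain[3].type = "nuc"
        model = sim.KineticModel(0.1, 0.1, 1.0, {**AB, "nuc": "blocked"})
        obs = np.zeros(6)
        emap = sim.compare_to_image(obs, chain, model, "F")
        assert 3 not in emap.error
        emap2 = sim.compare_to_image(obs, chain, model, "F", include_types=("nuc",))
        assert emap2.error[3] == pytest.approx(3.5)

    def test_all_missing_rejected(self):
        chain = typed_chain(4)
        model = sim.KineticModel(0.1, 0.1, 1.0, AB)
        with pytest.raises(ValueError):
            sim.compare_to_image(np.zeros(4), chain, model, "F")


class TestGradientSteepness:
    def test_smaller_gamma_gives_steeper_steady_gradient(self):
        """Halving the diffusion constant steepens the steady-state decay."""
        n = 25
        chain = make_chain(n)
        chain[0].type = "tip"
        for i in range(1, n):
            chain[i].type = "cyt"
        slopes = {}
        for gamma in (50.0, 100.0):
            rhs = sim.build_rhs(
                chain, sim.KineticModel(0.1, 0.1, gamma, AB, "paper_literal")
            )
            ss = sim.steady_state(rhs, np.zeros(n), tol=1e-11)
            logs = np.log(ss[2:15])
            slopes[gamma] = np.polyfit(np.arange(2, 15), logs, 1)[0]
        assert abs(slopes[50.0]) > abs(slopes[100.0])
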