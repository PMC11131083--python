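"""Co-moving finite-volume solver: mesh, fluxes, momentum, conservation."""

import math

import numpy as np
import pytest

from gelpore import make_problem
from gelpore.constitutive import saturated_cavity
from gelpore.fv_solver import (
    FvState,
    build_mesh,
    compute_fluxes,
    integrate_momentum,
    profile_frame,
    run_transient,
    stable_dt,
    steady_state_secant,
    step,
)

P0 = 101325.0


def _tau(problem):
    return problem.geom.R_out**2 / problem.gel.D_s


class TestMesh:
    def test_construction(self, default_problem):
        st = build_mesh(default_problem, n_core=10, n_skin=4)
        geom = default_problem.geom
        assert st.n_cv == 14
        assert st.R_face[0] == pytest.approx(geom.R_in)
        assert st.R_face[10] == pytest.approx(geom.R_m)  # interface on a face
        assert st.R_face[-1] == pytest.approx(geom.R_out)
        # total initial gel volume
        total = st.dV_w.sum() + st.dV_s.sum()
        assert total == pytest.approx(
            4 / 3 * math.pi * (geom.R_out**3 - geom.R_in**3), rel=1e-12
        )
        # per-CV polymer fraction equals the layer's initial fraction
        gel = default_problem.gel
        assert st.phi[:10] == pytest.approx(default_problem.core.phi0(gel))
        assert st.phi[10:] == pytest.approx(default_problem.skin.phi0(gel))

    def test_too_few_cvs_rejected(self, default_problem):
        with pytest.raises(ValueError):
            build_mesh(default_problem, n_core=2, n_skin=4)


class TestFluxes:
    def test_uniform_potential_no_interior_flux(self, free_swelling_problem):
        st = build_mesh(free_swelling_problem, 8, 4)
        J = compute_fluxes(st, free_swelling_problem)
        assert np.allclose(J[1:-1], 0.0)
        assert J[-1] == pytest.approx(0.0, abs=1e-25)

    def test_central_difference_magnitude(self, free_swelling_problem):
        """Flux between two centers: -(D_s nu_w/RT) dmu/dr * 4 pi r^2,
        with water flowing down-gradient."""
        prob = free_swelling_problem
        gel = prob.gel
        st = build_mesh(prob, 8, 4)
        integrate_momentum(st, gel)
        mu = st.mu_w.copy()
        dmu = 1e6
        mu[5] = mu[4] + dmu  # raise potential in CV 5
        st.mu_w = mu
        J = compute_fluxes(st, prob)
        r_f = st.face_r
        rc = 0.5 * (r_f[:-1] + r_f[1:])
        expected = (
            -gel.D_s * gel.nu_w / gel.RT * dmu / (rc[5] - rc[4]) * 4 * math.pi * r_f[5] ** 2
        )
        assert J[5] == pytest.approx(expected, rel=1e-12)
        assert expected < 0  # water flows inward, toward lower potential
        # antisymmetry: swapping the two center values flips the sign
        mu2 = st.mu_w.copy()
        mu2[4], mu2[5] = mu2[5], mu2[4]
        st.mu_w = mu2
        J2 = compute_fluxes(st, prob)
        assert J2[5] == pytest.approx(-J[5], rel=1e-12)


class TestMomentum:
    def test_uniform_state_ambient_stress(self, default_problem):
        st = build_mesh(default_problem, 10, 4)
        integrate_momentum(st, default_problem.gel)
        gel = default_problem.gel
        assert np.allclose(st.sigma_rr_face, -gel.p0)
        # initial pressure field G/lambda0 + p0 per layer
        assert st.p_liq[:10] == pytest.approx(
            default_problem.core.G / gel.lambda0 + gel.p0, rel=1e-12
        )
        assert st.p_liq[10:] == pytest.approx(
            default_problem.skin.G / gel.lambda0 + gel.p0, rel=1e-12
        )

    def test_outer_face_exactly_ambient_after_any_solve(self, default_problem):
        st = build_mesh(default_problem, 10, 4)
        rng = np.random.default_rng(1)
        st.dV_w *= 1.0 + 0.05 * rng.random(st.n_cv)  # perturbed water field
        integrate_momentum(st, default_problem.gel)
        assert st.sigma_rr_face[-1] == -default_problem.gel.p0


class TestTransient:
    def test_free_swelling_is_fixed_point(self, free_swelling_problem):
        """100 explicit steps without drying leave the state unchanged."""
        prob = free_swelling_problem
        st = build_mesh(prob, 8, 4)
        dV_w0 = st.dV_w.copy()
        dt = stable_dt(st, prob)
        for _ in range(100):
            step(st, dt, prob)
        assert st.dV_w == pytest.approx(dV_w0, rel=1e-12)
        assert st.cavity.p_gas == pytest.approx(P0, rel=1e-12)
        assert st.cavity.N_vap == pytest.approx(
            saturated_cavity(prob.geom.V_gas0, prob.gel).N_vap, rel=1e-12
        )

    def test_closed_system_conservation(self):
        """With the outer flux suppressed, total water (liquid plus the
        liquid-equivalent of the cavity vapour) is conserved exactly; the
        polymer volume per CV and the air moles never change."""
        prob = make_problem(G_ratio=5.0, Pi_ext_over_G=5.0, R_in_frac=0.5)
        gel = prob.gel
        st = build_mesh(prob, 8, 4)
        # start from a perturbed (non-equilibrium) water distribution
        st.dV_w *= 1.0 + 0.03 * np.sin(np.arange(st.n_cv))
        dV_s0 = st.dV_s.copy()
        N_air0 = st.cavity.N_air
        integrate_momentum(st, gel)
        total0 = st.dV_w.sum() + gel.nu_w * st.cavity.N_vap
        dt = stable_dt(st, prob)
        for _ in range(200):
            step(st, dt, prob, closed_system=True)
        total = st.dV_w.sum() + gel.nu_w * st.cavity.N_vap
        assert total == pytest.approx(total0, rel=1e-12)
        assert st.dV_s is dV_s0 or np.array_equal(st.dV_s, dV_s0)
        assert st.cavity.N_air == N_air0

    def test_drying_front_moves_inward(self):
        """Early in a drying transient the outer CVs dry first and the
        chemical potential increases monotonically toward the centre."""
        prob = make_problem(G_ratio=2.0, Pi_ext_over_G=2.0)
        st = build_mesh(prob, 10, 4)
        phi_w0 = st.phi_w.copy()
        dt = stable_dt(st, prob)
        for _ in range(300):
            step(st, dt, prob)
        dphi = st.phi_w - phi_w0
        # the outermost CV has lost by far the most water; the innermost is
        # essentially untouched (it may gain a trace by vapour condensation
        # while the cavity is compressed)
        assert dphi[-1] < -1e-3
        assert abs(dphi[0]) < 1e-4
        integrate_momentum(st, prob.gel)
        assert np.all(np.diff(st.mu_w) < 1e-6)  # mu decreasing outward

    def test_transient_approaches_steady_solver(self):
        """Long-time limit of the explicit transient matches the
        profile-resolving steady solution."""
        prob = make_problem(G_ratio=5.0, Pi_ext_over_G=4.0, R_in_frac=0.7)
        traj, st = run_transient(
            prob, t_end=8 * _tau(prob), n_core=10, n_skin=4, steady_tol=3e-9
        )
        sol = steady_state_secant(prob)
        assert traj.p_gas[-1] == pytest.approx(sol.p_gas, rel=0.01)
        assert traj.r_in[-1] == pytest.approx(sol.r_in, rel=0.01)


class TestSteadySolver:
    def test_identity_without_drying(self, free_swelling_problem):
        sol = steady_state_secant(free_swelling_problem)
        assert sol.Lambda_out == pytest.approx(1.0, rel=1e-10)
        assert sol.p_gas == pytest.approx(P0, rel=1e-8)

    def test_interface_kinematics(self, default_problem):
        """The hoop stretch is continuous across the core/skin interface
        while the radial stretch jumps (the stiffer skin swells less)."""
        sol = steady_state_secant(default_problem)
        R = sol.profile["R"]
        geom = default_problem.geom
        i = np.searchsorted(R, geom.R_m)
        below = slice(max(i - 3, 0), i)
        above = slice(i, i + 3)
        lam_t = sol.profile["lambda_theta"]
        lam_r = sol.profile["lambda_r"]
        assert abs(np.mean(lam_t[above]) - np.mean(lam_t[below])) < 5e-3
        jump = abs(np.mean(lam_r[above]) - np.mean(lam_r[below]))
        assert jump > 0.1 * np.mean(lam_r[below])

    def test_profile_satisfies_chemical_equilibrium(self, default_problem):
        sol = steady_state_secant(default_problem)
        mu_ext = default_problem.env.mu_ext(default_problem.gel)
        assert np.max(np.abs(sol.profile["mu_w"] - mu_ext)) < 1e-6 * abs(mu_ext)
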