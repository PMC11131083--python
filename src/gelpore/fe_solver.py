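"""1D spherical mixed finite-element solver on the fixed initial frame.

Unknowns are the radial displacement ``u(R)`` (quadratic elements), the
Lagrange-multiplier pressure ``p(R)`` (linear, discontinuous across the
core/skin interface, where the physical liquid pressure jumps), the water
molar concentrations per initial volume ``c_c(R)``, ``c_s(R)`` on the core
and skin subdomains (linear, coupled only through an interface Robin flux),
and the vapour moles ``N_vap`` in the cavity (a scalar ODE).

The weak form stacks

* the force balance, in the divergence-consistent form
  ``int (S_RR du~/dR + (2/R) S_tt u~) R^2 dR - [S_RR u~ R^2]`` with boundary
  tractions ``S_RR = -p0 lam_t^2`` (outer) and ``S_RR = -p_gas lam_t^2``
  (cavity, outward normal pointing inward);
* the incompressibility constraint ``J - (phi0 + nu_w c)`` tested with the
  pressure space;
* the referential mass balance with radial flux
  ``h_w = -(lam_t^2/lam_r) (D_s/RT) dmu_w/dR`` and Robin boundary fluxes:
  evaporation into the cavity, convective drying at the outer surface
  (Lewis-relation transfer coefficient), and a penalty-type interface flux
  ``D_mu (mu_c - mu_s)`` enforcing chemical-potential continuity;
* the cavity vapour balance ``dN_vap/dt = q_cav 4 pi R_in^2`` closed by the
  air isotherm (conserved air moles) and the ideal-gas vapour pressure.

Time integration is backward Euler with a monolithic Newton solve
(finite-difference Jacobian on the scaled unknowns, reused across iterations)
and adaptive step halving/growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .config import Problem
from .constitutive import p_sat_tetens, saturated_cavity
from .fv_solver import Trajectory

__all__ = [
    "FeState",
    "RobinBC",
    "FeSolver",
    "run_transient_fe",
]

# 3-point Gauss rule on [0, 1]
_XQ = np.array([0.5 - math.sqrt(3.0 / 20.0), 0.5, 0.5 + math.sqrt(3.0 / 20.0)])
_WQ = np.array([5.0 / 18.0, 8.0 / 18.0, 5.0 / 18.0])

# P2 shape functions (nodes at xi = 0, 1/2, 1) and xi-derivatives at the rule
_N2 = np.stack(
    [(1 - _XQ) * (1 - 2 * _XQ), 4 * _XQ * (1 - _XQ), _XQ * (2 * _XQ - 1)], axis=0
)
_D2 = np.stack([4 * _XQ - 3, 4 - 8 * _XQ, 4 * _XQ - 1], axis=0)
# P1 shape functions
_N1 = np.stack([1 - _XQ, _XQ], axis=0)
_D1 = np.stack([-np.ones_like(_XQ), np.ones_like(_XQ)], axis=0)


class NewtonError(RuntimeError):
    """Raised when the monolithic Newton iteration fails after dt retries."""


class ElementInversionError(RuntimeError):
    """Raised when a trial state has non-positive volume ratio J."""


@dataclass(frozen=True)
class RobinBC:
    """Boundary mass-transfer data.

    beta_air follows the Lewis relation ``h_air/(rho_air c_p,air)``; beta_cav
    is ``D_vap/(r_cav/5)`` with ``r_cav`` the current cavity radius; D_mu is
    the interface permeance (penalty enforcing mu_w continuity).
    """

    beta_air: float
    D_vap: float
    D_mu: float
    c_sat: float


@dataclass
class FeState:
    """Nodal fields and cavity vapour moles (SI units, unscaled)."""

    u: np.ndarray
    p_core: np.ndarray
    p_skin: np.ndarray
    c_core: np.ndarray
    c_skin: np.ndarray
    N_vap: float
    time: float = 0.0


class FeSolver:
    """Assembler and time stepper for the coupled weak formulation."""

    def __init__(
        self,
        problem: Problem,
        n_core: int = 16,
        n_skin: int = 6,
        D_mu_factor: float = 100.0,
        newton_tol: float = 1e-9,
        dt_max_frac: float = 0.1,
    ):
        self.problem = problem
        gel, geom = problem.gel, problem.geom
        self.nel_c, self.nel_s = n_core, n_skin
        self.edges_c = np.linspace(geom.R_in, geom.R_m, n_core + 1)
        self.edges_s = np.linspace(geom.R_m, geom.R_out, n_skin + 1)
        self.nel = n_core + n_skin
        edges = np.concatenate([self.edges_c, self.edges_s[1:]])
        self.edges = edges
        self.h = np.diff(edges)
        # u nodes: element endpoints and midpoints (P2, continuous)
        self.R_u = np.empty(2 * self.nel + 1)
        self.R_u[0::2] = edges
        self.R_u[1::2] = 0.5 * (edges[:-1] + edges[1:])
        self.nu = self.R_u.size
        # u connectivity (elements x 3)
        e = np.arange(self.nel)
        self.conn_u = np.stack([2 * e, 2 * e + 1, 2 * e + 2], axis=1)
        # quadrature point radii per element (elements x 3)
        self.Rq = edges[:-1, None] + np.outer(self.h, _XQ)
        # per-element layer data
        core_elems = np.arange(self.nel) < n_core
        self.G_el = np.where(core_elems, problem.core.G, problem.skin.G)
        self.phi0_el = np.where(
            core_elems, problem.core.phi0(gel), problem.skin.phi0(gel)
        )
        self.phi_ref_el = np.where(
            core_elems, problem.core.phi_ref, problem.skin.phi_ref
        )
        # Robin data
        env = problem.env
        h_min = float(self.h.min())
        self.bc = RobinBC(
            beta_air=env.beta_air(),
            D_vap=env.D_vap,
            D_mu=D_mu_factor * gel.D_s / (gel.RT * h_min),
            c_sat=p_sat_tetens(gel.T) / gel.RT,
        )
        self.cavity0 = saturated_cavity(geom.V_gas0, gel)
        self.newton_tol = newton_tol
        self.dt_max_frac = dt_max_frac
        # scaling of unknowns and residual blocks
        self.tau_d = geom.R_out**2 / gel.D_s
        self.N_vap0 = self.cavity0.N_vap
        self._sizes = (self.nu, n_core + 1, n_skin + 1, n_core + 1, n_skin + 1, 1)
        self.ndof = sum(self._sizes)
        self._x_scale = np.concatenate(
            [
                np.full(self.nu, geom.R_out),
                np.full(n_core + 1, problem.core.G),
                np.full(n_skin + 1, problem.core.G),
                np.full(n_core + 1, 1.0 / gel.nu_w),
                np.full(n_skin + 1, 1.0 / gel.nu_w),
                [self.N_vap0],
            ]
        )
        self._r_scale = np.concatenate(
            [
                np.full(self.nu, problem.core.G * geom.R_out**2),
                np.full(n_core + 1, geom.R_out**2 * geom.R_m / self.nel),
                np.full(n_skin + 1, geom.R_out**2 * geom.R_m / self.nel),
                np.full(
                    n_core + 1, geom.R_out**3 / (gel.nu_w * self.tau_d * self.nel)
                ),
                np.full(
                    n_skin + 1, geom.R_out**3 / (gel.nu_w * self.tau_d * self.nel)
                ),
                [self.N_vap0 / self.tau_d],
            ]
        )

    # -- state/vector packing ------------------------------------------------

    def initial_state(self) -> FeState:
        gel = self.problem.gel
        nc, ns = self.nel_c + 1, self.nel_s + 1
        return FeState(
            u=np.zeros(self.nu),
            p_core=np.full(nc, self.problem.core.G / gel.lambda0 + gel.p0),
            p_skin=np.full(ns, self.problem.skin.G / gel.lambda0 + gel.p0),
            c_core=np.full(nc, (1.0 - self.problem.core.phi0(gel)) / gel.nu_w),
            c_skin=np.full(ns, (1.0 - self.problem.skin.phi0(gel)) / gel.nu_w),
            N_vap=self.N_vap0,
        )

    def pack(self, s: FeState) -> np.ndarray:
        return (
            np.concatenate(
                [s.u, s.p_core, s.p_skin, s.c_core, s.c_skin, [s.N_vap]]
            )
            / self._x_scale
        )

    def unpack(self, x: np.ndarray, time: float = 0.0) -> FeState:
        v = x * self._x_scale
        i = np.cumsum(self._sizes)
        return FeState(
            u=v[: i[0]],
            p_core=v[i[0] : i[1]],
            p_skin=v[i[1] : i[2]],
            c_core=v[i[2] : i[3]],
            c_skin=v[i[3] : i[4]],
            N_vap=float(v[i[4]]),
            time=time,
        )

    # -- physics helpers -----------------------------------------------------

    def _mu(self, c, p, phi0, phi_ref, G):
        """Chemical potential from concentration and Lagrange pressure."""
        gel = self.problem.gel
        phi = phi0 / (phi0 + gel.nu_w * c)
        return -gel.alpha * G * (phi / phi_ref) ** gel.beta + p

    def cavity_quantities(self, s: FeState):
        """(lam_t_in, V_gas, p_air, p_vap, p_gas, RH_cav) from u(R_in), N_vap."""
        gel, geom = self.problem.gel, self.problem.geom
        lam_t_in = 1.0 + s.u[0] / geom.R_in
        if lam_t_in <= 0:
            raise ElementInversionError("cavity wall passed through the origin")
        V_gas = lam_t_in**3 * geom.V_gas0
        p_air = self.cavity0.p_air * geom.V_gas0 / V_gas
        p_vap = s.N_vap * gel.RT / V_gas
        return lam_t_in, V_gas, p_air, p_vap, p_air + p_vap, p_vap / p_sat_tetens(gel.T)

    def robin_fluxes(self, s: FeState):
        """Boundary molar fluxes per *reference* area [mol/m^2/s].

        Returns (q_cav, q_out, q_interface) with q_cav/q_out positive for
        water leaving the gel and q_interface positive core -> skin.
        """
        gel, geom, env = self.problem.gel, self.problem.geom, self.problem.env
        lam_t_in, _, _, _, p_gas, RH_cav = self.cavity_quantities(s)
        mu_c_in = self._mu(
            s.c_core[0],
            s.p_core[0],
            self.problem.core.phi0(gel),
            self.problem.core.phi_ref,
            self.problem.core.G,
        )
        a_w_int = math.exp((mu_c_in - p_gas) * gel.nu_w / gel.RT)
        beta_cav = self.bc.D_vap / (lam_t_in * geom.R_in / 5.0)
        q_cav = lam_t_in**2 * beta_cav * (a_w_int - RH_cav) * self.bc.c_sat

        lam_t_out = 1.0 + s.u[-1] / geom.R_out
        mu_s_out = self._mu(
            s.c_skin[-1],
            s.p_skin[-1],
            self.problem.skin.phi0(gel),
            self.problem.skin.phi_ref,
            self.problem.skin.G,
        )
        a_w_ext = math.exp((mu_s_out - gel.p0) * gel.nu_w / gel.RT)
        q_out = lam_t_out**2 * self.bc.beta_air * (a_w_ext - env.rh_ext(gel)) * self.bc.c_sat

        mu_c_m = self._mu(
            s.c_core[-1],
            s.p_core[-1],
            self.problem.core.phi0(gel),
            self.problem.core.phi_ref,
            self.problem.core.G,
        )
        mu_s_m = self._mu(
            s.c_skin[0],
            s.p_skin[0],
            self.problem.skin.phi0(gel),
            self.problem.skin.phi_ref,
            self.problem.skin.G,
        )
        q_if = self.bc.D_mu * (mu_c_m - mu_s_m)
        return q_cav, q_out, q_if

    # -- residual ------------------------------------------------------------

    def residual(self, x: np.ndarray, x_old: np.ndarray | None, dt: float) -> np.ndarray:
        """Scaled monolithic residual; ``x_old=None`` drops the time terms."""
        gel, geom = self.problem.gel, self.problem.geom
        s = self.unpack(x)
        s_old = self.unpack(x_old) if x_old is not None else None
        inv_dt = 0.0 if x_old is None else 1.0 / dt

        nu_w, lam0 = gel.nu_w, gel.lambda0
        h, Rq = self.h, self.Rq

        # field values at quadrature points (elements x 3)
        u_el = s.u[self.conn_u]  # (nel, 3)
        u_q = np.einsum("ea,aq->eq", u_el, _N2)
        du_q = np.einsum("ea,aq->eq", u_el, _D2) / h[:, None]
        lam_t = 1.0 + u_q / Rq
        lam_r = 1.0 + du_q
        if np.any(lam_r <= 0.0) or np.any(lam_t <= 0.0):
            raise ElementInversionError("non-positive stretch at quadrature point")
        J = lam_r * lam_t**2

        # p and c per element (P1 blocks per layer)
        p_nodes = np.concatenate([s.p_core, s.p_skin])
        c_nodes = np.concatenate([s.c_core, s.c_skin])
        e = np.arange(self.nel)
        off = np.where(e < self.nel_c, 0, 1)  # skin block starts after core block
        conn_1 = np.stack([e + off, e + off + 1], axis=1)
        p_q = np.einsum("ea,aq->eq", p_nodes[conn_1], _N1)
        c_q = np.einsum("ea,aq->eq", c_nodes[conn_1], _N1)
        dp_q = np.einsum("ea,aq->eq", p_nodes[conn_1], _D1) / h[:, None]
        dc_q = np.einsum("ea,aq->eq", c_nodes[conn_1], _D1) / h[:, None]

        G = self.G_el[:, None]
        phi0 = self.phi0_el[:, None]
        phi_ref = self.phi_ref_el[:, None]

        S_RR = G * lam_r / lam0 - p_q * lam_t**2
        S_tt = G * lam_t / lam0 - p_q * lam_t * lam_r

        # chemical potential gradient via chain rule
        phi = phi0 / (phi0 + nu_w * c_q)
        dPi_dphi = gel.alpha * G * gel.beta * phi ** (gel.beta - 1.0) / phi_ref**gel.beta
        dphi_dc = -nu_w * phi**2 / phi0
        dmu_q = -dPi_dphi * dphi_dc * dc_q + dp_q
        h_w = -(lam_t**2 / lam_r) * (gel.D_s / gel.RT) * dmu_q

        wR2 = _WQ[None, :] * Rq**2 * h[:, None]  # quadrature weights x R^2 x h

        res_u = np.zeros(self.nu)
        # int (S_RR dN/dR + 2/R S_tt N) R^2 dR
        contrib = np.einsum(
            "eq,aq,eq->ea", S_RR, _D2, wR2 / h[:, None]
        ) + np.einsum("eq,aq,eq->ea", 2.0 / Rq * S_tt, _N2, wR2)
        np.add.at(res_u, self.conn_u, contrib)
        # boundary tractions
        lam_t_in, V_gas, p_air, p_vap, p_gas, RH_cav = self.cavity_quantities(s)
        lam_t_out = 1.0 + s.u[-1] / geom.R_out
        res_u[-1] += gel.p0 * lam_t_out**2 * geom.R_out**2
        res_u[0] -= p_gas * lam_t_in**2 * geom.R_in**2

        # incompressibility, tested with the P1 pressure space
        res_p = np.zeros(p_nodes.size)
        gap = J - (phi0 + nu_w * c_q)
        np.add.at(res_p, conn_1, np.einsum("eq,aq,eq->ea", gap, _N1, wR2))

        # mass balances
        res_c = np.zeros(c_nodes.size)
        if s_old is not None:
            c_old_nodes = np.concatenate([s_old.c_core, s_old.c_skin])
            cdot_q = np.einsum("ea,aq->eq", (c_nodes - c_old_nodes)[conn_1], _N1) * inv_dt
        else:
            cdot_q = np.zeros_like(c_q)
        contrib_c = np.einsum("eq,aq,eq->ea", cdot_q, _N1, wR2) - np.einsum(
            "eq,aq,eq->ea", h_w, _D1, wR2 / h[:, None]
        )
        np.add.at(res_c, conn_1, contrib_c)
        q_cav, q_out, q_if = self.robin_fluxes(s)
        i_core_m = self.nel_c  # core node at interface
        i_skin_m = self.nel_c + 1  # skin node at interface (c block index)
        res_c[0] += geom.R_in**2 * q_cav
        res_c[i_core_m] += geom.R_m**2 * q_if
        res_c[i_skin_m] -= geom.R_m**2 * q_if
        res_c[-1] += geom.R_out**2 * q_out

        # cavity vapour ODE (backward Euler); 4 pi consistent with the
        # (dropped) 4 pi of the volume integrals: the c-residual carries
        # R^2 q, the cavity gains q * R_in^2 -> both scaled identically.
        Nv_dot = (s.N_vap - s_old.N_vap) * inv_dt if s_old is not None else 0.0
        res_N = Nv_dot - q_cav * geom.R_in**2

        return (
            np.concatenate([res_u, res_p, res_c, [res_N]]) / self._r_scale
        )

    # -- nonlinear solve -----------------------------------------------------

    def _fd_jacobian(self, x, x_old, dt, r0):
        eps = 1e-7
        Jm = np.empty((self.ndof, self.ndof))
        for j in range(self.ndof):
            xp = x.copy()
            step = eps * max(1.0, abs(x[j]))
            xp[j] += step
            Jm[:, j] = (self.residual(xp, x_old, dt) - r0) / step
        return Jm

    def newton(self, x0, x_old, dt, max_iter=12):
        """Damped modified-Newton solve; returns converged scaled vector."""
        x = x0.copy()
        r = self.residual(x, x_old, dt)
        Jm = None
        lu = None
        for it in range(max_iter):
            norm = float(np.max(np.abs(r)))
            if norm < self.newton_tol:
                return x
            if Jm is None or it % 4 == 3:
                Jm = self._fd_jacobian(x, x_old, dt, r)
                lu = sla.lu_factor(Jm)
            dx = sla.lu_solve(lu, r)
            damp = 1.0
            for _ in range(8):
                try:
                    r_new = self.residual(x - damp * dx, x_old, dt)
                except ElementInversionError:
                    damp *= 0.5
                    continue
                if np.max(np.abs(r_new)) < norm * (1.0 - 0.1 * damp) or damp < 0.1:
                    x = x - damp * dx
                    r = r_new
                    break
                damp *= 0.5
            else:
                raise NewtonError(f"line search stalled at |r|={norm:.3e}")
        raise NewtonError(f"no convergence in {max_iter} iterations")

    def time_step(self, s: FeState, dt: float, max_halvings: int = 12):
        """One adaptive backward-Euler step; returns (state, dt_taken, dt_next)."""
        x_old = self.pack(s)
        for _ in range(max_halvings):
            try:
                x = self.newton(x_old, x_old, dt)
                dt_next = min(dt * 1.5, self.dt_max_frac * self.tau_d)
                return self.unpack(x, s.time + dt), dt, dt_next
            except (NewtonError, ElementInversionError):
                dt *= 0.5
        raise NewtonError(f"step failed down to dt={dt:.3e}s at t={s.time:.3e}s")

    # -- output --------------------------------------------------------------

    def profile_frame(self, s: FeState) -> pd.DataFrame:
        """Nodal profile snapshot (element-endpoint nodes)."""
        gel, geom = self.problem.gel, self.problem.geom
        R = self.edges
        u_end = s.u[0::2]
        lam_t = 1.0 + u_end / R
        # lam_r from element-wise P2 derivative, averaged at shared nodes
        dN_at = np.array([[-3.0, 4.0, -1.0], [1.0, -4.0, 3.0]])  # xi=0, xi=1
        du = np.einsum("ea,ba->eb", s.u[self.conn_u], dN_at) / self.h[:, None]
        lam_r = np.empty_like(R)
        lam_r[0] = 1.0 + du[0, 0]
        lam_r[-1] = 1.0 + du[-1, 1]
        lam_r[1:-1] = 1.0 + 0.5 * (du[:-1, 1] + du[1:, 0])
        # interface node belongs to both layers; report the core side for
        # p/c and duplicate lam_r from the core element (per-layer profiles
        # are produced per layer by the comparison utilities anyway)
        p_nodes = np.concatenate([s.p_core[:-1], [s.p_core[-1]], s.p_skin[1:]])
        c_nodes = np.concatenate([s.c_core[:-1], [s.c_core[-1]], s.c_skin[1:]])
        layer = np.where(R < geom.R_m, "core", "skin")
        layer[self.nel_c] = "core"
        G = np.where(layer == "core", self.problem.core.G, self.problem.skin.G)
        phi0 = np.where(
            layer == "core", self.problem.core.phi0(gel), self.problem.skin.phi0(gel)
        )
        phi_ref = np.where(
            layer == "core", self.problem.core.phi_ref, self.problem.skin.phi_ref
        )
        phi = phi0 / (phi0 + gel.nu_w * c_nodes)
        mu = -gel.alpha * G * (phi / phi_ref) ** gel.beta + p_nodes
        phi_hat = phi / (phi0 * gel.lambda0)
        sigma_rr = G * phi_hat * lam_r**2 - p_nodes
        return pd.DataFrame(
            {
                "R": R,
                "r": R + u_end,
                "lambda_r": lam_r,
                "lambda_theta": lam_t,
                "sigma_rr": sigma_rr,
                "p_liq": p_nodes,
                "mu_w": mu,
                "phi_w": 1.0 - phi,
                "layer": layer,
                "t": s.time,
            }
        )


def run_transient_fe(
    problem: Problem,
    t_end: float,
    n_core: int = 16,
    n_skin: int = 6,
    dt0: float | None = None,
    steady_tol: float = 1e-10,
    snapshot_times: tuple = (),
    solver: FeSolver | None = None,
    record_every_step: bool = True,
) -> tuple[Trajectory, FeState, FeSolver]:
    """Run the FE transient to ``t_end`` or steady state.

    Returns the cavity/radius time series, the final state and the solver
    (for profile extraction).  ``steady_tol`` is the relative water-content
    rate [1/s] below which the run stops early.
    """
    fe = solver or FeSolver(problem, n_core=n_core, n_skin=n_skin)
    s = fe.initial_state()
    dt = dt0 if dt0 is not None else 1e-3 * fe.tau_d
    rec: dict[str, list] = {
        k: [] for k in ("t", "p_gas", "p_air", "p_vap", "r_in", "r_m", "r_out")
    }
    i_m = 2 * fe.nel_c  # u-node index at the core/skin interface
    snapshots: list[pd.DataFrame] = []
    snap_left = sorted(snapshot_times)
    geom = problem.geom

    def record(state: FeState) -> None:
        _, _, p_air, p_vap, p_gas, _ = fe.cavity_quantities(state)
        rec["t"].append(state.time)
        rec["p_gas"].append(p_gas)
        rec["p_air"].append(p_air)
        rec["p_vap"].append(p_vap)
        rec["r_in"].append(geom.R_in + state.u[0])
        rec["r_m"].append(geom.R_m + state.u[i_m])
        rec["r_out"].append(geom.R_out + state.u[-1])

    record(s)
    steady = False
    nu_w = problem.gel.nu_w
    while s.time < t_end:
        dt = min(dt, t_end - s.time)
        s_new, dt_taken, dt = fe.time_step(s, dt)
        while snap_left and s_new.time >= snap_left[0]:
            snapshots.append(fe.profile_frame(s_new))
            snap_left.pop(0)
        rate = (
            max(
                float(np.max(np.abs(s_new.c_core - s.c_core))),
                float(np.max(np.abs(s_new.c_skin - s.c_skin))),
            )
            * nu_w
            / dt_taken
        )
        s = s_new
        if record_every_step:
            record(s)
        if rate < steady_tol:
            steady = True
            break
    if not record_every_step:
        record(s)
    snapshots.append(fe.profile_frame(s))
    traj = Trajectory(
        **{k: np.asarray(v) for k, v in rec.items()},
        snapshots=snapshots,
        steady=steady,
    )
    return traj, s, fe
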