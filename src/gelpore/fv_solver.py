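"""Finite-volume solvers on a mesh co-moving with the polymer network.

The transient scheme subdivides the gel into spherical-shell control volumes
whose polymer content is fixed (the mesh rides on the network); water volumes
evolve by Darcy fluxes driven by chemical-potential gradients, the momentum
balance is integrated inward from the stress-free outer surface every step,
and the cavity gas follows the air isotherm with vapour equilibrated to the
gel at the cavity wall.  Explicit (forward-Euler) time stepping with an
adaptive diffusion-limited step.

``steady_state_secant`` solves the steady problem directly: for an assumed
outer hoop stretch it integrates the momentum balance in the material
coordinate with the local polymer fraction slaved to chemical equilibrium
with the environment, then iterates the outer stretch until the cavity gas
law and the vapour-equilibrium expression agree.  Unlike the closed-form
approximation in :mod:`gelpore.analytic_steady`, it resolves the radial
profiles exactly (to ODE tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .analytic_steady import ConvergenceError, SteadySolution
from .config import Problem
from .constitutive import (
    CavityState,
    GelParams,
    cavity_from_pressure,
    p_sat_tetens,
    saturated_cavity,
)

__all__ = [
    "FvState",
    "Trajectory",
    "build_mesh",
    "compute_fluxes",
    "integrate_momentum",
    "update_cavity",
    "step",
    "run_transient",
    "steady_state_secant",
]


class StepSizeError(RuntimeError):
    """Raised when the explicit step produces a nonphysical water content."""


# ---------------------------------------------------------------------------
# transient co-moving solver
# ---------------------------------------------------------------------------


@dataclass
class FvState:
    """Co-moving control-volume state.

    ``R_face`` are the initial-frame face positions (fixed); current face
    positions are rebuilt each evaluation from the cavity volume and the
    per-CV volumes ``dV_w + dV_s`` (``dV_s`` constant by construction).
    """

    R_face: np.ndarray
    dV_w: np.ndarray
    dV_s: np.ndarray
    G_cv: np.ndarray
    phi_ref_cv: np.ndarray
    phi0_cv: np.ndarray
    cavity: CavityState
    time: float = 0.0
    # diagnostic fields, populated by integrate_momentum / step
    face_r: np.ndarray | None = field(default=None, repr=False)
    sigma_rr_face: np.ndarray | None = field(default=None, repr=False)
    p_liq: np.ndarray | None = field(default=None, repr=False)
    mu_w: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_cv(self) -> int:
        return self.dV_s.size

    @property
    def phi(self) -> np.ndarray:
        """Polymer volume fraction per CV (current frame)."""
        return self.dV_s / (self.dV_s + self.dV_w)

    @property
    def phi_w(self) -> np.ndarray:
        return 1.0 - self.phi

    def current_faces(self) -> np.ndarray:
        """Current face radii from the cavity volume and CV volumes."""
        r3 = np.concatenate(
            ([3.0 * self.cavity.V_gas / (4.0 * math.pi)],
             3.0 / (4.0 * math.pi) * np.cumsum(self.dV_w + self.dV_s)
             + 3.0 * self.cavity.V_gas / (4.0 * math.pi))
        )
        return np.cbrt(r3)

    def stretches(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(r_center, lambda_r, lambda_theta) per CV.

        Discrete stretch definitions: lambda_r is the ratio of current to
        initial shell thickness, lambda_theta the ratio of current to initial
        center radius.
        """
        r_f = self.current_faces()
        rc = 0.5 * (r_f[:-1] + r_f[1:])
        Rc = 0.5 * (self.R_face[:-1] + self.R_face[1:])
        lam_r = np.diff(r_f) / np.diff(self.R_face)
        lam_t = rc / Rc
        return rc, lam_r, lam_t


def build_mesh(problem: Problem, n_core: int = 40, n_skin: int = 8) -> FvState:
    """Build the initial co-moving mesh; faces align with the cavity wall,
    the core/skin interface and the outer surface."""
    if n_core < 3 or n_skin < 3:
        raise ValueError("need at least 3 control volumes per layer")
    geom, gel = problem.geom, problem.gel
    R_face = np.concatenate(
        (
            np.linspace(geom.R_in, geom.R_m, n_core + 1),
            np.linspace(geom.R_m, geom.R_out, n_skin + 1)[1:],
        )
    )
    V_face = 4.0 / 3.0 * math.pi * R_face**3
    dV = np.diff(V_face)
    phi0 = np.concatenate(
        (
            np.full(n_core, problem.core.phi0(gel)),
            np.full(n_skin, problem.skin.phi0(gel)),
        )
    )
    G_cv = np.concatenate(
        (np.full(n_core, problem.core.G), np.full(n_skin, problem.skin.G))
    )
    phi_ref = np.concatenate(
        (np.full(n_core, problem.core.phi_ref), np.full(n_skin, problem.skin.phi_ref))
    )
    return FvState(
        R_face=R_face,
        dV_w=(1.0 - phi0) * dV,
        dV_s=phi0 * dV,
        G_cv=G_cv,
        phi_ref_cv=phi_ref,
        phi0_cv=phi0,
        cavity=saturated_cavity(geom.V_gas0, gel),
    )


def _pi_mix_cv(state: FvState, gel: GelParams) -> np.ndarray:
    return gel.alpha * state.G_cv * (state.phi / state.phi_ref_cv) ** gel.beta


def integrate_momentum(state: FvState, gel: GelParams) -> None:
    """March the radial stress inward from sigma_rr(r_out) = -p0.

    Fills ``face_r``, ``sigma_rr_face``, ``p_liq``, ``mu_w`` and updates the
    cavity gas pressure bookkeeping value p_gas = -sigma_rr(r_in).
    """
    rc, lam_r, lam_t = state.stretches()
    r_f = state.current_faces()
    phi = state.phi
    phi_hat = phi / (state.phi0_cv * gel.lambda0)
    dsig_dr = 2.0 * state.G_cv / rc * phi_hat * (lam_t**2 - lam_r**2)
    dr = np.diff(r_f)
    # sigma(r - dr/2) = sigma(r + dr/2) - dr * dsigma/dr(center), marched
    # inward from the stress-free outer surface
    sig = np.empty(state.n_cv + 1)
    sig[-1] = -gel.p0
    sig[:-1] = sig[-1] - np.cumsum((dr * dsig_dr)[::-1])[::-1]
    sig_center = sig[1:] - 0.5 * dr * dsig_dr
    p_liq = state.G_cv * phi_hat * lam_r**2 - sig_center
    state.face_r = r_f
    state.sigma_rr_face = sig
    state.p_liq = p_liq
    state.mu_w = -_pi_mix_cv(state, gel) + p_liq


def compute_fluxes(state: FvState, problem: Problem) -> np.ndarray:
    """Volumetric water fluxes at faces [m^3/s], positive outward.

    Central differencing of mu_w between adjacent CV centers; the outer face
    carries the Dirichlet condition mu_w(r_out) = p0 - Pi_ext through a ghost
    value at half spacing; the cavity face flux is handled by the vapour
    update, not by Darcy flow.
    """
    gel, env = problem.gel, problem.env
    if state.mu_w is None:
        integrate_momentum(state, gel)
    r_f = state.face_r
    rc = 0.5 * (r_f[:-1] + r_f[1:])
    mob = gel.D_s * gel.nu_w / gel.RT
    J = np.zeros(state.n_cv + 1)
    J[1:-1] = (
        -mob
        * np.diff(state.mu_w)
        / np.diff(rc)
        * 4.0
        * math.pi
        * r_f[1:-1] ** 2
    )
    J[-1] = (
        -mob
        * (env.mu_ext(gel) - state.mu_w[-1])
        / (r_f[-1] - rc[-1])
        * 4.0
        * math.pi
        * r_f[-1] ** 2
    )
    return J


def update_cavity(state: FvState, gel: GelParams) -> tuple[CavityState, float]:
    """Equilibrate the cavity gas with the gel at the cavity wall.

    Returns the new cavity state and the vapour-mole increment; the latter is
    drawn as liquid volume from the innermost CV by :func:`step`.
    """
    new_cavity = cavity_from_pressure(
        state.sigma_rr_face[0], state.mu_w[0], state.cavity, gel
    )
    dN_vap = new_cavity.N_vap - state.cavity.N_vap
    return new_cavity, dN_vap


def equilibrate_cavity_volume(state: FvState, gel: GelParams) -> None:
    """Make the cavity volume self-consistent with the momentum balance.

    The mechanics is quasi-static (no inertia), so at every instant the gas
    volume must satisfy the air isotherm evaluated at the gas pressure that
    the momentum integration produces *for that volume* (the mesh floats on
    the cavity).  A lagged explicit update of this pair is the dominant
    instability of the co-moving scheme (volume and pressure leapfrog with
    gain > 1 for stiff skins); solving the scalar consistency equation
    ``V = N_air RT / p_air(V)`` by bracketing removes it.  Water content per
    CV is untouched; on exit ``state.cavity`` and the stress/potential
    diagnostics are mutually consistent.
    """
    cav0 = state.cavity

    def evaluate(V: float) -> tuple[float, CavityState]:
        state.cavity = CavityState(
            N_air=cav0.N_air,
            N_vap=cav0.N_vap,
            V_gas=V,
            p_air=cav0.p_air,
            p_vap=cav0.p_vap,
            p_gas=cav0.p_gas,
        )
        integrate_momentum(state, gel)
        new = cavity_from_pressure(
            state.sigma_rr_face[0], state.mu_w[0], cav0, gel
        )
        return new.V_gas - V, new

    def geval(V: float) -> tuple[float, bool]:
        try:
            return evaluate(V)[0], True
        except ValueError:
            return math.nan, False

    V0 = cav0.V_gas
    # fast path: warm-started secant (the consistent volume moves only a
    # little between transport steps and the slope dg/dV varies slowly)
    slope = getattr(state, "_cavity_slope", None)
    if slope is not None and slope < 0:
        V = V0
        gv, ok = geval(V)
        for _ in range(8):
            if not ok:
                break
            if abs(gv) <= 1e-11 * V0:
                state._cavity_slope = slope
                state.cavity = evaluate(V)[1]
                integrate_momentum(state, gel)
                return
            V_new = V - gv / slope
            if not 0.5 * V0 < V_new < 2.0 * V0:
                ok = False
                break
            g_new, ok_new = geval(V_new)
            if not ok_new:
                ok = False
                break
            if V_new != V:
                slope = (g_new - gv) / (V_new - V)
                if slope >= 0:
                    ok = False
                    break
            V, gv = V_new, g_new
        # fall through to the robust bracketed path on any failure
    try:
        g0, ok = geval(V0)
        if not ok:
            # current volume inadmissible (transport pushed the state); scan
            # outward in both directions for any admissible trial
            for k in range(1, 60):
                for V in (V0 * 1.04**k, V0 / 1.04**k):
                    g0, ok = geval(V)
                    if ok:
                        V0 = V
                        break
                if ok:
                    break
            else:
                raise StepSizeError("no admissible cavity volume found")
        if abs(g0) <= 1e-12 * V0:
            state.cavity = evaluate(V0)[1]
            integrate_momentum(state, gel)
            return
        # g(V) = V_isotherm(V) - V is decreasing in V and defined only on a
        # (possibly narrow) admissible interval around the root; expand in
        # small factors toward the root and bisect back inside when a trial
        # leaves the admissible window.
        fac = 1.04
        if g0 < 0:
            hi, lo = V0, V0 / fac
            inward = hi
            for _ in range(600):
                val, ok = geval(lo)
                if not ok:
                    lo = 0.5 * (lo + inward)
                    continue
                if val > 0:
                    break
                inward = lo
                hi = lo
                lo /= fac
            else:
                raise StepSizeError("cavity-volume consistency bracket not found")
        else:
            lo, hi = V0, V0 * fac
            inward = lo
            for _ in range(600):
                val, ok = geval(hi)
                if not ok:
                    hi = 0.5 * (hi + inward)
                    continue
                if val < 0:
                    break
                inward = hi
                lo = hi
                hi *= fac
            else:
                raise StepSizeError("cavity-volume consistency bracket not found")
        V_star = brentq(
            lambda V: evaluate(V)[0], lo, hi, xtol=1e-14 * V0, rtol=1e-14
        )
        if hi > lo:
            glo, _ = geval(lo)
            ghi, _ = geval(hi)
            if math.isfinite(glo) and math.isfinite(ghi):
                state._cavity_slope = (ghi - glo) / (hi - lo)
        state.cavity = evaluate(V_star)[1]
        integrate_momentum(state, gel)
    except Exception:
        if state.cavity is not cav0:
            state.cavity = cav0
        raise


def stable_dt(state: FvState, problem: Problem, safety: float = 0.2) -> float:
    """Diffusion-limited explicit step: dt = C min(dr^2) RT/(D_s nu_w max|dPi/dphi_w|)."""
    gel = problem.gel
    r_f = state.current_faces()
    dr2 = np.diff(r_f) ** 2
    dPi_dphi = (
        gel.alpha
        * state.G_cv
        * gel.beta
        * (state.phi / state.phi_ref_cv) ** (gel.beta - 1.0)
        / state.phi_ref_cv
    )
    D_eff = gel.D_s * gel.nu_w / gel.RT * dPi_dphi
    return safety * float(np.min(dr2 / D_eff))


def step(
    state: FvState, dt: float, problem: Problem, closed_system: bool = False
) -> FvState:
    """One forward-Euler step (in place); returns the state for chaining.

    Sequence per the co-moving scheme: momentum solve -> chemical potentials
    -> cavity equilibration -> Darcy fluxes -> water-volume update.
    ``closed_system`` suppresses the outer boundary flux (conservation tests).
    """
    gel = problem.gel
    N_vap_old = state.cavity.N_vap
    equilibrate_cavity_volume(state, gel)
    dN_vap = state.cavity.N_vap - N_vap_old
    J = compute_fluxes(state, problem)
    if closed_system:
        J[-1] = 0.0
    dV_w = state.dV_w + dt * (J[:-1] - J[1:])
    dV_w[0] -= gel.nu_w * dN_vap  # evaporation into the cavity
    if np.any(dV_w <= 0):
        raise StepSizeError(
            f"non-positive water volume at t={state.time:.3e}s; reduce dt"
        )
    state.dV_w = dV_w
    state.time += dt
    state.mu_w = None  # invalidate diagnostics
    return state


@dataclass
class Trajectory:
    """Time series of cavity pressures and radii, plus profile snapshots."""

    t: np.ndarray
    p_gas: np.ndarray
    p_air: np.ndarray
    p_vap: np.ndarray
    r_in: np.ndarray
    r_m: np.ndarray
    r_out: np.ndarray
    snapshots: list = field(default_factory=list)
    steady: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "p_gas": self.p_gas,
                "p_air": self.p_air,
                "p_vap": self.p_vap,
                "r_in": self.r_in,
                "r_m": self.r_m,
                "r_out": self.r_out,
            }
        )


def profile_frame(state: FvState, problem: Problem) -> pd.DataFrame:
    """Radial profile snapshot as a tidy frame (per control volume)."""
    gel = problem.gel
    integrate_momentum(state, gel)
    rc, lam_r, lam_t = state.stretches()
    Rc = 0.5 * (state.R_face[:-1] + state.R_face[1:])
    sig_c = 0.5 * (state.sigma_rr_face[:-1] + state.sigma_rr_face[1:])
    return pd.DataFrame(
        {
            "R": Rc,
            "r": rc,
            "lambda_r": lam_r,
            "lambda_theta": lam_t,
            "sigma_rr": sig_c,
            "p_liq": state.p_liq,
            "mu_w": state.mu_w,
            "phi_w": state.phi_w,
            "layer": np.where(Rc < problem.geom.R_m, "core", "skin"),
            "t": state.time,
        }
    )


def run_transient(
    problem: Problem,
    t_end: float,
    n_core: int = 40,
    n_skin: int = 8,
    output_every: float | None = None,
    steady_tol: float = 1e-10,
    snapshot_times: tuple = (),
    closed_system: bool = False,
    state: FvState | None = None,
) -> tuple[Trajectory, FvState]:
    """Run the transient FV solver to ``t_end`` or steady state.

    ``steady_tol`` bounds the relative water-fraction rate max|dphi_w/dt|
    [1/s] below which the run terminates early.  Snapshots are recorded at
    the requested times (nearest step).
    """
    gel = problem.gel
    if state is None:
        state = build_mesh(problem, n_core, n_skin)
    if output_every is None:
        output_every = t_end / 400.0
    rec: dict[str, list] = {
        k: [] for k in ("t", "p_gas", "p_air", "p_vap", "r_in", "r_m", "r_out")
    }
    i_interface = n_core if state is None else int(
        np.searchsorted(state.R_face, problem.geom.R_m)
    )
    snapshots: list[pd.DataFrame] = []
    snap_left = sorted(snapshot_times)
    next_out = 0.0
    steady = False

    def record() -> None:
        c = state.cavity
        r_f = state.current_faces()
        rec["t"].append(state.time)
        rec["p_gas"].append(c.p_gas)
        rec["p_air"].append(c.p_air)
        rec["p_vap"].append(c.p_vap)
        rec["r_in"].append(r_f[0])
        rec["r_m"].append(r_f[i_interface])
        rec["r_out"].append(r_f[-1])

    # ensure cavity pressures reflect the mechanical state before recording
    equilibrate_cavity_volume(state, gel)
    n_since_dt = 0
    dt_cached = 0.0
    while state.time < t_end:
        if state.time >= next_out:
            record()
            next_out += output_every
        while snap_left and state.time >= snap_left[0]:
            snapshots.append(profile_frame(state, problem))
            snap_left.pop(0)
        # the stability bound drifts slowly; refresh it periodically (with a
        # margin) rather than every step
        if n_since_dt % 16 == 0:
            dt_cached = 0.9 * stable_dt(state, problem)
        n_since_dt += 1
        dt = min(dt_cached, t_end - state.time)
        phi_w_old = state.phi_w
        step(state, dt, problem, closed_system=closed_system)
        rate = float(np.max(np.abs(state.phi_w - phi_w_old))) / dt
        if rate < steady_tol:
            steady = True
            break
    record()
    snapshots.append(profile_frame(state, problem))
    traj = Trajectory(
        **{k: np.asarray(v) for k, v in rec.items()},
        snapshots=snapshots,
        steady=steady,
    )
    return traj, state


# ---------------------------------------------------------------------------
# profile-resolving steady solver
# ---------------------------------------------------------------------------


def _local_phi_hat_solver(problem: Problem):
    """Newton solve (warm-started, bracket fallback) of the pointwise
    chemical equilibrium Pi_mix(ph) = G ph lam_r^2 - sigma_rr - p0 + Pi_ext
    with lam_r = 1/(ph lam0 lam_t^2)."""
    gel, env = problem.gel, problem.env
    lam0, alpha, beta = gel.lambda0, gel.alpha, gel.beta
    offset_const = gel.p0 - env.Pi_ext
    guess = {"ph": 1.0 / lam0}

    def solve(sigma_rr: float, lam_t: float, G: float) -> float:
        a = alpha * G / lam0 ** (2 * beta)
        b = G / (lam0**2 * lam_t**4)
        c = sigma_rr + offset_const
        # f(ph) = a ph^beta - b/ph + c, strictly increasing
        ph = guess["ph"]
        for _ in range(40):
            f = a * ph**beta - b / ph + c
            fp = a * beta * ph ** (beta - 1.0) + b / ph**2
            dph = f / fp
            ph_new = ph - dph
            if ph_new <= 0:
                ph_new = 0.5 * ph
            if abs(ph_new - ph) < 1e-14 * ph_new:
                guess["ph"] = ph_new
                return ph_new
            ph = ph_new
        # bracketed fallback
        lo, hi = 1e-12, 1.0
        fl = a * lo**beta - b / lo + c
        while a * hi**beta - b / hi + c < 0:
            hi *= 2.0
            if hi > 1e15:
                raise ConvergenceError("local equilibrium has no root")
        if fl > 0:
            raise ConvergenceError("local equilibrium root below bracket")
        ph = brentq(lambda x: a * x**beta - b / x + c, lo, hi, xtol=1e-16, rtol=1e-14)
        guess["ph"] = ph
        return ph

    return solve


def _steady_profile(Lambda_out: float, problem: Problem, rtol: float = 1e-9):
    """Integrate (r, sigma_rr) inward in the material coordinate R.

    Local polymer fraction slaved to chemical equilibrium with the
    environment at every point.  Returns None if the trial state is
    inadmissible (collapse or loss of local equilibrium).
    """
    geom, gel = problem.geom, problem.gel
    lam0 = gel.lambda0
    local = _local_phi_hat_solver(problem)

    def rhs(R: float, y: np.ndarray):
        r, sig = y
        G = problem.core.G if R < geom.R_m else problem.skin.G
        lam_t = r / R
        ph = local(sig, lam_t, G)
        lam_r = 1.0 / (ph * lam0 * lam_t**2)
        dsig_dr = 2.0 * G / r * ph * (lam_t**2 - lam_r**2)
        return (lam_r, lam_r * dsig_dr)

    def collapse(R: float, y: np.ndarray) -> float:
        return y[0] - 1e-4 * geom.R_out

    collapse.terminal = True  # type: ignore[attr-defined]

    try:
        sol = solve_ivp(
            rhs,
            (geom.R_out, geom.R_in),
            (Lambda_out * geom.R_out, -gel.p0),
            method="RK45",
            rtol=rtol,
            atol=(1e-14 * geom.R_out, 1e-8 * gel.p0),
            events=collapse,
            dense_output=True,
        )
    except ConvergenceError:
        return None
    if (not sol.success) or sol.t[-1] > geom.R_in + 1e-12 * geom.R_out:
        return None
    return sol


def steady_state_secant(
    problem: Problem,
    cavity0: CavityState | None = None,
    tol: float = 1e-8,
    max_iter: int = 60,
    n_profile: int = 201,
) -> SteadySolution:
    """Profile-resolving steady state, iterating the outer hoop stretch.

    For each trial stretch the momentum balance is integrated with the local
    polymer fraction in chemical equilibrium with the environment; the
    mismatch between the vapour pressure from the cavity gas law and from the
    equilibrium expression closes the iteration (secant with bracketing
    fallback, tolerance relative on the mismatch).
    """
    gel, geom, env = problem.gel, problem.geom, problem.env
    if cavity0 is None:
        cavity0 = saturated_cavity(geom.V_gas0, gel)
    ps = p_sat_tetens(gel.T)
    mu_ext = env.mu_ext(gel)

    def mismatch(Lambda_out: float) -> float:
        sol = _steady_profile(Lambda_out, problem)
        if sol is None:
            return math.nan
        r_in, sig_in = sol.y[0, -1], sol.y[1, -1]
        p_gas = -sig_in
        # trial stretches may produce nonphysical (even negative) gas
        # pressures; the residual stays well-defined there, which is what
        # lets the scan bracket the root in the steep small-pore regime
        V = 4.0 / 3.0 * math.pi * r_in**3
        p_vap_gas = p_gas - cavity0.N_air * gel.RT / V
        expo = min((mu_ext - p_gas) * gel.nu_w / gel.RT, 50.0)
        p_vap_eq = ps * math.exp(expo)
        return p_vap_gas - p_vap_eq

    if env.Pi_ext == 0.0 and env.rh_ext(gel) >= 1.0 - 1e-12:
        L_star = 1.0
    else:
        # bracket scan (coarse) then Brent; secant refinement is implicit in
        # brentq's inverse-quadratic steps
        Ls = np.linspace(0.2, 1.2, 51)
        vals = np.array([mismatch(L) for L in Ls])
        ok = np.isfinite(vals)
        idx = np.flatnonzero(ok[:-1] & ok[1:] & (vals[:-1] * vals[1:] < 0))
        if idx.size == 0:
            raise ConvergenceError(
                "steady solver: no sign change of the vapour mismatch over the "
                f"stretch scan ({ok.sum()}/51 admissible trials)"
            )
        i = idx[0]
        L_star = brentq(
            mismatch, Ls[i], Ls[i + 1], xtol=1e-12, rtol=8.9e-16, maxiter=max_iter
        )

    sol = _steady_profile(L_star, problem, rtol=1e-10)
    if sol is None:
        raise ConvergenceError("steady solver: converged stretch inadmissible")
    R = np.linspace(geom.R_out, geom.R_in, n_profile)
    r, sig = sol.sol(R)
    lam_t = r / R
    lam0 = gel.lambda0
    local = _local_phi_hat_solver(problem)
    G_arr = np.where(R < geom.R_m, problem.core.G, problem.skin.G)
    ph = np.array([local(s, lt, g) for s, lt, g in zip(sig, lam_t, G_arr)])
    lam_r = 1.0 / (ph * lam0 * lam_t**2)
    p_liq = G_arr * ph * lam_r**2 - sig
    phi0_arr = np.where(
        R < geom.R_m, problem.core.phi0(gel), problem.skin.phi0(gel)
    )
    phi = ph * phi0_arr * lam0
    phi_ref_arr = np.where(
        R < geom.R_m, problem.core.phi_ref, problem.skin.phi_ref
    )
    mu = -gel.alpha * G_arr * (phi / phi_ref_arr) ** gel.beta + p_liq

    r_in, sig_in = sol.y[0, -1], sol.y[1, -1]
    p_gas = -sig_in
    V = 4.0 / 3.0 * math.pi * r_in**3
    p_air = cavity0.N_air * gel.RT / V
    # interface values by interpolation of the dense solution
    r_m, sig_m = sol.sol(geom.R_m)
    order = np.argsort(R)
    core_mask = R < geom.R_m
    return SteadySolution(
        Lambda_in=r_in / geom.R_in,
        Lambda_m=r_m / geom.R_m,
        Lambda_out=L_star,
        phi_hat_core=float(np.mean(ph[core_mask])),
        phi_hat_skin=float(np.mean(ph[~core_mask])),
        dp_core=p_gas - (-sig_m),
        dp_skin=(-sig_m) - gel.p0,
        p_gas=p_gas,
        p_vap=p_gas - p_air,
        p_air=p_air,
        r_in=r_in,
        r_out=L_star * geom.R_out,
        profile={
            "R": R[order],
            "r": r[order],
            "lambda_r": lam_r[order],
            "lambda_theta": lam_t[order],
            "sigma_rr": sig[order],
            "p_liq": p_liq[order],
            "mu_w": mu[order],
            "phi_w": (1.0 - phi)[order],
        },
    )
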