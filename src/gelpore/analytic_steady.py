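"""Closed-form steady-state approximation for the dried core/shell sphere.

The approximation assumes the polymer volume fraction is uniform within each
layer (valid for thin to moderately thick shells).  Under that assumption the
radial momentum balance integrates in closed form, giving the pressure drop
across a spherical hydrogel shell as a function of the hoop stretches at its
two surfaces and its (uniform) swelling measure ``phi_hat``.  Composing the
drops over skin and core and closing with the cavity gas law (conserved air
moles + vapour equilibrium) yields the steady state of the full problem.

Two forms of the shell pressure drop appear:

* :func:`shell_pressure_drop` is the textbook closed form
  ``(G/2)[(1+4 phi_hat La^3)/(phi_hat La^4) - (1+4 phi_hat Lb^3)/(phi_hat Lb^4)]``,
  exactly the integral of ``dsigma_rr = 2G(phi_hat l^2 - 1/(phi_hat l^4)) /
  (l - phi_hat l^4) dl``; it is internally consistent with the volume ratio
  ``J = 1/phi_hat``.
* the composed solver uses the frame-consistent variant
  (:func:`layer_pressure_drop`) for the physical kinematics
  ``J = 1/(phi_hat lambda0)`` of this package's stress convention
  (``sigma_i = phi_hat G lambda_i^2 - p``): the exact stress potential is then
  ``sigma(l) = (G/(2 lambda0)) (1+4 x l^3)/(x l^4) + C`` with
  ``x = lambda0 phi_hat``, and the drop p(inner) - p(outer) over a shell is
  ``sigma(Lb) - sigma(La)``.  In the thin-shell limit this variant converges
  to the profile-resolving steady solver; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .config import Problem
from .constitutive import (
    CavityState,
    Environment,
    GelParams,
    LayerSpec,
    p_sat_tetens,
    pi_mix_phi_hat,
    saturated_cavity,
)

__all__ = [
    "SteadySolution",
    "shell_pressure_drop",
    "layer_pressure_drop",
    "phi_hat_outer_equilibrium",
    "inner_radius_from_incompressibility",
    "core_shell_steady",
]


class ConvergenceError(RuntimeError):
    """Raised when a nonlinear solve fails to converge."""


class ShellCollapseError(ValueError):
    """Raised when incompressibility would require a negative cube radius."""


@dataclass
class SteadySolution:
    """Equilibrium state of the dried core/shell sphere.

    Hoop stretches at the three material surfaces, per-layer swelling
    measures and pressure drops, cavity pressures and current radii.  When
    produced by the profile-resolving solver, ``profile`` holds the radial
    fields on the initial-frame grid ``R``.
    """

    Lambda_in: float
    Lambda_m: float
    Lambda_out: float
    phi_hat_core: float
    phi_hat_skin: float
    dp_core: float
    dp_skin: float
    p_gas: float
    p_vap: float
    p_air: float
    r_in: float
    r_out: float
    profile: dict | None = field(default=None, repr=False)

    def lambda_theta_profile(self, problem: Problem, n: int = 101):
        """Hoop-stretch profile lambda_theta(R) on the initial-frame grid.

        For the uniform-swelling solution the profile follows from layer-wise
        incompressibility; the profile-resolving solvers return their own
        computed fields instead.
        """
        if self.profile is not None:
            return np.asarray(self.profile["R"]), np.asarray(
                self.profile["lambda_theta"]
            )
        geom = problem.geom
        lam0 = problem.gel.lambda0
        R = np.linspace(geom.R_in, geom.R_out, n)
        r3 = np.empty_like(R)
        core_mask = R <= geom.R_m
        J_core = 1.0 / (self.phi_hat_core * lam0)
        J_skin = 1.0 / (self.phi_hat_skin * lam0)
        r3[core_mask] = self.r_in**3 + J_core * (R[core_mask] ** 3 - geom.R_in**3)
        r_m3 = self.r_in**3 + J_core * (geom.R_m**3 - geom.R_in**3)
        r3[~core_mask] = r_m3 + J_skin * (R[~core_mask] ** 3 - geom.R_m**3)
        return R, np.cbrt(r3) / R


def shell_pressure_drop(phi_hat: float, Lambda_a: float, Lambda_b: float, G: float) -> float:
    """Closed-form pressure drop over a uniformly swollen spherical shell [Pa].

    ``(G/2)[(1+4 ph La^3)/(ph La^4) - (1+4 ph Lb^3)/(ph Lb^4)]`` with
    ``Lambda_a``/``Lambda_b`` the hoop stretches at the inner/outer surface.
    Antisymmetric under swapping the two stretches; vanishes when they agree.
    """
    if min(phi_hat, Lambda_a, Lambda_b) <= 0:
        raise ValueError("phi_hat and stretches must be positive")

    def f(L: float) -> float:
        return (1.0 + 4.0 * phi_hat * L**3) / (phi_hat * L**4)

    return 0.5 * G * (f(Lambda_a) - f(Lambda_b))


def layer_pressure_drop(
    phi_hat: float, Lambda_a: float, Lambda_b: float, G: float, gel: GelParams
) -> float:
    """Frame-consistent pressure drop p(inner) - p(outer) over a layer [Pa].

    Exact integral of the momentum balance for uniform swelling with the
    physical volume ratio ``J = 1/(phi_hat lambda0)``; equals
    ``-shell_pressure_drop(lambda0*phi_hat, La, Lb, G/lambda0)``.
    """
    lam0 = gel.lambda0
    return -shell_pressure_drop(lam0 * phi_hat, Lambda_a, Lambda_b, G / lam0)


def _phi_hat_equilibrium(Lambda: float, G: float, Pi_eff: float, gel: GelParams) -> float:
    """Largest root of ``G*ph*Lambda^2 + Pi_eff - Pi_mix(ph) = 0``.

    ``f`` rises linearly from ``Pi_eff`` and is eventually dominated by the
    Cloizeaux term (exponent 9/4 > 1), so it has a single interior maximum at
    ``ph_peak``; the physical (drier-than-peak) root is bracketed by
    ``[ph_peak, inf)``.  For ``Pi_eff < 0`` (a layer effectively under
    hydration) no root may exist, which signals an inadmissible trial state.
    """
    lam0 = gel.lambda0

    def f(ph: float) -> float:
        return G * ph * Lambda**2 + Pi_eff - pi_mix_phi_hat(ph, G, gel)

    ph_peak = lam0**2 * (Lambda**2 * lam0**2 / (gel.alpha * gel.beta)) ** (
        1.0 / (gel.beta - 1.0)
    )
    if f(ph_peak) < 0:
        raise ConvergenceError(
            f"no swelling equilibrium at Lambda={Lambda:.4g}, Pi_eff={Pi_eff:.4g}"
        )
    hi = max(2.0 * ph_peak, 1.0)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise ConvergenceError("equilibrium bracket blew up")
    return brentq(f, ph_peak, hi, xtol=1e-15, rtol=1e-14)


def phi_hat_outer_equilibrium(
    Lambda_b: float, env: Environment, layer: LayerSpec, gel: GelParams
) -> float:
    """Swelling measure at the outer surface from the stress-free-surface
    chemical equilibrium ``G*phi_hat*Lambda_b^2 + Pi_ext - Pi_mix(phi_hat) = 0``."""
    if Lambda_b <= 0:
        raise ValueError("Lambda_b must be positive")
    return _phi_hat_equilibrium(Lambda_b, layer.G, env.Pi_ext, gel)


def inner_radius_from_incompressibility(
    Lambda_b: float, phi_ratio: float, R_A: float, R_B: float
) -> float:
    """Inner current radius of a shell from volume conservation.

    ``r_a = (r_b^3 - phi_ratio (R_B^3 - R_A^3))^(1/3)`` with
    ``r_b = Lambda_b R_B`` and ``phi_ratio = phi0/phi`` the layer volume ratio.
    """
    if min(Lambda_b, phi_ratio, R_A, R_B) <= 0:
        raise ValueError("arguments must be positive")
    r_b = Lambda_b * R_B
    r_a3 = r_b**3 - phi_ratio * (R_B**3 - R_A**3)
    if r_a3 <= 0:
        raise ShellCollapseError(
            f"shell collapse: r_a^3 = {r_a3:.4g} <= 0 at Lambda_b = {Lambda_b:.4g}"
        )
    return r_a3 ** (1.0 / 3.0)


def _evaluate_at_Lambda_out(Lambda_out: float, problem: Problem, cavity0: CavityState):
    """One forward pass of the analytic chain at trial outer stretch.

    Returns (residual, SteadySolution); the residual is the cavity-closure
    mismatch p_gas - (p_air + p_vap) [Pa].
    """
    gel, geom, env = problem.gel, problem.geom, problem.env
    core, skin = problem.core, problem.skin
    lam0 = gel.lambda0

    ph_s = phi_hat_outer_equilibrium(Lambda_out, env, skin, gel)
    r_m = inner_radius_from_incompressibility(
        Lambda_out, 1.0 / (ph_s * lam0), geom.R_m, geom.R_out
    )
    Lambda_m = r_m / geom.R_m
    dp_skin = layer_pressure_drop(ph_s, Lambda_m, Lambda_out, skin.G, gel)

    # interface equilibrium: outer-boundary relation with the skin drop added
    # to the external osmotic pressure (see docs/methods.md)
    ph_c = _phi_hat_equilibrium(Lambda_m, core.G, env.Pi_ext + dp_skin, gel)
    r_in = inner_radius_from_incompressibility(
        Lambda_m, 1.0 / (ph_c * lam0), geom.R_in, geom.R_m
    )
    Lambda_in = r_in / geom.R_in
    dp_core = layer_pressure_drop(ph_c, Lambda_in, Lambda_m, core.G, gel)

    p_gas = gel.p0 + dp_skin + dp_core
    V_gas = 4.0 / 3.0 * math.pi * r_in**3
    p_air = cavity0.N_air * gel.RT / V_gas
    p_vap = p_sat_tetens(gel.T) * math.exp(
        (env.mu_ext(gel) - p_gas) * gel.nu_w / gel.RT
    )
    sol = SteadySolution(
        Lambda_in=Lambda_in,
        Lambda_m=Lambda_m,
        Lambda_out=Lambda_out,
        phi_hat_core=ph_c,
        phi_hat_skin=ph_s,
        dp_core=dp_core,
        dp_skin=dp_skin,
        p_gas=p_gas,
        p_vap=p_vap,
        p_air=p_air,
        r_in=r_in,
        r_out=Lambda_out * geom.R_out,
    )
    return p_gas - (p_air + p_vap), sol


def quasi_steady_p_gas(
    r_in: float, r_m: float, r_out: float, problem: Problem
) -> float:
    """Quasi-steady cavity pressure from the instantaneous geometry [Pa].

    Evaluates the layer pressure-drop decomposition with hoop stretches and
    per-layer swelling measures taken from the current radii alone
    (``phi_hat = (R_B^3-R_A^3)/(lambda0 (r_b^3-r_a^3))`` is the volume-average
    of the uniform-swelling measure).  During slow drying the mechanics is
    always equilibrated, so the true transient gas pressure should track this
    value once sharp moisture gradients have relaxed.
    """
    gel, geom = problem.gel, problem.geom
    lam0 = gel.lambda0
    ph_c = (geom.R_m**3 - geom.R_in**3) / (lam0 * (r_m**3 - r_in**3))
    ph_s = (geom.R_out**3 - geom.R_m**3) / (lam0 * (r_out**3 - r_m**3))
    dp_skin = layer_pressure_drop(
        ph_s, r_m / geom.R_m, r_out / geom.R_out, problem.skin.G, gel
    )
    dp_core = layer_pressure_drop(
        ph_c, r_in / geom.R_in, r_m / geom.R_m, problem.core.G, gel
    )
    return gel.p0 + dp_skin + dp_core


def _free_swelling_stretch(G: float, env: Environment, gel: GelParams) -> float:
    """Isotropic equilibrium stretch of an unconstrained gel ball under Pi_ext.

    Solves the outer-boundary relation self-consistently with
    ``Lambda = (1/(phi_hat lambda0))^(1/3)``; used as the secant seed.
    """

    def g(ph: float) -> float:
        Lam2 = (1.0 / (ph * gel.lambda0)) ** (2.0 / 3.0)
        return G * ph * Lam2 + env.Pi_ext - pi_mix_phi_hat(ph, G, gel)

    lo, hi = 1.0 / gel.lambda0, 1.0 / gel.lambda0
    while g(hi) > 0:
        hi *= 2.0
    while g(lo) < 0:
        lo *= 0.5
    ph = brentq(g, lo, hi, xtol=1e-15, rtol=1e-14) if hi > lo else lo
    return (1.0 / (ph * gel.lambda0)) ** (1.0 / 3.0)


def core_shell_steady(
    problem: Problem,
    cavity0: CavityState | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> SteadySolution:
    """Steady state of the core/shell sphere by secant iteration on Lambda_out.

    The residual is the cavity-closure mismatch between the mechanical gas
    pressure ``p0 + dp_skin + dp_core`` and the thermodynamic one
    ``N_air RT/V_gas + p_sat exp((mu_ext - p_gas) nu_w/RT)``.  The secant is
    seeded from the skin-only free-swelling stretch (perturbed by 1%); on
    failure it falls back to a bracketing scan plus Brent's method.
    """
    gel, env = problem.gel, problem.env
    if cavity0 is None:
        cavity0 = saturated_cavity(problem.geom.V_gas0, gel)

    if env.Pi_ext == 0.0 and env.rh_ext(gel) >= 1.0 - 1e-12:
        # the free-swollen state is an exact fixed point of the model
        _, sol = _evaluate_at_Lambda_out(1.0, problem, cavity0)
        return sol

    def resid(L: float) -> float:
        try:
            return _evaluate_at_Lambda_out(L, problem, cavity0)[0]
        except (ConvergenceError, ShellCollapseError):
            return math.nan

    # secant iteration
    L0 = min(_free_swelling_stretch(problem.skin.G, env, gel), 1.1)
    L1 = 0.99 * L0
    f0, f1 = resid(L0), resid(L1)
    for _ in range(max_iter):
        if not (math.isfinite(f0) and math.isfinite(f1)) or f1 == f0:
            break
        L2 = L1 - f1 * (L1 - L0) / (f1 - f0)
        if not 0.05 < L2 < 2.0:
            break
        L0, f0, L1, f1 = L1, f1, L2, resid(L2)
        if math.isfinite(f1) and abs(f1) < tol * gel.p0:
            return _evaluate_at_Lambda_out(L1, problem, cavity0)[1]

    # fallback: bracket scan + Brent
    Ls = np.linspace(0.2, 1.2, 101)
    vals = np.array([resid(L) for L in Ls])
    ok = np.isfinite(vals)
    sign_change = ok[:-1] & ok[1:] & (vals[:-1] * vals[1:] < 0)
    idx = np.flatnonzero(sign_change)
    if idx.size == 0:
        raise ConvergenceError(
            "no steady state found: cavity-closure residual has no sign change "
            f"(finite residuals at {ok.sum()}/101 scan points)"
        )
    i = idx[0]
    L_star = brentq(resid, Ls[i], Ls[i + 1], xtol=1e-13)
    return _evaluate_at_Lambda_out(L_star, problem, cavity0)[1]
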