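"""Material parameters, kinematics, constitutive laws and gas-phase thermodynamics.

The gel is a Neo-Hookean polymer network swollen with water.  All solvers in
this package share the relations defined here:

* the Cloizeaux scaling law for the osmotic mixing pressure,
  ``Pi_mix = alpha * G * (phi/phi_ref)**(9/4)``, which by the c*-theorem of
  deGennes replaces a Flory-Huggins chi-based mixing term;
* the Neo-Hookean Cauchy / first-Piola stresses of the swollen network,
  measured from the unstretched configuration via the multiplicative split
  ``F = F_e F_u`` (free-swelling pre-stretch ``lambda0`` with
  ``lambda0**3 = 3/2``);
* the water chemical potential ``mu_w = -Pi_mix + p_liq`` (units Pa = J/m^3);
* ideal-gas thermodynamics of the air/vapour mixture in the central cavity,
  with the Tetens relation for the saturation pressure.

Three reference configurations appear throughout.  B0 is the free-swollen
initial state (stress-free, in equilibrium with pure water, a_w = 1) and is
used as the computational reference frame; Bu is the unstretched state of the
network chains; Btau is the current (deformed) state.  Polymer volume
fractions in these frames are ``phi0``, ``phi_ref`` and ``phi`` respectively,
with ``phi_ref = lambda0**3 * phi0``.  Two derived swelling measures recur:

* ``phi_tilde = phi / phi_ref`` (argument of the Cloizeaux law), and
* ``phi_hat = phi / (phi0 * lambda0)`` (stress prefactor,
  ``sigma_i = phi_hat * G * lambda_i**2 - p_liq``),

related by ``phi_tilde = phi_hat / lambda0**2``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GelParams",
    "LayerSpec",
    "Geometry",
    "Environment",
    "LocalState",
    "CavityState",
    "skin_phi_ref",
    "osmotic_pressure_mix",
    "pi_mix_phi_hat",
    "phi_hat_from_pi_mix",
    "cauchy_stress",
    "piola_stress",
    "chemical_potential",
    "p_sat_tetens",
    "water_activity",
    "activity_to_mu",
    "saturated_cavity",
    "cavity_from_pressure",
]

#: default free-swelling volume ratio J0 = lambda0**3 (universal for food gels)
LAMBDA0_CUBED = 1.5

R_GAS_DEFAULT = 8.314  # J/mol/K


def _alpha_default(lambda0: float) -> float:
    # unique prefactor for which the free-swollen state is an equilibrium of
    # the model itself: Pi_mix(phi0) = alpha*G*(2/3)**(9/4) must equal G/lambda0
    return lambda0 ** (23.0 / 4.0)


@dataclass(frozen=True)
class GelParams:
    """Global gel-physics constants (shared by core and skin).

    Parameters
    ----------
    alpha : dimensionless osmotic prefactor of the Cloizeaux law (> 1).
        Default ``lambda0**(23/4) ~ 2.175234`` makes the free-swollen state
        (a_w = 1) stationary.
    beta : dimensionless Cloizeaux exponent, 9/4.
    lambda0 : free-swelling stretch, ``lambda0**3 = 3/2`` by default.
    nu_w : molar volume of water [m^3/mol].
    D_s : self-diffusivity of water in the gel [m^2/s].
    T : temperature [K].
    R_gas : gas constant [J/mol/K].
    p0 : ambient pressure [Pa].
    """

    alpha: float = None  # type: ignore[assignment]
    beta: float = 9.0 / 4.0
    lambda0: float = LAMBDA0_CUBED ** (1.0 / 3.0)
    nu_w: float = 1.8e-5
    D_s: float = 1e-9
    T: float = 308.15
    R_gas: float = R_GAS_DEFAULT
    p0: float = 101325.0

    def __post_init__(self) -> None:
        if self.alpha is None:
            object.__setattr__(self, "alpha", _alpha_default(self.lambda0))
        if not self.alpha > 1:
            raise ValueError(f"alpha must exceed 1, got {self.alpha}")
        for name in ("nu_w", "D_s", "T", "p0", "lambda0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def lambda0_cubed(self) -> float:
        return self.lambda0**3

    @property
    def RT(self) -> float:
        """Molar thermal energy R_gas * T [J/mol]."""
        return self.R_gas * self.T

    def with_temperature(self, T: float) -> "GelParams":
        return replace(self, T=T)


@dataclass(frozen=True)
class LayerSpec:
    """Per-layer material data: shear modulus and reference polymer fraction.

    ``phi_ref`` is the polymer volume fraction in the unstretched state Bu;
    the initial-state fraction is ``phi0 = phi_ref / lambda0**3``.
    """

    G: float
    phi_ref: float

    def __post_init__(self) -> None:
        if not self.G > 0:
            raise ValueError("shear modulus must be positive")
        if not 0.0 < self.phi_ref < 1.0:
            raise ValueError(f"phi_ref must lie in (0, 1), got {self.phi_ref}")

    def phi0(self, gel: GelParams) -> float:
        """Polymer fraction in the free-swollen initial state B0."""
        return self.phi_ref / gel.lambda0_cubed


@dataclass(frozen=True)
class Geometry:
    """Initial (free-swollen frame) radii of cavity, core/skin interface, surface."""

    R_in: float
    R_m: float
    R_out: float

    def __post_init__(self) -> None:
        if not 0.0 < self.R_in < self.R_m < self.R_out:
            raise ValueError(
                f"require 0 < R_in < R_m < R_out, got "
                f"({self.R_in}, {self.R_m}, {self.R_out})"
            )

    @property
    def t_skin(self) -> float:
        return self.R_out - self.R_m

    @property
    def V_gas0(self) -> float:
        """Initial cavity volume [m^3]."""
        return 4.0 / 3.0 * math.pi * self.R_in**3


@dataclass(frozen=True)
class Environment:
    """Drying environment: external osmotic pressure and gas-side transfer data.

    ``RH_ext`` defaults to the activity equivalent of ``Pi_ext``
    (``exp(-Pi_ext nu_w / RT)``); pass it explicitly to decouple the two.
    """

    Pi_ext: float = 0.0
    RH_ext: float | None = None
    h_air: float = 20.0  # W/m^2/K, convective heat transfer (Lewis relation)
    rho_air: float = 1.2  # kg/m^3
    cp_air: float = 1005.0  # J/kg/K
    D_vap: float = 2.5e-5  # m^2/s, vapour diffusivity in air

    def __post_init__(self) -> None:
        if self.Pi_ext < 0:
            raise ValueError("Pi_ext must be non-negative")
        if self.RH_ext is not None and not 0.0 <= self.RH_ext <= 1.0:
            raise ValueError("RH_ext must lie in [0, 1]")

    def mu_ext(self, gel: GelParams) -> float:
        """External water chemical potential mu_w,ext = p0 - Pi_ext [Pa]."""
        return gel.p0 - self.Pi_ext

    def rh_ext(self, gel: GelParams) -> float:
        """External relative humidity; derived from Pi_ext unless given."""
        if self.RH_ext is not None:
            return self.RH_ext
        return math.exp(-self.Pi_ext * gel.nu_w / gel.RT)

    def beta_air(self) -> float:
        """Outer mass-transfer coefficient via the Lewis relation [m/s]."""
        return self.h_air / (self.rho_air * self.cp_air)


@dataclass
class LocalState:
    """Pointwise kinematic/thermodynamic state relative to B0.

    Only ``lambda_r``, ``lambda_theta`` and ``p_liq`` are independent; ``phi``
    follows from incompressibility (``J = lambda_r lambda_theta^2 = phi0/phi``)
    and is stored for convenience.  Fields may be numpy arrays.
    """

    lambda_r: np.ndarray | float
    lambda_theta: np.ndarray | float
    phi: np.ndarray | float
    p_liq: np.ndarray | float = 0.0

    @classmethod
    def from_stretches(
        cls,
        lambda_r: np.ndarray | float,
        lambda_theta: np.ndarray | float,
        layer: LayerSpec,
        gel: GelParams,
        p_liq: np.ndarray | float = 0.0,
    ) -> "LocalState":
        J = lambda_r * lambda_theta**2
        return cls(lambda_r, lambda_theta, layer.phi0(gel) / J, p_liq)

    def J(self):
        return self.lambda_r * self.lambda_theta**2


@dataclass
class CavityState:
    """Air/vapour mixture in the central cavity (ideal gases).

    ``N_air`` is fixed at initialisation (air does not dissolve in the gel);
    the vapour exchanges with the surrounding hydrogel.
    """

    N_air: float
    N_vap: float
    V_gas: float
    p_air: float
    p_vap: float
    p_gas: float

    def check(self, gel: GelParams, rtol: float = 1e-9) -> None:
        RT = gel.RT
        assert abs(self.p_gas - (self.p_air + self.p_vap)) <= rtol * self.p_gas
        assert abs(self.p_air * self.V_gas - self.N_air * RT) <= rtol * self.N_air * RT
        assert abs(self.p_vap * self.V_gas - self.N_vap * RT) <= rtol * max(
            self.N_vap * RT, 1e-300
        )

    def rh_cav(self, gel: GelParams) -> float:
        return self.p_vap / p_sat_tetens(gel.T)


# ---------------------------------------------------------------------------
# constitutive operations
# ---------------------------------------------------------------------------


def skin_phi_ref(
    G_core: float, G_skin: float, phi_core: float, beta: float = 9.0 / 4.0
) -> float:
    """Reference polymer fraction of the skin from the c*-theorem.

    ``phi_skin = phi_core * (G_skin/G_core)**(1/beta)``: a stiffer network is
    a denser one, with modulus scaling as concentration to the power beta.
    """
    if min(G_core, G_skin, phi_core, beta) <= 0:
        raise ValueError("all arguments must be positive")
    if G_skin < G_core:
        raise ValueError("skin must be at least as stiff as the core")
    out = phi_core * (G_skin / G_core) ** (1.0 / beta)
    if out >= 1.0:
        raise ValueError(
            f"phi_skin = {out:.4g} >= 1: modulus ratio too large for a swollen skin"
        )
    return out


def osmotic_pressure_mix(phi, layer: LayerSpec, gel: GelParams):
    """Cloizeaux osmotic mixing pressure ``Pi_mix = alpha G (phi/phi_ref)**beta`` [Pa]."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0) or np.any(phi >= 1):
        raise ValueError("phi must lie in (0, 1)")
    out = gel.alpha * layer.G * (phi / layer.phi_ref) ** gel.beta
    return out if out.ndim else float(out)


def pi_mix_phi_hat(phi_hat, G: float, gel: GelParams):
    """Pi_mix expressed in the swelling measure phi_hat (= lambda0^2 phi_tilde)."""
    return gel.alpha * G * (np.asarray(phi_hat, dtype=float) / gel.lambda0**2) ** gel.beta


def phi_hat_from_pi_mix(Pi, G: float, gel: GelParams):
    """Invert the Cloizeaux law for phi_hat (closed form; Pi in Pa)."""
    return gel.lambda0**2 * (np.asarray(Pi, dtype=float) / (gel.alpha * G)) ** (
        1.0 / gel.beta
    )


def _phi_hat(state: LocalState, layer: LayerSpec, gel: GelParams):
    return state.phi / (layer.phi0(gel) * gel.lambda0)


def cauchy_stress(state: LocalState, layer: LayerSpec, gel: GelParams):
    """Neo-Hookean Cauchy stress components (sigma_rr, sigma_thetatheta) [Pa].

    ``sigma_i = phi_hat G lambda_i^2 - p_liq``; with incompressibility this is
    ``sigma_rr = G lambda_r/(lambda_theta^2 lambda0) - p_liq`` and
    ``sigma_tt = G/(lambda_r lambda0) - p_liq``.
    """
    ph = _phi_hat(state, layer, gel)
    s_rr = ph * layer.G * state.lambda_r**2 - state.p_liq
    s_tt = ph * layer.G * state.lambda_theta**2 - state.p_liq
    return s_rr, s_tt


def piola_stress(state: LocalState, layer: LayerSpec, gel: GelParams):
    """First Piola stress components (S_RR, S_thetatheta) [Pa].

    Push-forward identities: ``S_RR = sigma_rr lambda_theta^2``,
    ``S_tt = sigma_tt lambda_theta lambda_r``.
    """
    lr, lt, p = state.lambda_r, state.lambda_theta, state.p_liq
    S_RR = layer.G * lr / gel.lambda0 - p * lt**2
    S_tt = layer.G * lt / gel.lambda0 - p * lt * lr
    return S_RR, S_tt


def chemical_potential(phi, p_liq, layer: LayerSpec, gel: GelParams):
    """Water chemical potential ``mu_w = -Pi_mix(phi) + p_liq`` [Pa = J/m^3]."""
    return -osmotic_pressure_mix(phi, layer, gel) + p_liq


def p_sat_tetens(T: float) -> float:
    """Saturated water-vapour pressure [Pa], Tetens relation (0..100 degC)."""
    T = float(T)
    if not 273.15 <= T <= 373.15:
        raise ValueError(f"Tetens relation valid for 273.15..373.15 K, got {T}")
    tc = T - 273.15
    return 610.78 * math.exp(17.27 * tc / (tc + 237.3))


def water_activity(mu_w, gel: GelParams, warn_supersaturated: bool = True):
    """Water activity ``a_w = exp(mu_w nu_w / (R T))``.

    ``mu_w`` here is the chemical potential measured from the reference at
    which a_w = 1; callers working with the absolute convention
    ``mu_w,ext = p0 - Pi_ext`` pass ``mu_w - p_ref`` (p_ref = p0 at the outer
    surface, p_gas at the cavity wall, matching the cavity equilibrium law).
    """
    a_w = np.exp(np.asarray(mu_w, dtype=float) * gel.nu_w / gel.RT)
    if warn_supersaturated and np.any(a_w > 1.0 + 1e-9):
        warnings.warn("water activity exceeds 1: supersaturated state", stacklevel=2)
    return a_w if a_w.ndim else float(a_w)


def activity_to_mu(a_w, gel: GelParams):
    """Inverse of :func:`water_activity`: ``mu_w = (RT/nu_w) ln a_w`` [Pa]."""
    return gel.RT / gel.nu_w * np.log(np.asarray(a_w, dtype=float))


def saturated_cavity(V_gas0: float, gel: GelParams) -> CavityState:
    """Initial cavity state: total pressure p0, saturated vapour (a_w = 1)."""
    ps = p_sat_tetens(gel.T)
    p_air0 = gel.p0 - ps
    if p_air0 <= 0:
        raise ValueError("p_sat exceeds ambient pressure: no air in the cavity")
    RT = gel.RT
    return CavityState(
        N_air=p_air0 * V_gas0 / RT,
        N_vap=ps * V_gas0 / RT,
        V_gas=V_gas0,
        p_air=p_air0,
        p_vap=ps,
        p_gas=gel.p0,
    )


def cavity_from_pressure(
    sigma_rr_inner: float,
    mu_w_inner: float,
    cavity: CavityState,
    gel: GelParams,
) -> CavityState:
    """Update the cavity from the mechanical state at the cavity wall.

    The traction balance fixes ``p_gas = -sigma_rr(r_in)``.  Vapour equilibrium
    with the gel bounding the cavity gives ``a_w = exp((mu_w(r_in) - p_gas)
    nu_w/RT)`` hence ``p_vap = a_w p_sat``; the air partial pressure follows by
    difference and, with ``N_air`` conserved, Gay-Lussac's law
    ``p_air V_gas = N_air R T`` yields the new gas volume and vapour moles.
    This is the update mode used by the co-moving finite-volume solver.
    """
    p_gas = -float(sigma_rr_inner)
    if p_gas <= 0:
        raise ValueError("nonphysical state: non-positive cavity gas pressure")
    a_w = water_activity(mu_w_inner - p_gas, gel, warn_supersaturated=False)
    p_vap = a_w * p_sat_tetens(gel.T)
    p_air = p_gas - p_vap
    if p_air <= 0:
        raise ValueError(
            "nonphysical state: vapour pressure exceeds total gas pressure"
        )
    RT = gel.RT
    V_gas = cavity.N_air * RT / p_air
    return CavityState(
        N_air=cavity.N_air,
        N_vap=p_vap * V_gas / RT,
        V_gas=V_gas,
        p_air=p_air,
        p_vap=p_vap,
        p_gas=p_gas,
    )
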