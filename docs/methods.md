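# Methods

`gelpore` models pore formation in a drying sphere of hydrogel — an idealised
fruit or vegetable piece — with a stiff elastic skin and a central cavity
filled with air and water vapour.  Moisture transport is strongly coupled to
large-deformation mechanics: the hydrostatic pressure that enforces
incompressibility enters both the stress and the water chemical potential, so
hindered shrinkage under a stiff skin places the core liquid under tension
and can inflate the cavity far beyond its initial size (the mechanism behind
porosity increase under case hardening).

## Model

**Kinematics.**  The computational reference frame is the free-swollen state
B0 (stress-free, in equilibrium with pure water, water activity a_w = 1).
Network chains are pre-stretched in B0: the unstretched configuration Bu is
reached by the uniform map with stretch 1/λ0, where λ0³ = 3/2 (a value that
holds across food gels independently of crosslink density).  The deformation
from B0 is F = diag(λ_r, λ_θ, λ_θ) under spherical symmetry, with
J = λ_r λ_θ² = φ0/φ; polymer fractions are φ0 (in B0), φ_ref = λ0³ φ0 (in
Bu) and φ (current).  Two derived measures recur: φ̃ = φ/φ_ref and
φ̂ = φ/(φ0 λ0) = λ0²·φ̃.

**Constitutive laws.**  The osmotic mixing pressure follows the Cloizeaux
scaling Π_mix = α G φ̃^(9/4) (the c*-theorem of deGennes maps food-gel
sorption onto this single master curve, with the modulus G as the only
material scale).  The network is Neo-Hookean measured from Bu:
σ_i = φ̂ G λ_i² − p_liq.  The water chemical potential (units Pa) is
μ_w = −Π_mix + p_liq; the Darcy-type flux is j_w = −(D_s ν_w/RT) ∇μ_w.
Mechanics is quasi-static (no inertia).

**Cavity.**  The cavity holds a fixed amount of air (N_air, set by the
saturated initial state at ambient pressure) plus water vapour exchanging
with the gel.  At the wall, −σ_rr = p_gas = p_air + p_vap with
p_air V_gas = N_air R T and p_vap = a_w·p_sat(T) (Tetens relation), where
a_w = exp((μ_w(r_in) − p_gas) ν_w/RT).

**Boundary conditions.**  Outer surface: σ_rr = −p0 and either a Dirichlet
potential μ_w = p0 − Π_ext (finite-volume solver) or a convective Robin flux
q = λ_θ² β_air (a_w,ext − RH_ext) c_sat with β_air = h_air/(ρ_air c_p,air)
from the Lewis relation (finite-element solver).  The two environment
descriptions are equivalent through RH_ext = exp(−Π_ext ν_w/RT).

**Choice of α.**  The package fixes α = λ0^(23/4) ≈ 2.17525.  This is the
unique value for which the free-swollen configuration is an exact fixed
point of the model's own laws: with λ = 1 and p_liq = G/λ0 + p0 the surface
traction is −p0 and μ_w = p0 simultaneously in both layers.  Any other α
would make the declared initial state a non-equilibrium and every transient
would begin with a spurious relaxation.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| λ0³ | 3/2 | – | free-swelling volume ratio |
| α | λ0^(23/4) ≈ 2.17525 | – | osmotic prefactor (see above) |
| β | 9/4 | – | Cloizeaux exponent |
| φ_core (reference) | 0.05 | – | core polymer fraction in Bu |
| φ_skin (reference) | φ_core (G_skin/G_core)^(4/9) | – | c*-theorem |
| G_core | 1.89·10⁵ | Pa | core shear modulus; back-derived so that Π_ext/G_core = 2000 corresponds to a_w ≈ 0.07 at 308 K |
| R_out | 5 | mm | outer radius; sets the length scale only |
| D_s | 10⁻⁹ | m²/s | water self-diffusivity; sets the time scale τ = R_out²/D_s = 2.5·10⁴ s |
| ν_w | 1.8·10⁻⁵ | m³/mol | water molar volume |
| T | 308.15 | K | temperature (338.15 K for the hot-air studies) |
| p0 | 101325 | Pa | ambient pressure |
| h_air | 20 | W/m²K | outer transfer coefficient (≈1 m/s air) |
| D_vap | 2.5·10⁻⁵ | m²/s | vapour diffusivity; β_cav = D_vap/(r_cav/5) |

Headline outputs are reported in the dimensionless groups Π_ext/G_core,
p_gas/p0, r/R_out, so the absolute values of G_core, R_out and D_s cancel
except through p0/G_core (which is why G_core's absolute value is pinned by
the a_w ≈ 0.07 anchor rather than left arbitrary).

## Solvers

**Analytic steady state** (`analytic_steady.core_shell_steady`).  Assumes φ
uniform within each layer.  The radial momentum balance then integrates in
closed form: the stress potential is σ(λ) = (G/(2λ0))(1 + 4xλ³)/(xλ⁴) + C
with x = λ0 φ̂, so the drop over a layer is p(inner) − p(outer) =
σ(Λ_outer) − σ(Λ_inner).  (The textbook form of this bracket, exposed as
`shell_pressure_drop`, corresponds to the convention J = 1/φ̂; the composed
solver uses the frame-consistent reparametrisation `layer_pressure_drop`,
without which the drop has the wrong sign and magnitude — it was validated
by convergence to the profile-resolving solver in the thin-shell limit.)
φ̂_skin solves the outer-surface equilibrium G φ̂ Λ_out² + Π_ext = Π_mix(φ̂);
φ̂_core solves the same relation at the interface with Π_ext replaced by
Π_ext + Δp_skin (the form that reduces exactly to the identity solution at
Π_ext = 0).  Radii follow from layer-wise incompressibility, and a secant
iteration (bracketed-scan fallback) on Λ_out closes the system against the
cavity gas law.  Validity: the per-layer-uniform-φ assumption is good to
≲0.5% on stretches for a single domain and low stiffness contrast, degrading
to ~3% on λ_θ and ~8% on p_gas at G_skin/G_core = 5 and beyond — it is the
fast scan tool, not the reference solution.

**Profile-resolving steady state** (`fv_solver.steady_state_secant`).  For a
trial Λ_out, the momentum balance is integrated inward in the material
coordinate (adaptive Runge–Kutta), with φ at every radius slaved to
pointwise chemical equilibrium with the environment (a warm-started Newton
solve of a strictly monotone scalar equation).  The mismatch between the
vapour pressure from the cavity gas law and from the equilibrium expression
drives a bracketed root solve on Λ_out.  Trial stretches may produce
nonphysical intermediate gas pressures; the residual is kept defined there
so the scan can bracket the root in the steep small-pore regime.  This
solver agrees with the finite-element steady limit to ~10⁻⁵ relative and is
the reference for scans (critical stiffness ratio, pore-size scan, maximum
growth factor).

**Transient finite volume** (`fv_solver.run_transient`).  Control volumes
are spherical shells riding on the polymer network (fixed polymer volume per
CV; water volume evolves).  Each step: (i) the cavity volume is made
self-consistent with the momentum integration by a scalar root solve — the
mechanics being quasi-static, volume and pressure must be equilibrated at
every instant, and a lagged explicit update of this pair is violently
unstable for stiff skins (volume and pressure leapfrog with gain > 1);
(ii) the vapour increment is evaporated from the innermost CV; (iii) Darcy
fluxes from central differences of μ_w between CV centres update the water
volumes by forward Euler.  The step size is the diffusion bound
dt = C·min(Δr²)·RT/(D_s ν_w max|∂Π_mix/∂φ_w|) with C = 0.2.  Polymer volume
per CV and N_air are conserved exactly by construction; in closed-system
mode total water (liquid + vapour liquid-equivalent) is conserved to 10⁻¹²
relative.

**Mixed finite elements** (`fe_solver.FeSolver`).  Weak form on the fixed
initial frame with quadratic displacement / linear pressure / linear
concentration (an inf-sup-stable Taylor–Hood-type pair); the pressure and
concentration spaces are split at the core/skin interface (the physical
liquid pressure jumps there along with λ_r), coupled only by a penalty-type
interface flux D_μ(μ_c − μ_s).  The force-balance term is assembled in the
divergence-consistent form ∫(S_RR ∂_R ũ + (2/R) S_θθ ũ) R² dR minus the
boundary term [S_RR ũ R²], with tractions S_RR = −p0 λ_θ² (outer) and
−p_gas λ_θ² (cavity wall; the sign flip at the inner boundary comes from the
outward normal pointing toward the centre).  This form makes the
free-swollen state stationary to 10⁻¹¹ and matches the finite-volume
momentum integration after push-forward.  The cavity vapour balance is a
scalar ODE dN_vap/dt = q_cav·4πR_in², which together with the core boundary
term R_in² q_cav conserves water exactly between gel and cavity.  Time
stepping is backward Euler with a monolithic damped Newton solve
(finite-difference Jacobian on scaled unknowns, reused across iterations,
tolerance 10⁻⁹ on the scaled residual; adaptive step halving/growth, default
cap τ/10, raised to τ/2 for steady-seeking runs).

**Interface permeance D_μ.**  A literally small permeance would throttle the
flux; D_μ is instead chosen as 100·D_s/(RT·h_min) (h_min the smallest
element), a penalty large enough that the chemical-potential jump at the
interface stays below ~0.2% of the drying potential scale while leaving the
conditioning of the Newton system intact.

## Numerical choices and degenerate inputs

* Π_ext = 0 with RH_ext = 1 short-circuits the steady solvers to the exact
  identity solution (the residual has a tangential, not transversal, zero
  there).
* The outer-equilibrium scalar equation can have two roots when the
  effective osmotic pressure at an interface is negative (layer under net
  hydration); the physical branch is the larger root, bracketed from the
  residual's interior maximum.
* Shell collapse (negative cube in the incompressibility relation) and
  element inversion (J ≤ 0) raise typed errors; the steady scans treat such
  trial states as inadmissible rather than fatal.
* Steady-state detection for transients: max|dφ_w/dt| < 10⁻¹⁰ s⁻¹ (solver
  default; the comparison runners use 10⁻⁹ s⁻¹, which changes steady p_gas
  by < 10⁻⁴ relative at the settings used).

## Problem sizes used by the shipped runners and tests

Comparison and acceptance runs use 16+4 control volumes (core+skin) for the
transient finite-volume solver, 16+6 elements for the finite-element solver
(8+4 in unit tests), and 201-point profiles from the steady integrator.
These resolutions put the discretisation error (≤ 0.03% on λ_θ between FV
transient and the steady reference; < 0.2% change in steady p_gas under
mesh doubling for FE) far below the 2%/5% agreement bands being tested.

## What the checks do and do not show

All validation here is internal consistency of the model and between its
three independently implemented solvers, plus reproduction of the reference
parameter studies (critical stiffness ratio ≈ 10 for pore opening; fivefold
growth of a 10% pore; quasi-steady gas pressure during slow drying;
monotone, positive limiting gas pressure for small pores).  The model treats
the tissue as an elastic hydrogel with constant moduli: real drying tissue
becomes viscoelastic and glassy as it dries (a_w ≲ 0.1), its skin forms
gradually rather than pre-existing, and evaporative cooling and
non-sphericity are ignored.  Agreement between solvers therefore validates
the implementation and the mathematics, not the constitutive adequacy of
the model for any particular foodstuff.

## Known limitations

* The analytic approximation is unreliable above stiffness contrast ~5
  (documented above); use the profile-resolving solver for quantitative
  work there.
* The explicit finite-volume transient is diffusion-limited in dt and
  becomes expensive for fine meshes or small pores (the small-pore regime
  stresses the cavity-consistency solve; the finite-element path is the
  practical tool there).
* Very severe drying (Π_ext/G_core approaching ~2000, a_w below ~0.07)
  corresponds to a glassy core where the constant-modulus assumption has no
  physical standing; the solvers converge there but the results should not
  be over-interpreted.
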