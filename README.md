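# gelpore

Pore formation in a drying core/shell hydrogel sphere — a coupled
moisture-transport / large-deformation model of an idealised fruit or
vegetable piece with a stiff elastic skin and a central air/vapour-filled
cavity.

When soft plant tissue dries behind a dense skin ("case hardening"), the
skin resists shrinkage, the liquid in the core is put under tension, and
pre-existing pores — intercellular spaces — can grow many times their
original size.  `gelpore` implements this physics for a spherical two-layer
hydrogel and is aimed at food-process and soft-matter modellers who want a
transparent, fully scriptable alternative to commercial multiphysics tools.

## Model in brief

The gel is an incompressible Neo-Hookean network swollen with water,
referenced to its free-swollen state (network pre-stretch λ0 with
λ0³ = 3/2).  With φ the polymer volume fraction, φ̂ = φ/(φ0 λ0) and
φ̃ = φ/φ_ref:

* stress σ_i = φ̂ G λ_i² − p_liq,
* osmotic mixing pressure Π_mix = α G φ̃^(9/4)  (Cloizeaux scaling; the
  skin density follows the c*-theorem, φ_skin = φ_core (G_skin/G_core)^(4/9)),
* chemical potential μ_w = −Π_mix + p_liq, driving the Darcy flux
  j_w = −(D_s ν_w / RT) ∇μ_w,
* cavity: fixed air moles (p_air V_gas = N_air RT), vapour in equilibrium
  with the gel at the wall (p_vap = a_w p_sat(T), Tetens relation), and
  −σ_rr(r_in) = p_gas = p_air + p_vap.

Drying is imposed through the external osmotic pressure Π_ext (equivalently
the relative humidity RH_ext = exp(−Π_ext ν_w/RT)).

Three mutually validating solvers share these laws: a closed-form
steady-state approximation (uniform swelling per layer), a transient
finite-volume scheme on a mesh co-moving with the polymer network, and a 1D
spherical mixed finite-element solver of the weak formulation (quadratic
displacement / linear pressure / linear concentration, backward Euler,
monolithic Newton).  See `docs/methods.md` for the full account.

## Worked example

Steady state of the reference case — skin twenty times stiffer than the
core, drying strength Π_ext/G_core = 20, initial pore at 60% of the outer
radius, 5% skin:

```python
from gelpore import make_problem, steady_state_secant

prob = make_problem(G_ratio=20, Pi_ext_over_G=20, R_in_frac=0.6, t_skin_frac=0.05)
sol = steady_state_secant(prob)
print(f"pore radius ratio r_in/R_in   = {sol.Lambda_in:.3f}")
print(f"outer shrinkage  r_out/R_out  = {sol.Lambda_out:.3f}")
print(f"cavity pressure  p_gas/p0     = {sol.p_gas/prob.gel.p0:.3f}")
print(f"  of which vapour p_vap [kPa] = {sol.p_vap/1e3:.2f}")
```

prints

```
pore radius ratio r_in/R_in   = 1.123
outer shrinkage  r_out/R_out  = 0.824
cavity pressure  p_gas/p0     = 0.721
  of which vapour p_vap [kPa] = 5.48
```

The gel as a whole has shrunk to 82% of its radius, yet the pore has *grown*
by 12%: the stiff skin carries the shrinkage, the cavity pressure has
dropped below ambient, and the pore is held open by the tension in the
core.  With a soft skin (`G_ratio=1`) the same call gives a pore smaller
than its initial size at above-ambient pressure — the skin is a
prerequisite for pore growth.  Bisecting the boundary between the two
regimes:

```bash
$ gelpore critical-ratio --out crit.csv
critical G_skin/G_core = 9.528
```

so the skin must be roughly ten times stiffer than the core before a dried
pore ends up larger than it began.

Other entry points: `gelpore steady-analytic | steady-fv | transient-fv |
transient-fe | compare | pore-scan | transient-study` (each takes a flat
YAML `--config`; keys and defaults in `gelpore.config`), or the library
functions `core_shell_steady`, `run_transient`, `run_transient_fe` and the
runners in `gelpore.orchestration`.

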