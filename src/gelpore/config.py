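"""Problem assembly and flat key-value configuration files.

A complete drying problem is a :class:`Problem`: gel constants, core and skin
layers, geometry and environment.  The config format is a flat YAML mapping in
SI units; ratios (``G_ratio``, ``Pi_ext_over_G``, ``R_in_frac``,
``t_skin_frac``) are the model's dimensionless groups from which absolute
values are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .constitutive import (
    Environment,
    GelParams,
    Geometry,
    LayerSpec,
    skin_phi_ref,
)

__all__ = ["Problem", "make_problem", "load_config", "problem_from_config"]

#: default core shear modulus [Pa]; back-derived so that Pi_ext/G_core = 2000
#: corresponds to a_w ~ 0.07 at 308 K.  Headline outputs are reported in the
#: scaled groups (Pi_ext/G_core, p_gas/p0, r/R_out) and are insensitive to the
#: absolute value except through p0/G_core.
G_CORE_DEFAULT = 1.89e5
#: default outer radius [m]; sets only the length/time scale.
R_OUT_DEFAULT = 5e-3
PHI_CORE_REF = 0.05

_DEFAULTS = dict(
    G_core=G_CORE_DEFAULT,
    G_ratio=20.0,
    t_skin_frac=0.05,
    R_in_frac=0.6,
    R_out=R_OUT_DEFAULT,
    Pi_ext_over_G=20.0,
    T=308.15,
    p0=101325.0,
    alpha=None,
    beta=9.0 / 4.0,
    lambda0_cubed=1.5,
    nu_w=1.8e-5,
    D_s=1e-9,
    h_air=20.0,
    D_vap=2.5e-5,
    RH_ext=None,
    phi_core=PHI_CORE_REF,
)


@dataclass(frozen=True)
class Problem:
    """A fully specified drying problem."""

    gel: GelParams
    core: LayerSpec
    skin: LayerSpec
    geom: Geometry
    env: Environment

    def layer_at(self, R: float) -> LayerSpec:
        """Layer containing initial-frame radius R (interface belongs to skin)."""
        return self.core if R < self.geom.R_m else self.skin


def make_problem(
    G_core: float = G_CORE_DEFAULT,
    G_ratio: float = 20.0,
    Pi_ext_over_G: float = 20.0,
    R_in_frac: float = 0.6,
    t_skin_frac: float = 0.05,
    R_out: float = R_OUT_DEFAULT,
    T: float = 308.15,
    phi_core: float = PHI_CORE_REF,
    alpha: float | None = None,
    beta: float = 9.0 / 4.0,
    lambda0_cubed: float = 1.5,
    nu_w: float = 1.8e-5,
    D_s: float = 1e-9,
    p0: float = 101325.0,
    h_air: float = 20.0,
    D_vap: float = 2.5e-5,
    RH_ext: float | None = None,
) -> Problem:
    """Assemble a :class:`Problem` from the model's dimensionless groups."""
    gel = GelParams(
        alpha=alpha,
        beta=beta,
        lambda0=lambda0_cubed ** (1.0 / 3.0),
        nu_w=nu_w,
        D_s=D_s,
        T=T,
        p0=p0,
    )
    G_skin = G_ratio * G_core
    core = LayerSpec(G=G_core, phi_ref=phi_core)
    skin = LayerSpec(G=G_skin, phi_ref=skin_phi_ref(G_core, G_skin, phi_core, beta))
    geom = Geometry(
        R_in=R_in_frac * R_out,
        R_m=(1.0 - t_skin_frac) * R_out,
        R_out=R_out,
    )
    env = Environment(
        Pi_ext=Pi_ext_over_G * G_core,
        RH_ext=RH_ext,
        h_air=h_air,
        D_vap=D_vap,
    )
    return Problem(gel=gel, core=core, skin=skin, geom=geom, env=env)


def load_config(path: str | Path) -> dict:
    """Read a flat key-value config file (YAML mapping), applying defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    return cfg


def problem_from_config(path: str | Path) -> Problem:
    return make_problem(**load_config(path))
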