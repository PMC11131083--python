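"""Experiment runners: cross-solver comparison, parameter scans, transients.

All runners are deterministic and report results in the scaled groups
(``Pi_ext/G_core``, ``p_gas/p0``, ``r/R_out``) so that the absolute defaults
(G_core, R_out, D_s) cancel wherever the underlying claims are ratio-based.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .analytic_steady import SteadySolution, core_shell_steady
from .config import Problem, make_problem
from .fe_solver import run_transient_fe
from .fv_solver import profile_frame, run_transient, steady_state_secant

__all__ = [
    "ExperimentSpec",
    "steady_by_solver",
    "compare_solvers",
    "critical_ratio_scan",
    "pore_size_scan",
    "transient_study",
]

SOLVERS = ("analytic", "fv", "fv-transient", "fe")


@dataclass
class ExperimentSpec:
    """A parameter grid over the model's dimensionless groups."""

    solvers: tuple[str, ...] = ("analytic", "fv")
    G_ratio: tuple[float, ...] = (20.0,)
    Pi_over_G: tuple[float, ...] = (20.0,)
    R_in_frac: tuple[float, ...] = (0.6,)
    t_skin_frac: tuple[float, ...] = (0.05,)
    T: tuple[float, ...] = (308.15,)
    extra: dict = field(default_factory=dict)

    def points(self):
        for combo in itertools.product(
            self.G_ratio, self.Pi_over_G, self.R_in_frac, self.t_skin_frac, self.T
        ):
            yield dict(
                zip(("G_ratio", "Pi_ext_over_G", "R_in_frac", "t_skin_frac", "T"), combo)
            )


def _steady_from_profile(df: pd.DataFrame, problem: Problem, p_gas: float) -> SteadySolution:
    geom, gel = problem.geom, problem.gel
    core = df[df.layer == "core"]
    skin = df[df.layer == "skin"]
    return SteadySolution(
        Lambda_in=float(df.r.iloc[0] / df.R.iloc[0]),
        Lambda_m=float(np.interp(geom.R_m, df.R, df.r)) / geom.R_m,
        Lambda_out=float(df.r.iloc[-1] / df.R.iloc[-1]),
        phi_hat_core=float(
            np.mean((1.0 - core.phi_w) / (problem.core.phi0(gel) * gel.lambda0))
        ),
        phi_hat_skin=float(
            np.mean((1.0 - skin.phi_w) / (problem.skin.phi0(gel) * gel.lambda0))
        ),
        dp_core=math.nan,
        dp_skin=math.nan,
        p_gas=p_gas,
        p_vap=math.nan,
        p_air=math.nan,
        r_in=float(df.r.iloc[0]),
        r_out=float(df.r.iloc[-1]),
        profile={
            "R": df.R.to_numpy(),
            "lambda_theta": df.lambda_theta.to_numpy(),
            "lambda_r": df.lambda_r.to_numpy(),
            "sigma_rr": df.sigma_rr.to_numpy(),
        },
    )


def steady_by_solver(
    problem: Problem,
    solver: str,
    fv_mesh: tuple[int, int] = (16, 4),
    fe_mesh: tuple[int, int] = (16, 6),
    t_end_tau: float = 100.0,
    steady_tol: float = 1e-9,
) -> SteadySolution:
    """Steady state via the requested solver.

    ``fv-transient`` and ``fe`` run their transients to the steady-detection
    tolerance; the others solve the steady problem directly.
    """
    tau = problem.geom.R_out**2 / problem.gel.D_s
    if solver == "analytic":
        return core_shell_steady(problem)
    if solver == "fv":
        return steady_state_secant(problem)
    if solver == "fv-transient":
        traj, st = run_transient(
            problem,
            t_end=t_end_tau * tau,
            n_core=fv_mesh[0],
            n_skin=fv_mesh[1],
            steady_tol=steady_tol,
        )
        return _steady_from_profile(
            profile_frame(st, problem), problem, float(traj.p_gas[-1])
        )
    if solver == "fe":
        from .fe_solver import FeSolver

        fe = FeSolver(
            problem, n_core=fe_mesh[0], n_skin=fe_mesh[1], dt_max_frac=0.5
        )
        traj, s, fe = run_transient_fe(
            problem,
            t_end=t_end_tau * tau,
            steady_tol=steady_tol,
            solver=fe,
            record_every_step=False,
        )
        return _steady_from_profile(
            fe.profile_frame(s), problem, float(traj.p_gas[-1])
        )
    raise ValueError(f"unknown solver {solver!r}; choose from {SOLVERS}")


def compare_solvers(
    spec: ExperimentSpec, problem_kwargs: dict | None = None
) -> pd.DataFrame:
    """Run the selected solvers on every grid point and tabulate deviations.

    For each pair of solvers the hoop-stretch profiles are interpolated onto
    a common initial-frame grid and the maximum relative deviation recorded,
    along with the relative gas-pressure deviation.  Solver failures are
    recorded per point, not fatal.
    """
    if len(spec.solvers) < 2:
        raise ValueError("need at least two solvers to compare")
    base = dict(problem_kwargs or {})
    rows = []
    for pt in spec.points():
        problem = make_problem(**{**base, **pt})
        sols: dict[str, SteadySolution | None] = {}
        errors: dict[str, str] = {}
        for sv in spec.solvers:
            try:
                sols[sv] = steady_by_solver(problem, sv, **spec.extra)
            except Exception as exc:  # recorded, not fatal
                sols[sv] = None
                errors[sv] = f"{type(exc).__name__}: {exc}"
        row = dict(pt)
        R_common = np.linspace(problem.geom.R_in, problem.geom.R_out, 200)
        for a, b in itertools.combinations(spec.solvers, 2):
            key = f"{a}|{b}"
            if sols[a] is None or sols[b] is None:
                row[f"dev_lambda_theta[{key}]"] = math.nan
                row[f"dev_p_gas[{key}]"] = math.nan
                continue
            Ra, la = sols[a].lambda_theta_profile(problem)
            Rb, lb = sols[b].lambda_theta_profile(problem)
            la_i = np.interp(R_common, Ra, la)
            lb_i = np.interp(R_common, Rb, lb)
            row[f"dev_lambda_theta[{key}]"] = float(
                np.max(np.abs(la_i - lb_i) / np.abs(lb_i))
            )
            row[f"dev_p_gas[{key}]"] = float(
                abs(sols[a].p_gas - sols[b].p_gas) / abs(sols[b].p_gas)
            )
        for sv in spec.solvers:
            if sols[sv] is not None:
                row[f"p_gas_over_p0[{sv}]"] = sols[sv].p_gas / problem.gel.p0
                row[f"Lambda_in[{sv}]"] = sols[sv].Lambda_in
        if errors:
            row["errors"] = "; ".join(f"{k}: {v}" for k, v in errors.items())
        rows.append(row)
    return pd.DataFrame(rows)


def critical_ratio_scan(
    Pi_ext_over_G: float = 20.0,
    R_in_frac: float = 0.6,
    t_skin_frac: float = 0.05,
    T: float = 308.15,
    solver: str = "analytic",
    bracket: tuple[float, float] = (2.0, 40.0),
    xtol: float = 0.25,
    problem_kwargs: dict | None = None,
) -> tuple[float, pd.DataFrame]:
    """Critical skin/core stiffness ratio for pore opening.

    Bisects ``G_skin/G_core`` for the condition ``p_gas = p0`` (equivalently
    ``-sigma_rr(r_in)/p0 - 1 = 0``, i.e. steady ``r_in = R_in``): below the
    threshold the dried pore is compressed below its initial size, above it
    the skin carries the shrinkage and the pore opens.  Returns the threshold
    and the scan table.
    """
    base = dict(problem_kwargs or {})
    records = []

    def gap(G_ratio: float) -> float:
        problem = make_problem(
            G_ratio=G_ratio,
            Pi_ext_over_G=Pi_ext_over_G,
            R_in_frac=R_in_frac,
            t_skin_frac=t_skin_frac,
            T=T,
            **base,
        )
        sol = steady_by_solver(problem, solver)
        records.append(
            {
                "G_ratio": G_ratio,
                "p_gas_over_p0": sol.p_gas / problem.gel.p0,
                "Lambda_in": sol.Lambda_in,
            }
        )
        return sol.p_gas - problem.gel.p0

    lo, hi = bracket
    f_lo, f_hi = gap(lo), gap(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change of p_gas - p0 over bracket {bracket}: "
            f"({f_lo:.3g}, {f_hi:.3g})"
        )
    threshold = brentq(gap, lo, hi, xtol=xtol)
    table = (
        pd.DataFrame(records)
        .drop_duplicates("G_ratio")
        .sort_values("G_ratio")
        .reset_index(drop=True)
    )
    return float(threshold), table


def pore_size_scan(
    R_in_fracs=(0.6, 0.4, 0.3, 0.2, 0.1, 0.05, 0.03),
    Pi_ext_over_G: float = 20.0,
    G_ratio: float = 20.0,
    t_skin_frac: float = 0.05,
    solver: str = "fv",
    problem_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Steady gas pressure versus initial pore size.

    With a stiff skin the gas pressure decreases monotonically with the
    initial pore radius and approaches a small positive limiting value (no
    sign of unbounded pore-growth instability).  Failures are recorded.
    """
    base = dict(problem_kwargs or {})
    rows = []
    for frac in R_in_fracs:
        row = {"R_in_frac": frac}
        try:
            problem = make_problem(
                G_ratio=G_ratio,
                Pi_ext_over_G=Pi_ext_over_G,
                R_in_frac=frac,
                t_skin_frac=t_skin_frac,
                **base,
            )
            sol = steady_by_solver(problem, solver)
            row.update(
                p_gas_over_p0=sol.p_gas / problem.gel.p0,
                Lambda_in=sol.Lambda_in,
                r_in_over_R_out=sol.r_in / problem.geom.R_out,
            )
        except Exception as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def transient_study(
    spec: ExperimentSpec,
    t_end_tau: float = 100.0,
    steady_tol: float = 1e-9,
    fe_mesh: tuple[int, int] = (16, 6),
    problem_kwargs: dict | None = None,
):
    """Run FE transients over the grid; returns (summary frame, trajectories)."""
    base = dict(problem_kwargs or {})
    rows, trajs = [], {}
    for pt in spec.points():
        problem = make_problem(**{**base, **pt})
        tau = problem.geom.R_out**2 / problem.gel.D_s
        key = tuple(sorted(pt.items()))
        row = dict(pt)
        try:
            traj, s, fe = run_transient_fe(
                problem,
                t_end=t_end_tau * tau,
                n_core=fe_mesh[0],
                n_skin=fe_mesh[1],
                steady_tol=steady_tol,
            )
            trajs[key] = traj
            row.update(
                steady=traj.steady,
                p_gas_over_p0=traj.p_gas[-1] / problem.gel.p0,
                p_air_over_p0=traj.p_air[-1] / problem.gel.p0,
                p_vap_over_p0=traj.p_vap[-1] / problem.gel.p0,
                r_in_over_R_in=traj.r_in[-1] / problem.geom.R_in,
                r_out_over_R_out=traj.r_out[-1] / problem.geom.R_out,
            )
        except Exception as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows), trajs
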