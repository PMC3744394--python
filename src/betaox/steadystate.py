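"""Steady-state location by root-finding on the ODE right-hand side.

Steady states are found by setting all time derivatives to zero and solving
the resulting nonlinear system, seeded with the endpoint of a time
simulation.  Conserved moieties make the raw system rank-deficient, so for
each unbroken moiety the derivative equation of a representative species
(CoASH for the CoA moiety, free matrix carnitine for the carnitine moiety)
is replaced by the corresponding conservation constraint.

A converged solution satisfies max |d/dt| < 1e-11 uM min^-1 across all
variable species, where the derivative is taken of each species'
assay-volume concentration (amount per litre of total assay volume,
d(c_i V_i)/dt = (N v)_i).  This is the volume-free reading of the
convergence criterion: per-compartment concentration derivatives are the
same quantity divided by a volume fraction, which for the mitochondrial
matrix (V_MAT ~ 5e-4) would amplify double-precision cancellation noise in
the rate sums above the criterion itself.  Different initial conditions
must lead to the same fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root as _scipy_root

from .dynamics import CompiledModel, default_initial_state
from .kinetics import ParameterSet
from .network import NetworkModel, conserved_moieties

__all__ = [
    "SteadyStateResult",
    "SteadyStateError",
    "solve_steady_state",
    "continuation_scan",
    "scan_frame",
]

RESIDUAL_TOL = 1e-11
SEED_MINUTES = 200.0


class SteadyStateError(RuntimeError):
    """Root-finding failed; carries the best residual reached."""

    def __init__(self, message: str, best_residual: float | None = None) -> None:
        super().__init__(message)
        self.best_residual = best_residual


@dataclass
class SteadyStateResult:
    """A fixed point with per-reaction fluxes and diagnostics."""

    model: NetworkModel
    params: ParameterSet
    state: np.ndarray                  # uM, variable species order
    fluxes: np.ndarray                 # uM/min (assay), reaction order
    residual: float                    # max |d/dt| in uM/min
    converged: bool
    seed_provenance: str
    jacobian_det_sign: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def concentration(self, name: str) -> float:
        return float(self.state[self.model.index[name]])

    def flux_of(self, reaction_name: str) -> float:
        names = [r.name for r in self.model.reactions]
        return float(self.fluxes[names.index(reaction_name)])

    @property
    def beta_ox_flux(self) -> float:
        """Oxygen-equivalent beta-oxidation flux (NADH + FADH2 production)/2."""
        j_nadh = j_fadh2 = 0.0
        for v, r in zip(self.fluxes, self.model.reactions):
            if r.enzyme in ("MSCHAD", "MTP"):
                j_nadh += v
            if r.enzyme in ("VLCAD", "LCAD", "MCAD", "SCAD"):
                j_fadh2 += v
        return 0.5 * (j_nadh + j_fadh2)

    @property
    def coash(self) -> float:
        if "CoASH_m" in self.model.index:
            return self.concentration("CoASH_m")
        return float(self.model.variant.clamped_species.get("CoASH_m", np.nan))

    @property
    def total_coa_esters(self) -> float:
        """Sum of all matrix CoA esters (everything CoA-bound except CoASH)."""
        total = 0.0
        for i, s in enumerate(self.model.species):
            if s.name in ("CoASH_m",):
                continue
            if s.species_class.value in (
                "acylCoA", "enoylCoA", "hydroxyacylCoA", "ketoacylCoA", "acetylCoA"
            ) and s.compartment.value == "m":
                total += self.state[i]
        return float(total)

    def to_series(self) -> pd.Series:
        return pd.Series(self.state, index=self.model.species_names())


def _false_transient_seed(compiled: CompiledModel, pseudo_minutes: float) -> np.ndarray:
    """Endpoint of a volume-equalized ("false transient") time simulation.

    Fixed points satisfy N v = 0 and are independent of the compartment
    volumes; the physical transient, however, relaxes the extramitochondrial
    pools a factor V_extra/V_MAT (~2000) more slowly than the matrix.
    Integrating d y/dt = N v — the same system with all compartment volumes
    set equal — reaches the neighbourhood of the same fixed point in a few
    hundred pseudo-minutes and makes a good root-finder seed.
    """
    from scipy.integrate import solve_ivp

    model = compiled.network
    y0 = default_initial_state(model, compiled.params)

    def rhs(t, y):
        return model.N @ compiled.rates(compiled.full_concentrations(y, t))

    sol = solve_ivp(rhs, (0.0, pseudo_minutes), y0, method="BDF",
                    t_eval=[pseudo_minutes], rtol=1e-10, atol=1e-12)
    if not sol.success:
        return y0
    return np.clip(sol.y[:, -1], 0.0, None)


def _constrained_system(compiled: CompiledModel, seed: np.ndarray):
    """Residual function with moiety rows replaced by conservation constraints."""
    model = compiled.network
    replacements: list[tuple[int, np.ndarray, float]] = []
    representative = {"CoA": "CoASH_m", "carnitine_matrix": "carnitine_m"}
    for m in conserved_moieties(model):
        if m.get("weights") is None or m["broken"]:
            continue
        rep = representative.get(m["name"])
        if rep is None or rep not in model.index:
            continue
        if m["name"] == "CoA":
            # the conserved CoA total is a model parameter; the carnitine
            # total is set by the initial conditions carried in the seed
            total = float(compiled.params.coa_total)
        else:
            total = float(m["weights"] @ seed)
        replacements.append((model.index[rep], m["weights"], total))

    def fun(y: np.ndarray) -> np.ndarray:
        f = compiled.amount_rhs(0.0, y)
        for i, w, total in replacements:
            f[i] = w @ y - total
        return f

    return fun, replacements


_LOG_FLOOR = 1e-20


#: Conversion weight folding a conservation-constraint violation (uM) into
#: the residual metric (uM/min): 1e-5 uM off-total counts like 1e-11 uM/min.
_CONSTRAINT_WEIGHT = 1e-6


def _newton_polish(compiled: CompiledModel, fun, y: np.ndarray,
                   constraints=(), max_iter: int = 60) -> tuple[np.ndarray, float]:
    """Damped-Newton polish in log-concentration space.

    Steady-state concentrations are strictly positive away from degenerate
    boundaries, but span many orders of magnitude (the M/SCHAD equilibrium
    keeps ketoacyl pools far below their hydroxyacyl partners), which makes
    linear-space Newton steps overshoot into negative territory.  Working on
    x = log(y) preserves positivity and equilibrates the scales.  Returns
    the iterate with the smallest combined residual: max |d/dt| plus any
    conservation-constraint violation (fixed points form a family along the
    moiety totals, so the dynamical residual alone cannot pin the totals).
    """
    n = len(y)
    x = np.log(np.maximum(y, _LOG_FLOOR))

    def F(x_: np.ndarray) -> np.ndarray:
        return fun(np.exp(x_))

    def metric(y_: np.ndarray) -> float:
        res = float(np.max(np.abs(compiled.amount_rhs(0.0, y_))))
        for _, w, total in constraints:
            res = max(res, abs(float(w @ y_ - total)) * _CONSTRAINT_WEIGHT)
        return res

    best_y = y.copy()
    best_res = metric(y)
    f = F(x)
    for _ in range(max_iter):
        normf = np.linalg.norm(f)
        if normf == 0.0:
            break
        J = np.empty((n, n))
        for k in range(n):
            h = 1e-7
            xk = x.copy()
            xk[k] += h
            J[:, k] = (F(xk) - f) / h
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -f, rcond=None)
        # cap the log-step to keep the damping line search effective
        smax = np.max(np.abs(step))
        if smax > 5.0:
            step *= 5.0 / smax
        lam, improved = 1.0, False
        for _ in range(12):
            x_new = x + lam * step
            f_new = F(x_new)
            if np.linalg.norm(f_new) < normf:
                x, f = x_new, f_new
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
        y_cur = np.exp(x)
        res = metric(y_cur)
        if res < best_res:
            best_res, best_y = res, y_cur
        if best_res < 0.1 * RESIDUAL_TOL:
            break
    return best_y, best_res


def solve_steady_state(model: NetworkModel, params: ParameterSet,
                       seed: np.ndarray | None = None,
                       tol: float = RESIDUAL_TOL,
                       seed_minutes: float = SEED_MINUTES) -> SteadyStateResult:
    """Locate a steady state under constant boundary conditions.

    The default seed is the endpoint of a ``seed_minutes``-long integration
    from the default initial state; if polishing from that endpoint fails,
    a five-fold longer integration is tried once before failing loudly.
    """
    compiled = CompiledModel(model, params)
    provenance = "user seed"
    attempts = []
    if seed is not None:
        attempts.append(("user seed", np.asarray(seed, dtype=float), None))
    attempts.append(("trajectory endpoint", None, seed_minutes))
    attempts.append(("trajectory endpoint (5x)", None, 5 * seed_minutes))

    best_res = np.inf
    for provenance, y_seed, minutes in attempts:
        if y_seed is None:
            y_seed = _false_transient_seed(compiled, minutes)
        fun, replacements = _constrained_system(compiled, y_seed)
        y, res = _newton_polish(compiled, fun, y_seed, replacements)
        if res >= tol:
            # fall back on a trust-region solve, then re-polish
            sol = _scipy_root(fun, y, method="hybr", options={"xtol": 1e-13})
            if sol.success or np.linalg.norm(fun(sol.x)) < np.linalg.norm(fun(y)):
                y2, res2 = _newton_polish(compiled, fun, np.abs(sol.x), replacements)
                if res2 < res:
                    y, res = y2, res2
        best_res = min(best_res, res)
        if res < tol:
            if np.min(y) < -1e-9:
                i = int(np.argmin(y))
                raise SteadyStateError(
                    f"negative concentration {y[i]:.3e} uM for "
                    f"{model.species[i].name} at the root", best_residual=res
                )
            y = np.clip(y, 0.0, None)
            c = compiled.full_concentrations(y.copy())
            fluxes = compiled.rates(c)
            det_sign = _jacobian_det_sign(compiled, fun, y)
            return SteadyStateResult(
                model=model, params=params, state=y, fluxes=fluxes,
                residual=res, converged=True, seed_provenance=provenance,
                jacobian_det_sign=det_sign,
                diagnostics={"seed_minutes": minutes},
            )
    raise SteadyStateError(
        f"steady-state root-finding did not reach max|d/dt| < {tol:g} "
        f"(best residual {best_res:.3e} uM/min)", best_residual=best_res
    )


def _jacobian_det_sign(compiled: CompiledModel, fun, y: np.ndarray) -> float:
    n = len(y)
    f = fun(y)
    J = np.empty((n, n))
    for k in range(n):
        h = 1e-7 * max(abs(y[k]), 1e-3)
        yk = y.copy()
        yk[k] += h
        J[:, k] = (fun(yk) - f) / h
    sign, _ = np.linalg.slogdet(J)
    return float(sign)


def continuation_scan(model: NetworkModel, params: ParameterSet,
                      boundary_species: str, values,
                      tol: float = RESIDUAL_TOL) -> list[SteadyStateResult]:
    """Natural-parameter continuation along a boundary concentration.

    Each converged solution seeds the next value.  On failure at one value a
    fresh trajectory-endpoint seed is tried there; if that also fails the
    scan stops and the partial branch is returned with a ``failure_index``
    attribute on the raised error.
    """
    results: list[SteadyStateResult] = []
    seed = None
    for k, value in enumerate(values):
        p = ParameterSet(
            vmax=params.vmax, keq=params.keq, km=params.km,
            ki_malonyl=params.ki_malonyl, k1_acesink=params.k1_acesink,
            v_mat=params.v_mat, coa_total=params.coa_total,
            boundaries={**params.boundaries, boundary_species: float(value)},
            initial=params.initial,
        )
        try:
            res = solve_steady_state(model, p, seed=seed, tol=tol)
        except SteadyStateError as exc:
            exc.failure_index = k  # type: ignore[attr-defined]
            exc.partial_results = results  # type: ignore[attr-defined]
            raise
        results.append(res)
        seed = res.state
    return results


def scan_frame(results: list[SteadyStateResult], boundary_species: str) -> pd.DataFrame:
    """Summary table of a continuation scan."""
    rows = []
    for r in results:
        rows.append(
            {
                boundary_species: r.params.boundaries[boundary_species],
                "flux_o2_equiv": r.beta_ox_flux,
                "CoASH": r.coash,
                "total_CoA_esters": r.total_coa_esters,
                "residual": r.residual,
            }
        )
    return pd.DataFrame(rows)
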