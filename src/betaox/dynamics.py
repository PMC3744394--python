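"""ODE right-hand side assembly and time integration.

The state vector holds the variable species concentrations (uM, each in its
own compartment) in ``NetworkModel.species`` order.  Rates are expressed per
litre of total assay volume, so

    d[x]/dt = (sum_j N_xj * v_j) / V(compartment of x)

with V the compartment volume fraction.  Boundary species are clamped at
their configured concentrations, optionally time-dependent through an
:class:`InputProfile` for the titrated substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .kinetics import ParameterSet, RateContext, reaction_rate
from .network import Compartment, ConfigurationError, NetworkModel, conserved_moieties

__all__ = [
    "InputProfile",
    "CompiledModel",
    "SimulationResult",
    "SolverError",
    "build_rhs",
    "integrate",
    "default_initial_state",
]


class SolverError(RuntimeError):
    """Stiff integration failed; carries the failure time and worst state."""


@dataclass(frozen=True)
class InputProfile:
    """Time-dependent clamp for the titrated substrate.

    Monotone piecewise-cubic (PCHIP) interpolation between samples with
    constant extrapolation beyond the last sample; times in minutes,
    concentrations in uM.
    """

    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    species: str = "palmitoylCoA_e"
    kind: str = "pchip"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ConfigurationError("input profile times must be strictly increasing")
        if np.any(c < 0):
            raise ConfigurationError("input profile concentrations must be >= 0")
        if self.kind == "pchip":
            interp = PchipInterpolator(t, c, extrapolate=False)
        elif self.kind == "linear":
            interp = lambda x: np.interp(x, t, c)  # noqa: E731
        else:
            raise ConfigurationError(f"unknown interpolation kind {self.kind!r}")
        object.__setattr__(self, "_interp", interp)

    def __call__(self, t) -> np.ndarray | float:
        t = np.clip(t, self.times[0], self.times[-1])
        return np.maximum(np.nan_to_num(self._interp(t)), 0.0)

    @classmethod
    def from_csv(cls, path, species: str = "palmitoylCoA_e") -> "InputProfile":
        df = pd.read_csv(path)
        t, c = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
        return cls(times=tuple(t), concentrations=tuple(c), species=species)


class CompiledModel:
    """Network + parameters compiled to fast rate / RHS evaluation.

    Precomputes index arrays for the shared competitive denominators (one
    per enzyme pool) and per-reaction parameter bindings, then evaluates all
    56 reaction rates with plain float arithmetic.
    """

    def __init__(self, network: NetworkModel, params: ParameterSet,
                 input_profile: InputProfile | None = None) -> None:
        self.network = network
        self.params = params
        self.input_profile = input_profile
        self.n_var = network.n_species
        names = [s.name for s in network.species] + [s.name for s in network.boundary]
        self.all_names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.volumes = network.compartment_volumes(params.v_mat)

        variant = network.variant
        boundary_values = {}
        for s in network.boundary:
            if s.name in variant.clamped_species:
                boundary_values[s.name] = variant.clamped_species[s.name]
            elif s.name in params.boundaries:
                boundary_values[s.name] = params.boundaries[s.name]
            else:
                raise ConfigurationError(f"no clamped concentration for boundary {s.name}")
        if variant.malonyl_coa and "malonylCoA_e" in boundary_values:
            boundary_values["malonylCoA_e"] = variant.malonyl_coa
        if "NAD_m" in boundary_values and "NADH_m" in boundary_values:
            total = boundary_values["NAD_m"] + boundary_values["NADH_m"]
            r = variant.nad_ratio
            if variant.nad_sum_preserved:
                boundary_values["NAD_m"] = total * r / (1.0 + r)
                boundary_values["NADH_m"] = total / (1.0 + r)
        boundary_values.update(variant.boundary_overrides)
        self.boundary_values = boundary_values
        self._c = np.zeros(len(names))
        for name, value in boundary_values.items():
            self._c[self.index[name]] = value
        if input_profile is not None and input_profile.species not in self.index:
            raise ConfigurationError(
                f"input species {input_profile.species!r} not in the network"
            )
        if input_profile is not None and input_profile.species not in self.boundary_values:
            raise ConfigurationError(
                f"input species {input_profile.species!r} must be clamped (boundary) "
                "to follow an input profile"
            )
        self._input_idx = (
            self.index[input_profile.species] if input_profile is not None else None
        )
        self._compile()

    # -- compilation -------------------------------------------------------
    def _compile(self) -> None:
        from .kinetics import ester_pair

        net, p = self.network, self.params
        idx = self.index
        pool_members: dict[str, list[tuple[int, float]]] = {}
        for r in net.reactions:
            if r.rate_law_kind == "sink":
                continue
            members = pool_members.setdefault(r.pool_id, [])
            s, pr = ester_pair(r)
            if s is not None:
                members.append((idx[s], 1.0 / p.km_of(r.enzyme, r.chain_length, s)))
            if pr is not None:
                members.append((idx[pr], 1.0 / p.km_of(r.enzyme, r.chain_length, pr)))
        self._pools = {
            pid: (np.array([i for i, _ in mem]), np.array([w for _, w in mem]))
            for pid, mem in pool_members.items()
        }

        self._records: list[tuple] = []
        for r in net.reactions:
            kind = r.rate_law_kind
            if kind == "sink":
                self._records.append(("sink", idx["acetylCoA_m"], p.k1_acesink * p.v_mat))
                continue
            e, n = r.enzyme, r.chain_length
            vmax = p.vmax[e] * r.dedicated_fraction
            keq = p.keq_of(e, n)
            s_name, p_name = ester_pair(r)
            i_s = idx[s_name]
            i_p = idx[p_name] if p_name is not None else -1
            km_s = p.km_of(e, n, s_name)
            pid = r.pool_id
            if kind == "cpt1_inhibited":
                rec = ("cpt1", vmax, keq, i_s, i_p, km_s,
                       p.km_of(e, n, p_name),
                       idx["carnitine_e"], p.km_of(e, None, "carnitine_e"),
                       idx["CoASH_e"], p.km_of(e, None, "CoASH_e"),
                       idx["malonylCoA_e"], p.ki_malonyl, pid)
            elif kind == "antiporter":
                rec = ("cact", vmax, keq, i_s, i_p, km_s,
                       idx["carnitine_m"], p.km_of(e, n, "carnitine_m"),
                       idx["carnitine_e"], p.km_of(e, n, "carnitine_e"), pid)
            elif kind == "mtp_lumped":
                rec = ("mtp", vmax, keq, i_s, i_p, km_s,
                       idx["NAD_m"], p.km_of(e, None, "NAD_m"),
                       idx["NADH_m"], p.km_of(e, None, "NADH_m"),
                       idx["CoASH_m"], p.km_of(e, None, "CoASH_m"),
                       idx["acetylCoA_m"], p.km_of(e, None, "acetylCoA_m"), pid)
            elif e in ("VLCAD", "LCAD", "MCAD", "SCAD", "crotonase"):
                rec = ("uni", vmax, keq, i_s, i_p, km_s, pid)
            elif e == "MSCHAD":
                rec = ("nadlinked", vmax, keq, i_s, i_p, km_s,
                       idx["NAD_m"], p.km_of(e, n, "NAD_m"),
                       idx["NADH_m"], p.km_of(e, n, "NADH_m"), pid)
            elif e == "CPT2":
                rec = ("cpt2", vmax, keq, i_s, i_p, km_s,
                       idx["CoASH_m"], p.km_of(e, n, "CoASH_m"),
                       idx["carnitine_m"], p.km_of(e, n, "carnitine_m"), pid)
            elif e == "MCKAT":
                rec = ("mckat", vmax, keq, i_s, i_p, km_s,
                       idx["CoASH_m"], p.km_of(e, n, "CoASH_m"),
                       idx["acetylCoA_m"], pid)
            else:  # pragma: no cover - guarded by network construction
                raise ConfigurationError(f"no compiled law for {r.name}")
            self._records.append(rec)

    # -- evaluation --------------------------------------------------------
    def full_concentrations(self, y: np.ndarray, t: float = 0.0) -> np.ndarray:
        c = self._c
        c[: self.n_var] = y
        if self._input_idx is not None:
            c[self._input_idx] = float(self.input_profile(t))
        return c

    def rates(self, c: np.ndarray) -> np.ndarray:
        """All reaction rates (uM min^-1, assay volume) at concentrations c."""
        denom = {pid: 1.0 + float(c[ix] @ w) for pid, (ix, w) in self._pools.items()}
        v = np.empty(len(self._records))
        for j, rec in enumerate(self._records):
            kind = rec[0]
            if kind == "uni":
                _, vmax, keq, i_s, i_p, km_s, pid = rec
                v[j] = vmax * (c[i_s] - c[i_p] / keq) / (km_s * denom[pid])
            elif kind == "nadlinked":
                (_, vmax, keq, i_s, i_p, km_s,
                 i_nad, km_nad, i_nadh, km_nadh, pid) = rec
                nad, nadh = c[i_nad], c[i_nadh]
                dcof = 1.0 + nad / km_nad + nadh / km_nadh
                v[j] = vmax * (c[i_s] * nad - c[i_p] * nadh / keq) / (
                    km_s * km_nad * denom[pid] * dcof
                )
            elif kind == "cpt2":
                (_, vmax, keq, i_s, i_p, km_s,
                 i_coa, km_coa, i_carn, km_carn, pid) = rec
                coa, carn = c[i_coa], c[i_carn]
                dcof = 1.0 + coa / km_coa + carn / km_carn
                v[j] = vmax * (c[i_s] * coa - c[i_p] * carn / keq) / (
                    km_s * km_coa * denom[pid] * dcof
                )
            elif kind == "mckat":
                _, vmax, keq, i_s, i_p, km_s, i_coa, km_coa, i_ace, pid = rec
                coa, ace = c[i_coa], c[i_ace]
                dcof = 1.0 + coa / km_coa
                prod = ace * ace if i_p < 0 else c[i_p] * ace
                v[j] = vmax * (c[i_s] * coa - prod / keq) / (
                    km_s * km_coa * denom[pid] * dcof
                )
            elif kind == "mtp":
                (_, vmax, keq, i_s, i_p, km_s, i_nad, km_nad, i_nadh, km_nadh,
                 i_coa, km_coa, i_ace, km_ace, pid) = rec
                nad, nadh, coa, ace = c[i_nad], c[i_nadh], c[i_coa], c[i_ace]
                dnad = 1.0 + nad / km_nad + nadh / km_nadh
                dcoa = 1.0 + coa / km_coa + ace / km_ace
                num = c[i_s] * nad * coa - c[i_p] * ace * nadh / keq
                v[j] = vmax * num / (km_s * km_nad * km_coa * denom[pid] * dnad * dcoa)
            elif kind == "cact":
                (_, vmax, keq, i_s, i_p, km_s,
                 i_cm, km_cm, i_ce, km_ce, pid) = rec
                cm, ce = c[i_cm], c[i_ce]
                dcarn = 1.0 + cm / km_cm + ce / km_ce
                v[j] = vmax * (c[i_s] * cm - c[i_p] * ce / keq) / (
                    km_s * km_cm * denom[pid] * dcarn
                )
            elif kind == "cpt1":
                (_, vmax, keq, i_s, i_p, km_s, km_p, i_carn, km_carn,
                 i_coa, km_coa, i_mal, ki, pid) = rec
                s, pr = c[i_s], c[i_p]
                carn, coa, mal = c[i_carn], c[i_coa], c[i_mal]
                dacyl = 1.0 + s / km_s + pr / km_p + mal / ki
                dcof = 1.0 + carn / km_carn + coa / km_coa
                v[j] = vmax * (s * carn - pr * coa / keq) / (
                    km_s * km_carn * dacyl * dcof
                )
            else:  # sink
                _, i_ace, k = rec
                v[j] = k * c[i_ace]
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if len(y) != self.n_var:
            raise ConfigurationError(
                f"state length {len(y)} does not match {self.n_var} variable species"
            )
        c = self.full_concentrations(np.asarray(y, dtype=float), t)
        v = self.rates(c)
        return (self.network.N @ v) / self.volumes

    def amount_rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Derivatives of the assay-volume concentrations, d(c_i V_i)/dt = N v
        (uM min^-1 per litre assay; volume-free)."""
        c = self.full_concentrations(np.asarray(y, dtype=float), t)
        return self.network.N @ self.rates(c)

    # -- reference-path cross-check ----------------------------------------
    def rates_reference(self, c_map: dict[str, float]) -> np.ndarray:
        """Slow dict-based evaluation through the kinetics module (used by
        tests to pin the compiled path to the written rate laws)."""
        out = np.empty(self.network.n_reactions)
        for j, r in enumerate(self.network.reactions):
            ctx = RateContext(self.network, self.params, r, c_map)
            out[j] = reaction_rate(ctx)
        return out


def build_rhs(model: NetworkModel, params: ParameterSet,
              input_profile: InputProfile | None = None):
    """Derivative function ``f(t, state) -> d(state)/dt`` for the network."""
    return CompiledModel(model, params, input_profile).rhs


def default_initial_state(model: NetworkModel, params: ParameterSet) -> np.ndarray:
    """All esters zero; CoASH at the conserved total; carnitine and any other
    species at their configured initial concentrations."""
    y0 = np.zeros(model.n_species)
    if "CoASH_m" in model.index:
        y0[model.index["CoASH_m"]] = params.coa_total
    for name, value in params.initial.items():
        if name in model.index:
            y0[model.index[name]] = value
    return y0


@dataclass
class SimulationResult:
    """Trajectories, fluxes and conservation diagnostics of one simulation."""

    model: NetworkModel
    params: ParameterSet
    t: np.ndarray
    y: np.ndarray                      # (n_var, nt)
    fluxes: np.ndarray                 # (n_reactions, nt)
    moieties: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def species_names(self) -> list[str]:
        return self.model.species_names()

    def series(self, name: str) -> np.ndarray:
        return self.y[self.model.index[name]]

    def flux(self, reaction_name: str) -> np.ndarray:
        names = [r.name for r in self.model.reactions]
        return self.fluxes[names.index(reaction_name)]

    def moiety_drift(self, name: str) -> float:
        """Maximum relative drift of a conserved moiety over the run."""
        series = self.moieties[name]
        ref = series[0]
        if ref == 0:
            return float(np.max(np.abs(series)))
        return float(np.max(np.abs(series - ref) / abs(ref)))

    def exported_c2(self) -> np.ndarray:
        """Cumulative C2 units exported by the acetyl-CoA sink (uM assay)."""
        sink = [j for j, r in enumerate(self.model.reactions) if r.rate_law_kind == "sink"]
        if not sink:
            return np.zeros_like(self.t)
        v = self.fluxes[sink[0]]
        out = np.zeros_like(self.t)
        out[1:] = np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(self.t))
        return out

    def concentrations_frame(self) -> pd.DataFrame:
        """Tidy (time, species, compartment, concentration) table."""
        rows = []
        for i, s in enumerate(self.model.species):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.t,
                        "species": s.name,
                        "compartment": s.compartment.value,
                        "concentration": self.y[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def fluxes_frame(self) -> pd.DataFrame:
        rows = []
        for j, r in enumerate(self.model.reactions):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.t,
                        "enzyme": r.enzyme,
                        "chain": r.chain_length if r.chain_length is not None else 0,
                        "rate": self.fluxes[j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def integrate(model: NetworkModel, params: ParameterSet,
              y0: np.ndarray | None = None,
              t_span: tuple[float, float] = (0.0, 24.0),
              input_profile: InputProfile | None = None,
              t_eval: np.ndarray | None = None,
              rtol: float = 1e-8, atol: float = 1e-9,
              method: str = "BDF") -> SimulationResult:
    """Integrate the stiff ODE system over ``t_span`` (minutes).

    The default output grid spans the experimental sampling window at
    0.1-minute resolution.  Concentrations marginally below zero (above
    -1e-9 uM) are clipped on reporting; larger negativity raises
    :class:`SolverError`.
    """
    compiled = CompiledModel(model, params, input_profile)
    if y0 is None:
        y0 = default_initial_state(model, params)
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 < 0):
        raise ConfigurationError("initial concentrations must be >= 0")
    if input_profile is not None:
        lo, hi = input_profile.times[0], input_profile.times[-1]
        if t_span[0] < lo or t_span[1] > hi:
            raise ConfigurationError(
                f"t_span {t_span} outside input-profile domain [{lo}, {hi}]"
            )
    if t_eval is None:
        t_eval = np.arange(t_span[0], t_span[1] + 1e-9, 0.1)

    sol = solve_ivp(compiled.rhs, t_span, y0, method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        y_end = sol.y[:, -1] if sol.y.size else y0
        worst = int(np.argmax(np.abs(compiled.rhs(sol.t[-1] if sol.t.size else 0.0, y_end))))
        raise SolverError(
            f"integration failed at t={sol.t[-1] if sol.t.size else t_span[0]:.4g} min; "
            f"worst-scaled state: {model.species[worst].name} ({sol.message})"
        )
    y = sol.y
    if np.min(y) < -1e-9:
        i, k = np.unravel_index(np.argmin(y), y.shape)
        raise SolverError(
            f"negative concentration {y[i, k]:.3e} uM for {model.species[i].name} "
            f"at t={sol.t[k]:.3g} min"
        )
    y = np.clip(y, 0.0, None)

    fluxes = np.empty((model.n_reactions, len(sol.t)))
    for k, tk in enumerate(sol.t):
        fluxes[:, k] = compiled.rates(compiled.full_concentrations(y[:, k].copy(), tk))

    moieties = {}
    for m in conserved_moieties(model):
        if m.get("weights") is None or m.get("broken"):
            continue
        moieties[m["name"]] = m["weights"] @ y

    return SimulationResult(
        model=model, params=params, t=sol.t, y=y, fluxes=fluxes, moieties=moieties,
        diagnostics={"nfev": sol.nfev, "njev": sol.njev, "nlu": sol.nlu,
                     "method": method, "rtol": rtol, "atol": atol},
    )
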