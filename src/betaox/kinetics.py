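"""Rate laws: reversible, saturable kinetics with shared competitive denominators.

Every enzyme-catalysed reaction is reversible and zero exactly at its
thermodynamic equilibrium (mass-action ratio equal to Keq).  Enzymes that
accept several chain lengths carry one shared competitive denominator that
sums the occupancy of *all* ester substrates and products the enzyme binds;
this term couples the parallel reactions and is the origin of the
feedforward competitive inhibition studied with this model.  Cofactor
couples (NAD+/NADH, CoASH/carnitine) sit in separate binding factors, not in
the ester competition sum.  FAD is enzyme-bound: its redox state is folded
into the dehydrogenase Vmax values.

Conventions: concentrations in uM (per litre of the species' own
compartment), time in minutes, rates in uM min^-1 per litre of total assay
volume, volumes as fractions of the assay volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .network import (
    DEHYDROGENASES,
    ConfigurationError,
    NetworkModel,
    ReactionSpec,
    validate_microscopic_reversibility,
)

__all__ = [
    "ParameterSet",
    "RateContext",
    "DomainError",
    "ester_pair",
    "reaction_rate",
    "rate_reversible_mm_competitive",
    "rate_cpt1",
    "rate_mtp",
    "rate_shuttle",
    "rate_sink",
    "validate_parameters",
    "rate_law_registry",
]


class DomainError(ValueError):
    """Rate evaluation outside its domain (negative concentration)."""


@dataclass
class ParameterSet:
    """All kinetic constants, volumes, totals and boundary concentrations.

    ``vmax``: enzyme -> maximal rate (uM min^-1, assay volume).
    ``keq``: (enzyme, chain) -> dimensionless equilibrium constant in the
    beta-oxidation direction.
    ``km``: (enzyme, chain-or-None, species name) -> Michaelis constant (uM);
    chain ``None`` marks constants shared across an enzyme's chain range.
    ``ki_malonyl``: competitive inhibition constant of malonyl-CoA on CPT1.
    ``k1_acesink``: first-order acetyl-CoA drain (min^-1, matrix).
    ``v_mat``: matrix volume fraction of the assay (extramitochondrial
    fraction is 1 - v_mat).
    ``coa_total``: conserved matrix CoA moiety total (uM).
    ``boundaries``: clamped concentrations (uM); experimental conditions,
    not counted as model parameters.
    ``initial``: default initial concentrations for otherwise-zero species.
    """

    vmax: dict[str, float]
    keq: dict[tuple[str, int], float]
    km: dict[tuple[str, int | None, str], float]
    ki_malonyl: float
    k1_acesink: float
    v_mat: float
    coa_total: float
    boundaries: dict[str, float] = field(default_factory=dict)
    initial: dict[str, float] = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        """Counted model parameters (boundaries and initials excluded)."""
        return len(self.vmax) + len(self.keq) + len(self.km) + 4

    @property
    def v_extra(self) -> float:
        return 1.0 - self.v_mat

    # -- lookup helpers ----------------------------------------------------
    def km_of(self, enzyme: str, chain: int | None, species: str) -> float:
        try:
            return self.km[(enzyme, chain, species)]
        except KeyError:
            try:
                return self.km[(enzyme, None, species)]
            except KeyError:
                raise ConfigurationError(
                    f"missing Km for enzyme {enzyme!r}, chain {chain!r}, species {species!r}"
                ) from None

    def keq_of(self, enzyme: str, chain: int) -> float:
        try:
            return self.keq[(enzyme, chain)]
        except KeyError:
            raise ConfigurationError(
                f"missing Keq for enzyme {enzyme!r}, chain {chain!r}"
            ) from None

    # -- flat parameter vector (sensitivity analysis) ----------------------
    def flatten(self, include_boundaries: bool = False) -> dict[str, float]:
        flat: dict[str, float] = {}
        for enzyme, v in self.vmax.items():
            flat[f"Vmax_{enzyme}"] = v
        for (enzyme, chain), v in self.keq.items():
            flat[f"Keq_{enzyme}_C{chain}"] = v
        for (enzyme, chain, species), v in self.km.items():
            tag = f"C{chain}" if chain is not None else "all"
            flat[f"Km_{enzyme}_{tag}_{species}"] = v
        flat["Ki_malonylCoA"] = self.ki_malonyl
        flat["K1acesink"] = self.k1_acesink
        flat["V_MAT"] = self.v_mat
        flat["CoA_total"] = self.coa_total
        if include_boundaries:
            for name, v in self.boundaries.items():
                flat[f"boundary_{name}"] = v
        return flat

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Return a copy with one flattened parameter replaced."""
        if name.startswith("Vmax_"):
            enzyme = name[5:]
            if enzyme not in self.vmax:
                raise KeyError(name)
            return replace(self, vmax={**self.vmax, enzyme: value})
        if name.startswith("Keq_"):
            enzyme, _, chain = name[4:].rpartition("_C")
            key = (enzyme, int(chain))
            if key not in self.keq:
                raise KeyError(name)
            return replace(self, keq={**self.keq, key: value})
        if name.startswith("Km_"):
            for key in self.km:
                enzyme, chain, species = key
                tag = f"C{chain}" if chain is not None else "all"
                if name == f"Km_{enzyme}_{tag}_{species}":
                    return replace(self, km={**self.km, key: value})
            raise KeyError(name)
        if name == "Ki_malonylCoA":
            return replace(self, ki_malonyl=value)
        if name == "K1acesink":
            return replace(self, k1_acesink=value)
        if name == "V_MAT":
            return replace(self, v_mat=value)
        if name == "CoA_total":
            return replace(self, coa_total=value)
        if name.startswith("boundary_"):
            species = name[len("boundary_"):]
            if species not in self.boundaries:
                raise KeyError(name)
            return replace(self, boundaries={**self.boundaries, species: value})
        raise KeyError(name)


@dataclass
class RateContext:
    """Evaluation context for one reaction instance: network wiring (which
    species the enzyme binds), parameter bindings and a concentration map."""

    network: NetworkModel
    params: ParameterSet
    reaction: ReactionSpec
    conc: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.conc.items():
            if value < 0:
                raise DomainError(f"negative concentration for {name}: {value}")

    def c(self, name: str) -> float:
        return float(self.conc[name])


def ester_pair(reaction: ReactionSpec) -> tuple[str | None, str | None]:
    """(substrate, product) ester species of a reaction instance.

    These are the chain-indexed species whose occupancy enters the shared
    competitive denominator.  MCKAT at C4 has no ester product (acetyl-CoA
    occupancy is neglected); the sink has neither.
    """
    e, n = reaction.enzyme, reaction.chain_length
    if e == "CPT1":
        return "palmitoylCoA_e", "acylcarnitine_C16_e"
    if e == "CACT":
        return f"acylcarnitine_C{n}_e", f"acylcarnitine_C{n}_m"
    if e == "CPT2":
        return f"acylcarnitine_C{n}_m", f"acylCoA_C{n}_m"
    if e in DEHYDROGENASES:
        return f"acylCoA_C{n}_m", f"enoylCoA_C{n}_m"
    if e == "crotonase":
        return f"enoylCoA_C{n}_m", f"hydroxyacylCoA_C{n}_m"
    if e == "MSCHAD":
        return f"hydroxyacylCoA_C{n}_m", f"ketoacylCoA_C{n}_m"
    if e == "MCKAT":
        return f"ketoacylCoA_C{n}_m", (f"acylCoA_C{n - 2}_m" if n > 4 else None)
    if e == "MTP":
        return f"enoylCoA_C{n}_m", f"acylCoA_C{n - 2}_m"
    return None, None


def _competing_reactions(ctx: RateContext) -> list[ReactionSpec]:
    """Reactions sharing this reaction's enzyme pool (the Sigma-term scope)."""
    pid = ctx.reaction.pool_id
    return [r for r in ctx.network.reactions if r.pool_id == pid]


def _ester_denominator(ctx: RateContext) -> float:
    d = 1.0
    for r in _competing_reactions(ctx):
        s, p = ester_pair(r)
        if s is not None:
            d += ctx.c(s) / ctx.params.km_of(r.enzyme, r.chain_length, s)
        if p is not None:
            d += ctx.c(p) / ctx.params.km_of(r.enzyme, r.chain_length, p)
    return d


def rate_reversible_mm_competitive(ctx: RateContext) -> float:
    """Reversible Michaelis-Menten rate with shared competitive denominator.

    Covers CPT2, the four acyl-CoA dehydrogenases, crotonase, M/SCHAD and
    MCKAT.  Redox- or CoA-coupled variants carry the cofactor couple in the
    numerator mass-action difference and in a separate binding factor.
    Positive in the beta-oxidation direction; exactly zero when the
    mass-action ratio equals Keq.
    """
    r = ctx.reaction
    p_ = ctx.params
    e, n = r.enzyme, r.chain_length
    vmax = p_.vmax[e] * r.dedicated_fraction
    keq = p_.keq_of(e, n)
    s_name, p_name = ester_pair(r)
    s = ctx.c(s_name)
    km_s = p_.km_of(e, n, s_name)
    d_ester = _ester_denominator(ctx)

    if e in DEHYDROGENASES or e == "crotonase":
        p = ctx.c(p_name)
        return vmax * (s - p / keq) / (km_s * d_ester)

    if e == "MSCHAD":
        p = ctx.c(p_name)
        nad, nadh = ctx.c("NAD_m"), ctx.c("NADH_m")
        km_nad = p_.km_of(e, n, "NAD_m")
        km_nadh = p_.km_of(e, n, "NADH_m")
        d_cof = 1.0 + nad / km_nad + nadh / km_nadh
        return vmax * (s * nad - p * nadh / keq) / (km_s * km_nad * d_ester * d_cof)

    if e == "CPT2":
        p = ctx.c(p_name)
        coash, carn = ctx.c("CoASH_m"), ctx.c("carnitine_m")
        km_coash = p_.km_of(e, n, "CoASH_m")
        km_carn = p_.km_of(e, n, "carnitine_m")
        d_cof = 1.0 + coash / km_coash + carn / km_carn
        return vmax * (s * coash - p * carn / keq) / (km_s * km_coash * d_ester * d_cof)

    if e == "MCKAT":
        coash = ctx.c("CoASH_m")
        ace = ctx.c("acetylCoA_m")
        km_coash = p_.km_of(e, n, "CoASH_m")
        d_cof = 1.0 + coash / km_coash
        if n == 4:
            num = s * coash - ace * ace / keq
        else:
            num = s * coash - ctx.c(p_name) * ace / keq
        return vmax * num / (km_s * km_coash * d_ester * d_cof)

    raise ConfigurationError(f"{e} is not handled by the competitive reversible MM law")


def rate_cpt1(ctx: RateContext) -> float:
    """CPT1 rate with competitive malonyl-CoA inhibition.

    Malonyl-CoA adds [malonyl-CoA]/Ki to the acyl-binding denominator; at
    zero malonyl-CoA the law reduces exactly to the uninhibited reversible
    competitive form.
    """
    p_ = ctx.params
    vmax = p_.vmax["CPT1"] * ctx.reaction.dedicated_fraction
    keq = p_.keq_of("CPT1", 16)
    s = ctx.c("palmitoylCoA_e")
    p = ctx.c("acylcarnitine_C16_e")
    carn, coash = ctx.c("carnitine_e"), ctx.c("CoASH_e")
    mal = ctx.c("malonylCoA_e")
    km_s = p_.km_of("CPT1", 16, "palmitoylCoA_e")
    km_p = p_.km_of("CPT1", 16, "acylcarnitine_C16_e")
    km_carn = p_.km_of("CPT1", None, "carnitine_e")
    km_coash = p_.km_of("CPT1", None, "CoASH_e")
    d_acyl = 1.0 + s / km_s + p / km_p + mal / p_.ki_malonyl
    d_cof = 1.0 + carn / km_carn + coash / km_coash
    return vmax * (s * carn - p * coash / keq) / (km_s * km_carn * d_acyl * d_cof)


def rate_shuttle(ctx: RateContext) -> float:
    """CACT antiport: acyl-carnitine in, free carnitine out (reversible).

    All chain lengths compete for the translocase; net export of matrix
    acyl-carnitines appears as a negative import rate.
    """
    r = ctx.reaction
    p_ = ctx.params
    n = r.chain_length
    vmax = p_.vmax["CACT"] * r.dedicated_fraction
    keq = p_.keq_of("CACT", n)
    s_name, p_name = ester_pair(r)
    ae, am = ctx.c(s_name), ctx.c(p_name)
    cm, ce = ctx.c("carnitine_m"), ctx.c("carnitine_e")
    km_ae = p_.km_of("CACT", n, s_name)
    km_cm = p_.km_of("CACT", n, "carnitine_m")
    km_ce = p_.km_of("CACT", n, "carnitine_e")
    d_acar = _ester_denominator(ctx)
    d_carn = 1.0 + cm / km_cm + ce / km_ce
    return vmax * (ae * cm - am * ce / keq) / (km_ae * km_cm * d_acar * d_carn)


def rate_mtp(ctx: RateContext) -> float:
    """Lumped MTP rate: hydratase + dehydrogenase + thiolase in one step.

    The hydroxy- and ketoacyl intermediates are channelled between active
    sites and never free in the matrix, so they appear in no denominator and
    in no state variable of this flux.  The overall Keq equals the product of
    the crotonase-branch equilibrium constants (microscopic reversibility).
    """
    r = ctx.reaction
    p_ = ctx.params
    n = r.chain_length
    if n is None or n < 8:
        raise ConfigurationError(f"MTP does not accept chain length {n}")
    vmax = p_.vmax["MTP"] * r.dedicated_fraction
    keq = p_.keq_of("MTP", n)
    s_name, p_name = ester_pair(r)
    s, p = ctx.c(s_name), ctx.c(p_name)
    nad, nadh = ctx.c("NAD_m"), ctx.c("NADH_m")
    coash, ace = ctx.c("CoASH_m"), ctx.c("acetylCoA_m")
    km_s = p_.km_of("MTP", n, s_name)
    km_nad = p_.km_of("MTP", None, "NAD_m")
    km_nadh = p_.km_of("MTP", None, "NADH_m")
    km_coash = p_.km_of("MTP", None, "CoASH_m")
    km_ace = p_.km_of("MTP", None, "acetylCoA_m")
    d_ester = _ester_denominator(ctx)
    d_nad = 1.0 + nad / km_nad + nadh / km_nadh
    d_coa = 1.0 + coash / km_coash + ace / km_ace
    num = s * nad * coash - p * ace * nadh / keq
    return vmax * num / (km_s * km_nad * km_coash * d_ester * d_nad * d_coa)


def rate_sink(ctx: RateContext) -> float:
    """First-order acetyl-CoA drain regenerating CoASH.

    d[acetyl-CoA]/dt receives -K1acesink * [acetyl-CoA] (matrix units); the
    assay-volume rate therefore carries a factor V_MAT.
    """
    return ctx.params.k1_acesink * ctx.c("acetylCoA_m") * ctx.params.v_mat


_DISPATCH = {
    "reversible_mm_competitive": rate_reversible_mm_competitive,
    "cpt1_inhibited": rate_cpt1,
    "antiporter": rate_shuttle,
    "mtp_lumped": rate_mtp,
    "sink": rate_sink,
}


def reaction_rate(ctx: RateContext) -> float:
    """Evaluate one reaction rate (uM min^-1, assay volume)."""
    return _DISPATCH[ctx.reaction.rate_law_kind](ctx)


def rate_law_registry() -> dict[str, str]:
    """Machine-readable registry of the rate-law templates (documentation)."""
    return {
        "reversible_mm_competitive": (
            "Vmax * (S*cof_s - P*cof_p/Keq) / "
            "(Km_S * Km_cof_s * (1 + sum_i S_i/Km_S_i + sum_j P_j/Km_P_j) * D_cof)"
        ),
        "cpt1_inhibited": (
            "Vmax * (palmCoA*carnitine - palmcarnitine*CoASH/Keq) / "
            "(Km_palmCoA * Km_carnitine * "
            "(1 + palmCoA/Km_palmCoA + palmcarnitine/Km_palmcarnitine + malonylCoA/Ki) * "
            "(1 + carnitine/Km_carnitine + CoASH/Km_CoASH))"
        ),
        "antiporter": (
            "Vmax * (acylcar_out*carn_in - acylcar_in*carn_out/Keq) / "
            "(Km_acylcar_out * Km_carn_in * (1 + sum_n acylcar_out_n/Km + acylcar_in_n/Km) * "
            "(1 + carn_in/Km_carn_in + carn_out/Km_carn_out))"
        ),
        "mtp_lumped": (
            "Vmax * (enoyl*NAD*CoASH - acyl*acetylCoA*NADH/Keq) / "
            "(Km_enoyl * Km_NAD * Km_CoASH * (1 + sum_n enoyl_n/Km + acyl_n/Km) * "
            "(1 + NAD/Km_NAD + NADH/Km_NADH) * (1 + CoASH/Km_CoASH + acetylCoA/Km_acetylCoA))"
        ),
        "sink": "K1acesink * acetylCoA * V_MAT",
    }


# ---------------------------------------------------------------------------
# validation

def required_km_keys(reaction: ReactionSpec) -> list[tuple[str, int | None, str]]:
    """Km keys a reaction instance needs (chain-specific or shared)."""
    e, n = reaction.enzyme, reaction.chain_length
    s_name, p_name = ester_pair(reaction)
    keys: list[tuple[str, int | None, str]] = []
    if s_name is not None:
        keys.append((e, n, s_name))
    if p_name is not None:
        keys.append((e, n, p_name))
    if e == "CPT1":
        keys += [(e, None, "carnitine_e"), (e, None, "CoASH_e")]
    elif e == "CACT":
        keys += [(e, n, "carnitine_m"), (e, n, "carnitine_e")]
    elif e == "CPT2":
        keys += [(e, n, "CoASH_m"), (e, n, "carnitine_m")]
    elif e == "MSCHAD":
        keys += [(e, n, "NAD_m"), (e, n, "NADH_m")]
    elif e == "MCKAT":
        keys += [(e, n, "CoASH_m")]
    elif e == "MTP":
        keys += [(e, None, "NAD_m"), (e, None, "NADH_m"),
                 (e, None, "CoASH_m"), (e, None, "acetylCoA_m")]
    return keys


def validate_parameters(params: ParameterSet, network: NetworkModel,
                        microrev_rtol: float = 1e-2) -> list[str]:
    """Run all load-time validators; return the aggregated list of problems.

    Checks positivity of every constant, completeness of the Km bindings for
    each reaction in the network, the Haldane-implied reverse capacity
    (finite and positive, automatic for a positive parameterization) and
    microscopic reversibility between the crotonase branch and MTP.
    """
    problems: list[str] = []
    for enzyme, v in params.vmax.items():
        if not v > 0:
            problems.append(f"Vmax_{enzyme} must be > 0 (got {v})")
    for (enzyme, chain), v in params.keq.items():
        if not v > 0:
            problems.append(f"Keq_{enzyme}_C{chain} must be > 0 (got {v})")
    for (enzyme, chain, species), v in params.km.items():
        tag = f"C{chain}" if chain is not None else "all"
        if not v > 0:
            problems.append(f"Km_{enzyme}_{tag}_{species} must be > 0 (got {v})")
    if not params.ki_malonyl > 0:
        problems.append(f"Ki_malonylCoA must be > 0 (got {params.ki_malonyl})")
    if not params.k1_acesink > 0:
        problems.append(f"K1acesink must be > 0 (got {params.k1_acesink})")
    if not 0 < params.v_mat < 1:
        problems.append(f"V_MAT must be in (0, 1) (got {params.v_mat})")
    if not params.coa_total > 0:
        problems.append(f"CoA_total must be > 0 (got {params.coa_total})")
    for name, v in params.boundaries.items():
        if v < 0:
            problems.append(f"boundary concentration {name} must be >= 0 (got {v})")

    for r in network.reactions:
        if r.rate_law_kind == "sink":
            continue
        if r.chain_length is not None and (r.enzyme, r.chain_length) not in params.keq:
            problems.append(f"missing Keq for {r.name}")
        for key in required_km_keys(r):
            enzyme, chain, species = key
            if key not in params.km and (enzyme, None, species) not in params.km:
                problems.append(f"missing Km for {r.name}: species {species}")

    if not problems:
        report = validate_microscopic_reversibility(
            params, network.specificity, rtol=microrev_rtol
        )
        for check in report["checks"]:
            if not check["passed"]:
                problems.append(
                    "microscopic reversibility violated at C{chain}: "
                    "branch product {branch_product:.6g} vs lumped {lumped:.6g}".format(**check)
                )
    return problems
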