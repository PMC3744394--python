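"""Reaction-network assembly for mitochondrial fatty-acid beta-oxidation.

The network spans even-chain saturated acyl esters (C4-C16) distributed over
two compartments (mitochondrial matrix and extramitochondrial space).  Acyl
esters of different chain lengths share enzymes with overlapping specificity;
the carnitine shuttle (CPT1 / CACT / CPT2) connects the compartments, a set of
four acyl-CoA dehydrogenases feeds two parallel routes for enoyl-CoA
conversion (the free-intermediate "crotonase branch" and the channelled,
lumped MTP reaction), and a first-order sink drains acetyl-CoA while
regenerating free CoA (mimicking citrate synthase + malate dehydrogenase in
the validation experiments).

With the default chain-length specificity the standard configuration yields
exactly 45 variable species and 56 reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "CHAINS",
    "DEFAULT_SPECIFICITY",
    "BOUNDARY_SPECIES",
    "SpeciesClass",
    "Compartment",
    "MetaboliteSpec",
    "ReactionSpec",
    "ModelVariant",
    "NetworkModel",
    "NetworkError",
    "ConfigurationError",
    "build_network",
    "stoichiometric_matrix",
    "conserved_moieties",
    "validate_microscopic_reversibility",
]

#: Even chain lengths handled by the model (carbons of the acyl group).
CHAINS: tuple[int, ...] = (4, 6, 8, 10, 12, 14, 16)

#: Chain-length specificity of each enzyme.  CPT1 is restricted to palmitoyl
#: CoA (C16); C4 and C6 enoyl esters are uniquely handled by the crotonase
#: branch (MTP starts at C8); the four dehydrogenases jointly cover C4-C16.
DEFAULT_SPECIFICITY: dict[str, tuple[int, ...]] = {
    "CPT1": (16,),
    "CACT": CHAINS,
    "CPT2": CHAINS,
    "VLCAD": (12, 14, 16),
    "LCAD": (8, 10, 12, 14, 16),
    "MCAD": (6, 8, 10, 12),
    "SCAD": (4, 6),
    "crotonase": CHAINS,
    "MSCHAD": CHAINS,
    "MCKAT": CHAINS,
    "MTP": (8, 10, 12, 14, 16),
}

DEHYDROGENASES: tuple[str, ...] = ("VLCAD", "LCAD", "MCAD", "SCAD")

#: Species whose concentrations are clamped in the standard configuration.
#: Extramitochondrial palmitoyl-CoA is the titrated substrate; carnitine and
#: CoASH outside the membrane are buffered by the medium; malonyl-CoA is the
#: CPT1 inhibitor; the matrix NAD+/NADH couple is held at a fixed ratio
#: (default 15) and fixed sum.  FAD is enzyme-bound and folded into the
#: dehydrogenase Vmax values.
BOUNDARY_SPECIES: tuple[str, ...] = (
    "palmitoylCoA_e",
    "carnitine_e",
    "CoASH_e",
    "malonylCoA_e",
    "NAD_m",
    "NADH_m",
)


class NetworkError(ValueError):
    """Structural inconsistency in an assembled network."""


class ConfigurationError(ValueError):
    """Invalid specificity ranges, variants or parameter bindings."""


class SpeciesClass(str, Enum):
    acylCoA = "acylCoA"
    enoylCoA = "enoylCoA"
    hydroxyacylCoA = "hydroxyacylCoA"
    ketoacylCoA = "ketoacylCoA"
    acylcarnitine = "acylcarnitine"
    acetylCoA = "acetylCoA"
    CoASH = "CoASH"
    carnitine = "carnitine"
    NAD = "NAD"
    NADH = "NADH"
    malonylCoA = "malonylCoA"


class Compartment(str, Enum):
    matrix = "m"
    extramitochondrial = "e"


#: Species classes that are indexed by a chain length.
CHAIN_CLASSES = frozenset(
    {
        SpeciesClass.acylCoA,
        SpeciesClass.enoylCoA,
        SpeciesClass.hydroxyacylCoA,
        SpeciesClass.ketoacylCoA,
        SpeciesClass.acylcarnitine,
    }
)

#: Species classes carrying the CoA moiety (weight 1 each).
COA_CLASSES = frozenset(
    {
        SpeciesClass.acylCoA,
        SpeciesClass.enoylCoA,
        SpeciesClass.hydroxyacylCoA,
        SpeciesClass.ketoacylCoA,
        SpeciesClass.acetylCoA,
        SpeciesClass.CoASH,
    }
)


@dataclass(frozen=True)
class MetaboliteSpec:
    """One chemical species at one compartment."""

    name: str
    species_class: SpeciesClass
    chain_length: int | None
    compartment: Compartment
    is_boundary: bool = False

    def __post_init__(self) -> None:
        chain_indexed = self.species_class in CHAIN_CLASSES
        if chain_indexed and self.chain_length is None:
            raise ConfigurationError(f"{self.name}: chain-indexed class needs a chain length")
        if not chain_indexed and self.chain_length is not None:
            raise ConfigurationError(f"{self.name}: cofactor class must not carry a chain length")
        if self.chain_length is not None and self.chain_length not in CHAINS:
            raise ConfigurationError(
                f"{self.name}: chain length {self.chain_length} outside even range 4-16"
            )

    @property
    def carbons(self) -> int:
        """Carbon atoms of the acyl group counted in the carbon balance.

        Carnitine and CoA moieties are catalytic and excluded; acetyl-CoA
        carries the terminal C2 unit.
        """
        if self.species_class is SpeciesClass.acetylCoA:
            return 2
        if self.species_class in CHAIN_CLASSES:
            return int(self.chain_length)  # type: ignore[arg-type]
        return 0


@dataclass(frozen=True)
class ReactionSpec:
    """One (enzyme, chain-length) reaction instance.

    ``stoichiometry`` maps species name to a signed integer coefficient in
    the forward (beta-oxidation) direction.  ``pool`` identifies the
    independent saturable enzyme pool serving this reaction: in the standard
    model all reactions of an enzyme share one pool (the origin of substrate
    competition); the no-competition variant dedicates one pool per chain.
    """

    name: str
    enzyme: str
    chain_length: int | None
    stoichiometry: dict[str, int]
    rate_law_kind: str
    reversible: bool = True
    pool: str | None = None
    dedicated_fraction: float = 1.0

    @property
    def pool_id(self) -> str:
        return self.pool if self.pool is not None else self.enzyme


@dataclass(frozen=True)
class ModelVariant:
    """Switches selecting the standard model or one of its published variants.

    ``enzyme_fractions`` maps (enzyme, chain) to the Vmax fraction dedicated
    to that chain in the no-competition variant (fractions per enzyme sum to
    one).  ``clamped_species`` clamps additional, normally variable species
    at fixed concentrations (the fixed-CoASH variant clamps ``CoASH_m``).
    ``nad_ratio`` sets [NAD+]/[NADH] at a preserved total.
    """

    competition: bool = True
    enzyme_fractions: dict[tuple[str, int], float] | None = None
    clamped_species: dict[str, float] = field(default_factory=dict)
    malonyl_coa: float = 0.0
    nad_ratio: float = 15.0
    nad_sum_preserved: bool = True
    boundary_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.competition and self.enzyme_fractions is not None:
            sums: dict[str, float] = {}
            for (enzyme, _chain), frac in self.enzyme_fractions.items():
                if frac < 0:
                    raise ConfigurationError(f"negative enzyme fraction for {enzyme}")
                sums[enzyme] = sums.get(enzyme, 0.0) + frac
            for enzyme, total in sums.items():
                if abs(total - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"dedicated fractions of {enzyme} sum to {total!r}, expected 1"
                    )
        if self.malonyl_coa < 0:
            raise ConfigurationError("malonyl-CoA concentration must be >= 0")
        if self.nad_ratio <= 0:
            raise ConfigurationError("NAD+/NADH ratio must be > 0")

    def with_clamped(self, name: str, value: float) -> "ModelVariant":
        clamped = dict(self.clamped_species)
        clamped[name] = value
        return replace(self, clamped_species=clamped)


STANDARD = ModelVariant()


# ---------------------------------------------------------------------------
# species / reaction construction helpers

def _acyl(n: int) -> str:
    return f"acylCoA_C{n}_m"


def _enoyl(n: int) -> str:
    return f"enoylCoA_C{n}_m"


def _hydroxy(n: int) -> str:
    return f"hydroxyacylCoA_C{n}_m"


def _keto(n: int) -> str:
    return f"ketoacylCoA_C{n}_m"


def _acar(n: int, comp: str) -> str:
    return f"acylcarnitine_C{n}_{comp}"


def _species_from_name(name: str, boundary: frozenset[str]) -> MetaboliteSpec:
    comp = Compartment.matrix if name.endswith("_m") else Compartment.extramitochondrial
    stem = name[:-2]
    chain: int | None = None
    if "_C" in stem:
        stem, _, tail = stem.rpartition("_C")
        chain = int(tail)
    cls_by_stem = {
        "acylCoA": SpeciesClass.acylCoA,
        "enoylCoA": SpeciesClass.enoylCoA,
        "hydroxyacylCoA": SpeciesClass.hydroxyacylCoA,
        "ketoacylCoA": SpeciesClass.ketoacylCoA,
        "acylcarnitine": SpeciesClass.acylcarnitine,
        "acetylCoA": SpeciesClass.acetylCoA,
        "CoASH": SpeciesClass.CoASH,
        "carnitine": SpeciesClass.carnitine,
        "NAD": SpeciesClass.NAD,
        "NADH": SpeciesClass.NADH,
        "malonylCoA": SpeciesClass.malonylCoA,
        "palmitoylCoA": SpeciesClass.acylCoA,
    }
    if stem == "palmitoylCoA":
        chain = 16
    if stem not in cls_by_stem:
        raise ConfigurationError(f"unknown species name {name!r}")
    return MetaboliteSpec(
        name=name,
        species_class=cls_by_stem[stem],
        chain_length=chain,
        compartment=comp,
        is_boundary=name in boundary,
    )


def _check_specificity(specificity: dict[str, tuple[int, ...]]) -> None:
    valid = set(DEFAULT_SPECIFICITY)
    for enzyme, chains in specificity.items():
        if enzyme not in valid:
            raise ConfigurationError(
                f"unknown enzyme {enzyme!r}; valid enzymes: {sorted(valid)}"
            )
        for n in chains:
            if n not in CHAINS:
                raise ConfigurationError(
                    f"{enzyme}: chain length {n} is not an even integer in [4, 16]"
                )
    if "CPT1" in specificity and tuple(specificity["CPT1"]) not in ((), (16,)):
        raise ConfigurationError("CPT1 activity is restricted to palmitoyl CoA (C16)")
    if "MTP" in specificity and any(n < 8 for n in specificity["MTP"]):
        raise ConfigurationError("C4 and C6 esters are handled by the crotonase branch, not MTP")


@dataclass
class NetworkModel:
    """Assembled reaction network.

    ``species`` lists variable species in state-vector order; ``boundary``
    lists clamped species.  ``N`` is the integer stoichiometric matrix over
    (variable species x reactions).  Volumes are fractions of the total assay
    volume; rates are expressed per litre of assay, so the ODE for species x
    reads d[x]/dt = (sum_j N_xj v_j) / V(compartment of x).
    """

    species: list[MetaboliteSpec]
    boundary: list[MetaboliteSpec]
    reactions: list[ReactionSpec]
    variant: ModelVariant
    specificity: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        self.index = {s.name: i for i, s in enumerate(self.species)}
        self.boundary_index = {s.name: i for i, s in enumerate(self.boundary)}
        self.N = stoichiometric_matrix(self)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_enzyme_pools(self) -> int:
        return len({r.pool_id for r in self.reactions})

    def reactions_of(self, enzyme: str) -> list[ReactionSpec]:
        return [r for r in self.reactions if r.enzyme == enzyme]

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def compartment_volumes(self, v_mat: float) -> np.ndarray:
        """Per-variable-species compartment volume fractions."""
        if not 0 < v_mat < 1:
            raise ConfigurationError("V_MAT must be a volume fraction in (0, 1)")
        v_extra = 1.0 - v_mat
        return np.array(
            [v_mat if s.compartment is Compartment.matrix else v_extra for s in self.species]
        )


def build_network(
    specificity: dict[str, tuple[int, ...]] | None = None,
    variant: ModelVariant = STANDARD,
    include_sink: bool = True,
) -> NetworkModel:
    """Assemble the reaction network for a given chain-length specificity.

    Every (enzyme, chain) pair in the specificity map becomes one reaction
    instance.  Species are enumerated from the reactions actually present, so
    restricted specificities (toy models) yield consistent sub-networks.

    Raises
    ------
    ConfigurationError
        for odd or out-of-range chain lengths or unknown enzymes.
    NetworkError
        if a chain-indexed species is produced but never consumed (dead end).
    """
    spec = dict(DEFAULT_SPECIFICITY) if specificity is None else dict(specificity)
    _check_specificity(spec)

    reactions: list[ReactionSpec] = []

    def add(name: str, enzyme: str, chain: int | None, stoich: dict[str, int],
            kind: str, reversible: bool = True) -> None:
        pool = None
        frac = 1.0
        if not variant.competition and variant.enzyme_fractions is not None and chain is not None:
            frac = variant.enzyme_fractions.get((enzyme, chain), 1.0)
            pool = f"{enzyme}_C{chain}"
        reactions.append(
            ReactionSpec(
                name=name,
                enzyme=enzyme,
                chain_length=chain,
                stoichiometry=stoich,
                rate_law_kind=kind,
                reversible=reversible,
                pool=pool,
                dedicated_fraction=frac,
            )
        )

    if spec.get("CPT1"):
        add(
            "CPT1_C16", "CPT1", 16,
            {"palmitoylCoA_e": -1, "carnitine_e": -1, _acar(16, "e"): 1, "CoASH_e": 1},
            "cpt1_inhibited",
        )
    for n in spec.get("CACT", ()):
        add(
            f"CACT_C{n}", "CACT", n,
            {_acar(n, "e"): -1, "carnitine_m": -1, _acar(n, "m"): 1, "carnitine_e": 1},
            "antiporter",
        )
    for n in spec.get("CPT2", ()):
        add(
            f"CPT2_C{n}", "CPT2", n,
            {_acar(n, "m"): -1, "CoASH_m": -1, _acyl(n): 1, "carnitine_m": 1},
            "reversible_mm_competitive",
        )
    for enzyme in DEHYDROGENASES:
        for n in spec.get(enzyme, ()):
            add(
                f"{enzyme}_C{n}", enzyme, n,
                {_acyl(n): -1, _enoyl(n): 1},
                "reversible_mm_competitive",
            )
    for n in spec.get("crotonase", ()):
        add(
            f"crotonase_C{n}", "crotonase", n,
            {_enoyl(n): -1, _hydroxy(n): 1},
            "reversible_mm_competitive",
        )
    for n in spec.get("MSCHAD", ()):
        add(
            f"MSCHAD_C{n}", "MSCHAD", n,
            {_hydroxy(n): -1, "NAD_m": -1, _keto(n): 1, "NADH_m": 1},
            "reversible_mm_competitive",
        )
    for n in spec.get("MCKAT", ()):
        if n == 4:
            # thiolysis of acetoacetyl-CoA yields two acetyl-CoA: the C2 unit
            # is not modelled as a separate acyl-CoA species
            stoich = {_keto(4): -1, "CoASH_m": -1, "acetylCoA_m": 2}
        else:
            stoich = {_keto(n): -1, "CoASH_m": -1, _acyl(n - 2): 1, "acetylCoA_m": 1}
        add(f"MCKAT_C{n}", "MCKAT", n, stoich, "reversible_mm_competitive")
    for n in spec.get("MTP", ()):
        add(
            f"MTP_C{n}", "MTP", n,
            {
                _enoyl(n): -1, "NAD_m": -1, "CoASH_m": -1,
                _acyl(n - 2): 1, "acetylCoA_m": 1, "NADH_m": 1,
            },
            "mtp_lumped",
        )
    if include_sink:
        add(
            "acetylCoA_sink", "acetylCoA_sink", None,
            {"acetylCoA_m": -1, "CoASH_m": 1},
            "sink", reversible=False,
        )

    boundary_names = set(BOUNDARY_SPECIES) | set(variant.clamped_species)
    referenced: list[str] = []
    for r in reactions:
        for name in r.stoichiometry:
            if name not in referenced:
                referenced.append(name)
    # malonyl-CoA inhibits CPT1 without appearing in any stoichiometry
    if spec.get("CPT1") and "malonylCoA_e" not in referenced:
        referenced.append("malonylCoA_e")
    boundary = frozenset(n for n in referenced if n in boundary_names)
    variable = [n for n in referenced if n not in boundary]

    species = [_species_from_name(n, boundary) for n in variable]
    bspecies = [_species_from_name(n, boundary) for n in referenced if n in boundary]

    _validate_structure(species, reactions)

    return NetworkModel(
        species=species,
        boundary=bspecies,
        reactions=reactions,
        variant=variant,
        specificity=spec,
    )


def _validate_structure(species: list[MetaboliteSpec], reactions: list[ReactionSpec]) -> None:
    """Flag chain-indexed species that are produced but never consumed."""
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in reactions:
        for name, coeff in r.stoichiometry.items():
            if coeff > 0:
                produced.add(name)
            elif coeff < 0:
                consumed.add(name)
    for s in species:
        if s.species_class in CHAIN_CLASSES and s.name in produced and s.name not in consumed:
            raise NetworkError(
                f"dead-end species {s.name!r}: produced but never consumed in forward direction"
            )
    # carbon must balance reaction by reaction (the sink deliberately exports
    # the C2 unit and is checked by the trajectory-level carbon balance)
    carbons = {s.name: s.carbons for s in species}
    for r in reactions:
        if r.rate_law_kind == "sink":
            continue
        total = sum(carbons.get(name, _species_from_name(name, frozenset()).carbons) * c
                    for name, c in r.stoichiometry.items())
        if total != 0:
            raise NetworkError(f"reaction {r.name} does not balance carbon ({total:+d})")


def stoichiometric_matrix(model: NetworkModel) -> np.ndarray:
    """Integer stoichiometric matrix over (variable species x reactions)."""
    index = {s.name: i for i, s in enumerate(model.species)}
    N = np.zeros((len(model.species), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for name, coeff in r.stoichiometry.items():
            i = index.get(name)
            if i is not None:
                N[i, j] = coeff
    return N


def conserved_moieties(model: NetworkModel) -> list[dict]:
    """Conserved-moiety vectors over the variable species.

    Returns the CoA moiety (CoASH + all matrix CoA esters + acetyl-CoA) and
    the matrix carnitine moiety (free matrix carnitine + matrix
    acyl-carnitines; the CACT antiport exchanges carnitine across the
    membrane 1:1, so the matrix total is invariant).  Clamped cofactor
    couples (NAD, FAD) are reported as boundary identities.  Moieties whose
    member species have been clamped (fixed-CoASH variant) are flagged
    ``broken``.
    """
    names = model.species_names()
    clamped = set(model.variant.clamped_species) | {s.name for s in model.boundary}
    moieties: list[dict] = []

    coa_members = [
        s.name
        for s in model.species
        if s.species_class in COA_CLASSES and s.compartment is Compartment.matrix
    ]
    if coa_members or "CoASH_m" in clamped:
        w = np.array([1.0 if n in coa_members else 0.0 for n in names])
        broken = "CoASH_m" in clamped
        moieties.append({"name": "CoA", "weights": w, "members": coa_members, "broken": broken})

    carn_members = [
        s.name
        for s in model.species
        if s.compartment is Compartment.matrix
        and s.species_class in (SpeciesClass.carnitine, SpeciesClass.acylcarnitine)
    ]
    if carn_members:
        w = np.array([1.0 if n in carn_members else 0.0 for n in names])
        broken = any(m in clamped for m in ("carnitine_m",))
        moieties.append(
            {"name": "carnitine_matrix", "weights": w, "members": carn_members, "broken": broken}
        )

    for cofactor, members in (("NAD", ["NAD_m", "NADH_m"]),):
        if all(m in {s.name for s in model.boundary} for m in members):
            moieties.append(
                {"name": cofactor, "weights": None, "members": members, "broken": False,
                 "clamped_boundary": True}
            )

    # verify unbroken moieties lie in the left null space of N, exactly
    for m in moieties:
        if m.get("weights") is None or m["broken"]:
            continue
        residual = m["weights"] @ model.N
        if np.any(residual != 0):
            raise NetworkError(f"moiety {m['name']} is not conserved by the stoichiometry")
    return moieties


def validate_microscopic_reversibility(params, specificity=None, rtol: float = 1e-2) -> dict:
    """Check that parallel routes share one overall equilibrium constant.

    For every chain length served by both the crotonase branch and MTP the
    product Keq(crotonase) * Keq(MSCHAD) * Keq(MCKAT) must equal the lumped
    Keq(MTP).  Returns a report dict with one entry per shared chain.
    """
    spec = dict(DEFAULT_SPECIFICITY) if specificity is None else dict(specificity)
    shared = [
        n
        for n in spec.get("MTP", ())
        if all(n in spec.get(e, ()) for e in ("crotonase", "MSCHAD", "MCKAT"))
    ]
    checks = []
    ok = True
    for n in shared:
        try:
            branch = (
                params.keq[("crotonase", n)]
                * params.keq[("MSCHAD", n)]
                * params.keq[("MCKAT", n)]
            )
            lumped = params.keq[("MTP", n)]
        except KeyError as exc:
            raise ConfigurationError(f"missing equilibrium constant: {exc.args[0]}") from exc
        rel = abs(branch - lumped) / lumped
        passed = rel <= rtol
        ok = ok and passed
        checks.append(
            {"chain": n, "branch_product": branch, "lumped": lumped,
             "relative_error": rel, "passed": passed}
        )
    return {"passed": ok, "checks": checks, "tolerance": rtol}
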