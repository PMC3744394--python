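"""Parameter-set construction, YAML (de)serialization and load-time validation.

The shipped default set (``betaox/data/default_params.yaml``) exposes exactly
234 model parameters: 11 Vmax, 55 Keq, 164 Km, the malonyl-CoA inhibition
constant, the acetyl-CoA sink constant, the matrix volume fraction and the
conserved CoA total.  Boundary concentrations and initial conditions are
experimental conditions, not counted parameters.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .kinetics import ParameterSet, validate_parameters
from .network import (
    CHAINS,
    DEFAULT_SPECIFICITY,
    DEHYDROGENASES,
    ConfigurationError,
    ModelVariant,
    build_network,
)

__all__ = [
    "default_parameters",
    "default_config_path",
    "load_config",
    "save_config",
    "params_to_dict",
    "params_from_dict",
]

# Equilibrium constants printed for the thermodynamically critical couple and
# the lumped channelled route; microscopic reversibility fixes the crotonase
# value: Keq_crot * Keq_mschad * Keq_mckat = Keq_mtp.
KEQ_MSCHAD = 2.2e-4
KEQ_MCKAT = 1.1e3
KEQ_MTP = 0.7
KEQ_CROTONASE = KEQ_MTP / (KEQ_MSCHAD * KEQ_MCKAT)


def _acar(n: int, comp: str) -> str:
    return f"acylcarnitine_C{n}_{comp}"


def _acyl(n: int) -> str:
    return f"acylCoA_C{n}_m"


def default_parameters() -> ParameterSet:
    """The shipped rat-liver parameter set (reconstruction, see docs/methods.md)."""
    vmax = {
        "CPT1": 1.8,
        "CACT": 30.0,
        "CPT2": 20.0,
        "VLCAD": 2.2,
        "LCAD": 1.8,
        "MCAD": 2.5,
        "SCAD": 2.5,
        "crotonase": 14.0,
        "MSCHAD": 12.0,
        "MCKAT": 8.0,
        "MTP": 10.0,
    }

    keq: dict[tuple[str, int], float] = {("CPT1", 16): 1.0}
    for n in CHAINS:
        keq[("CACT", n)] = 1.0
        keq[("CPT2", n)] = 1.0
        keq[("crotonase", n)] = KEQ_CROTONASE
        keq[("MSCHAD", n)] = KEQ_MSCHAD
        keq[("MCKAT", n)] = KEQ_MCKAT
    for enzyme in DEHYDROGENASES:
        for n in DEFAULT_SPECIFICITY[enzyme]:
            keq[(enzyme, n)] = 3.0
    for n in DEFAULT_SPECIFICITY["MTP"]:
        keq[("MTP", n)] = KEQ_MTP

    km: dict[tuple[str, int | None, str], float] = {}

    km[("CPT1", 16, "palmitoylCoA_e")] = 45.0
    km[("CPT1", 16, _acar(16, "e"))] = 60.0
    km[("CPT1", None, "carnitine_e")] = 150.0
    km[("CPT1", None, "CoASH_e")] = 40.0

    for n in CHAINS:
        km[("CACT", n, _acar(n, "e"))] = 15.0
        km[("CACT", n, _acar(n, "m"))] = 15.0
        km[("CACT", n, "carnitine_m")] = 400.0
        km[("CACT", n, "carnitine_e")] = 400.0

        km[("CPT2", n, _acar(n, "m"))] = 25.0
        km[("CPT2", n, _acyl(n))] = 30.0
        km[("CPT2", n, "CoASH_m")] = 30.0
        km[("CPT2", n, "carnitine_m")] = 350.0

    dh_km_s = {
        "VLCAD": {12: 4.0, 14: 3.0, 16: 2.0},
        "LCAD": {8: 12.0, 10: 9.0, 12: 7.0, 14: 6.0, 16: 8.0},
        "MCAD": {6: 6.0, 8: 3.0, 10: 4.0, 12: 6.0},
        "SCAD": {4: 10.0, 6: 18.0},
    }
    for enzyme, by_chain in dh_km_s.items():
        for n, v in by_chain.items():
            km[(enzyme, n, _acyl(n))] = v
            km[(enzyme, n, f"enoylCoA_C{n}_m")] = 2.0 * v

    crot_km = {4: 40.0, 6: 35.0, 8: 30.0, 10: 28.0, 12: 25.0, 14: 25.0, 16: 25.0}
    for n in CHAINS:
        km[("crotonase", n, f"enoylCoA_C{n}_m")] = crot_km[n]
        km[("crotonase", n, f"hydroxyacylCoA_C{n}_m")] = 45.0

        km[("MSCHAD", n, f"hydroxyacylCoA_C{n}_m")] = 4.0
        km[("MSCHAD", n, f"ketoacylCoA_C{n}_m")] = 15.0
        km[("MSCHAD", n, "NAD_m")] = 60.0
        km[("MSCHAD", n, "NADH_m")] = 30.0

        km[("MCKAT", n, f"ketoacylCoA_C{n}_m")] = 0.1
        km[("MCKAT", n, "CoASH_m")] = 30.0
        if n > 4:
            km[("MCKAT", n, _acyl(n - 2))] = 2.55

    mtp_km_s = {8: 2.0, 10: 2.0, 12: 2.0, 14: 2.0, 16: 2.0}
    for n, v in mtp_km_s.items():
        km[("MTP", n, f"enoylCoA_C{n}_m")] = v
        km[("MTP", n, _acyl(n - 2))] = 30.0
    km[("MTP", None, "NAD_m")] = 60.0
    km[("MTP", None, "NADH_m")] = 50.0
    km[("MTP", None, "CoASH_m")] = 35.0
    km[("MTP", None, "acetylCoA_m")] = 40.0

    nad_total = 3000.0
    nad_ratio = 15.0
    boundaries = {
        "palmitoylCoA_e": 25.0,
        "carnitine_e": 500.0,
        "CoASH_e": 0.5,
        "malonylCoA_e": 0.0,
        "NAD_m": nad_total * nad_ratio / (1.0 + nad_ratio),
        "NADH_m": nad_total / (1.0 + nad_ratio),
    }

    return ParameterSet(
        vmax=vmax,
        keq=keq,
        km=km,
        ki_malonyl=10.0,
        k1_acesink=100.0,
        v_mat=5.0e-4,
        coa_total=1500.0,
        boundaries=boundaries,
        initial={"carnitine_m": 1000.0},
    )


# ---------------------------------------------------------------------------
# YAML round trip

def params_to_dict(params: ParameterSet,
                   specificity: dict[str, tuple[int, ...]] | None = None,
                   variant: ModelVariant | None = None) -> dict:
    spec = dict(DEFAULT_SPECIFICITY) if specificity is None else dict(specificity)
    enzymes: dict[str, dict] = {}
    for enzyme, v in params.vmax.items():
        enzymes[enzyme] = {"Vmax": float(v), "Keq": {}, "Km": {}}
    for (enzyme, chain), v in sorted(params.keq.items()):
        enzymes[enzyme]["Keq"][int(chain)] = float(v)
    for (enzyme, chain, species), v in sorted(
        params.km.items(), key=lambda kv: (kv[0][0], kv[0][1] or 0, kv[0][2])
    ):
        key = int(chain) if chain is not None else "shared"
        enzymes[enzyme]["Km"].setdefault(key, {})[species] = float(v)
    enzymes["CPT1"]["Ki_malonylCoA"] = float(params.ki_malonyl)
    enzymes["acetylCoA_sink"] = {"K1acesink": float(params.k1_acesink)}

    doc = {
        "specificity": {e: list(map(int, chains)) for e, chains in spec.items()},
        "volumes": {"V_MAT": float(params.v_mat)},
        "totals": {"CoA_total": float(params.coa_total)},
        "boundaries": {k: float(v) for k, v in params.boundaries.items()},
        "initial": {k: float(v) for k, v in params.initial.items()},
        "parameters": enzymes,
    }
    if variant is not None:
        doc["variant"] = {
            "competition": variant.competition,
            "malonyl_coa": float(variant.malonyl_coa),
            "nad_ratio": float(variant.nad_ratio),
            "clamped_species": {k: float(v) for k, v in variant.clamped_species.items()},
        }
    return doc


def params_from_dict(doc: dict) -> tuple[ParameterSet, dict[str, tuple[int, ...]], ModelVariant]:
    problems: list[str] = []
    spec_doc = doc.get("specificity", {})
    specificity = {}
    for enzyme, chains in spec_doc.items():
        if enzyme not in DEFAULT_SPECIFICITY:
            problems.append(
                f"specificity: unknown enzyme {enzyme!r}; "
                f"valid enzymes: {sorted(DEFAULT_SPECIFICITY)}"
            )
            continue
        specificity[enzyme] = tuple(int(n) for n in chains)

    enzymes = doc.get("parameters", {})
    vmax: dict[str, float] = {}
    keq: dict[tuple[str, int], float] = {}
    km: dict[tuple[str, int | None, str], float] = {}
    ki_malonyl = float(enzymes.get("CPT1", {}).get("Ki_malonylCoA", 0.0))
    k1_acesink = float(enzymes.get("acetylCoA_sink", {}).get("K1acesink", 0.0))
    valid_enzymes = set(DEFAULT_SPECIFICITY) | {"acetylCoA_sink"}
    for enzyme, block in enzymes.items():
        if enzyme not in valid_enzymes:
            problems.append(
                f"parameters: unknown enzyme {enzyme!r}; valid enzymes: {sorted(valid_enzymes)}"
            )
            continue
        if enzyme == "acetylCoA_sink":
            continue
        if "Vmax" in block:
            vmax[enzyme] = float(block["Vmax"])
        for chain, v in block.get("Keq", {}).items():
            keq[(enzyme, int(chain))] = float(v)
        for chain, by_species in block.get("Km", {}).items():
            c = None if chain == "shared" else int(chain)
            for species, v in by_species.items():
                km[(enzyme, c, species)] = float(v)

    params = ParameterSet(
        vmax=vmax,
        keq=keq,
        km=km,
        ki_malonyl=ki_malonyl,
        k1_acesink=k1_acesink,
        v_mat=float(doc.get("volumes", {}).get("V_MAT", 0.0)),
        coa_total=float(doc.get("totals", {}).get("CoA_total", 0.0)),
        boundaries={k: float(v) for k, v in doc.get("boundaries", {}).items()},
        initial={k: float(v) for k, v in doc.get("initial", {}).items()},
    )

    vdoc = doc.get("variant", {})
    variant = ModelVariant(
        competition=bool(vdoc.get("competition", True)),
        malonyl_coa=float(vdoc.get("malonyl_coa", 0.0)),
        nad_ratio=float(vdoc.get("nad_ratio", 15.0)),
        clamped_species={k: float(v) for k, v in vdoc.get("clamped_species", {}).items()},
    )
    if problems:
        raise ConfigurationError("invalid configuration:\n" + "\n".join(problems))
    return params, specificity, variant


def default_config_path() -> Path:
    return Path(str(importlib.resources.files("betaox") / "data" / "default_params.yaml"))


def load_config(path: str | Path | None = None):
    """Load and validate a model configuration.

    Returns ``(ParameterSet, specificity, ModelVariant)``.  All load-time
    validators run (positivity, completeness, microscopic reversibility);
    failures are aggregated into one ConfigurationError listing every
    problem, not just the first.
    """
    p = default_config_path() if path is None else Path(path)
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    params, specificity, variant = params_from_dict(doc)
    network = build_network(specificity or None, variant)
    problems = validate_parameters(params, network)
    if problems:
        raise ConfigurationError(
            f"invalid configuration {p}:\n" + "\n".join(problems)
        )
    return params, specificity, variant


def save_config(params: ParameterSet, path: str | Path,
                specificity: dict[str, tuple[int, ...]] | None = None,
                variant: ModelVariant | None = None) -> None:
    doc = params_to_dict(params, specificity, variant)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
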