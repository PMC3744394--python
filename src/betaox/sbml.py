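"""SBML Level 3 export of the assembled network.

Species (with boundary flags), compartments, reactions and kinetic laws are
written so the model structure round-trips exactly; kinetic laws carry the
full rate expressions with numeric constants inlined (rates in uM min^-1
per litre of assay volume).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .kinetics import ParameterSet, ester_pair
from .network import Compartment, NetworkModel, ReactionSpec

__all__ = ["formula_for", "export_sbml", "read_stoichiometric_matrix"]


def _num(x: float) -> str:
    return repr(float(x))


def _pool_denominator(network: NetworkModel, params: ParameterSet,
                      reaction: ReactionSpec) -> str:
    terms = ["1"]
    for r in network.reactions:
        if r.pool_id != reaction.pool_id or r.rate_law_kind == "sink":
            continue
        s, p = ester_pair(r)
        if s is not None:
            terms.append(f"{s} / {_num(params.km_of(r.enzyme, r.chain_length, s))}")
        if p is not None:
            terms.append(f"{p} / {_num(params.km_of(r.enzyme, r.chain_length, p))}")
    return "(" + " + ".join(terms) + ")"


def formula_for(network: NetworkModel, params: ParameterSet,
                reaction: ReactionSpec) -> str:
    """Infix rate expression of one reaction with parameters inlined.

    Species identifiers are the model's species names, so the string both
    parses as SBML L3 math and evaluates directly against a concentration
    namespace (used as a cross-check in the test-suite).
    """
    e, n = reaction.enzyme, reaction.chain_length
    p_ = params
    if reaction.rate_law_kind == "sink":
        return f"{_num(p_.k1_acesink * p_.v_mat)} * acetylCoA_m"
    vmax = p_.vmax[e] * reaction.dedicated_fraction
    keq = p_.keq_of(e, n)
    s, pr = ester_pair(reaction)
    km_s = p_.km_of(e, n, s)
    D = _pool_denominator(network, params, reaction)

    if e in ("VLCAD", "LCAD", "MCAD", "SCAD", "crotonase"):
        return (f"{_num(vmax)} * ({s} - {pr} / {_num(keq)}) / ({_num(km_s)} * {D})")
    if e == "MSCHAD":
        km_nad = p_.km_of(e, n, "NAD_m")
        km_nadh = p_.km_of(e, n, "NADH_m")
        return (
            f"{_num(vmax)} * ({s} * NAD_m - {pr} * NADH_m / {_num(keq)}) / "
            f"({_num(km_s)} * {_num(km_nad)} * {D} * "
            f"(1 + NAD_m / {_num(km_nad)} + NADH_m / {_num(km_nadh)}))"
        )
    if e == "CPT2":
        km_coa = p_.km_of(e, n, "CoASH_m")
        km_carn = p_.km_of(e, n, "carnitine_m")
        return (
            f"{_num(vmax)} * ({s} * CoASH_m - {pr} * carnitine_m / {_num(keq)}) / "
            f"({_num(km_s)} * {_num(km_coa)} * {D} * "
            f"(1 + CoASH_m / {_num(km_coa)} + carnitine_m / {_num(km_carn)}))"
        )
    if e == "MCKAT":
        km_coa = p_.km_of(e, n, "CoASH_m")
        prod = "acetylCoA_m * acetylCoA_m" if pr is None else f"{pr} * acetylCoA_m"
        return (
            f"{_num(vmax)} * ({s} * CoASH_m - {prod} / {_num(keq)}) / "
            f"({_num(km_s)} * {_num(km_coa)} * {D} * (1 + CoASH_m / {_num(km_coa)}))"
        )
    if e == "MTP":
        km_nad = p_.km_of(e, None, "NAD_m")
        km_nadh = p_.km_of(e, None, "NADH_m")
        km_coa = p_.km_of(e, None, "CoASH_m")
        km_ace = p_.km_of(e, None, "acetylCoA_m")
        return (
            f"{_num(vmax)} * ({s} * NAD_m * CoASH_m - "
            f"{pr} * acetylCoA_m * NADH_m / {_num(keq)}) / "
            f"({_num(km_s)} * {_num(km_nad)} * {_num(km_coa)} * {D} * "
            f"(1 + NAD_m / {_num(km_nad)} + NADH_m / {_num(km_nadh)}) * "
            f"(1 + CoASH_m / {_num(km_coa)} + acetylCoA_m / {_num(km_ace)}))"
        )
    if e == "CACT":
        km_cm = p_.km_of(e, n, "carnitine_m")
        km_ce = p_.km_of(e, n, "carnitine_e")
        return (
            f"{_num(vmax)} * ({s} * carnitine_m - {pr} * carnitine_e / {_num(keq)}) / "
            f"({_num(km_s)} * {_num(km_cm)} * {D} * "
            f"(1 + carnitine_m / {_num(km_cm)} + carnitine_e / {_num(km_ce)}))"
        )
    if e == "CPT1":
        km_p = p_.km_of(e, n, pr)
        km_carn = p_.km_of(e, None, "carnitine_e")
        km_coa = p_.km_of(e, None, "CoASH_e")
        return (
            f"{_num(vmax)} * ({s} * carnitine_e - {pr} * CoASH_e / {_num(keq)}) / "
            f"({_num(km_s)} * {_num(km_carn)} * "
            f"(1 + {s} / {_num(km_s)} + {pr} / {_num(km_p)} + "
            f"malonylCoA_e / {_num(p_.ki_malonyl)}) * "
            f"(1 + carnitine_e / {_num(km_carn)} + CoASH_e / {_num(km_coa)}))"
        )
    raise ValueError(f"no formula template for {reaction.name}")


def export_sbml(model: NetworkModel, params: ParameterSet, path: str | Path) -> None:
    """Write the network as an SBML Level 3 Version 2 document.

    The document passes libsbml's consistency checks (units are left
    undeclared).  Boundary species carry boundaryCondition=true.
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    m = doc.createModel("fa_beta_oxidation")

    comp_ids = {Compartment.matrix: "MAT", Compartment.extramitochondrial: "EXT"}
    for comp, cid in comp_ids.items():
        c = m.createCompartment()
        c.setId(cid)
        c.setConstant(True)
        c.setSize(params.v_mat if comp is Compartment.matrix else 1.0 - params.v_mat)
        c.setSpatialDimensions(3)

    initial = {**params.initial}
    for sp in list(model.species) + list(model.boundary):
        s = m.createSpecies()
        s.setId(sp.name)
        s.setCompartment(comp_ids[sp.compartment])
        s.setBoundaryCondition(sp.is_boundary)
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
        if sp.is_boundary:
            value = model.variant.clamped_species.get(
                sp.name, params.boundaries.get(sp.name, 0.0)
            )
        elif sp.name == "CoASH_m":
            value = params.coa_total
        else:
            value = initial.get(sp.name, 0.0)
        s.setInitialConcentration(float(value))

    for r in model.reactions:
        rx = m.createReaction()
        rx.setId(r.name)
        rx.setReversible(r.reversible)
        for name, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(name)
            ref.setStoichiometry(float(abs(coeff)))
            ref.setConstant(True)
        formula = formula_for(model, params, r)
        # competitors and inhibitors appear in the law but not the
        # stoichiometry; declare them as modifiers
        import re

        referenced = set(re.findall(r"[A-Za-z]\w*", formula))
        all_names = {sp.name for sp in list(model.species) + list(model.boundary)}
        for name in sorted((referenced & all_names) - set(r.stoichiometry)):
            mod = rx.createModifier()
            mod.setSpecies(name)
        law = rx.createKineticLaw()
        ast = libsbml.parseL3Formula(formula)
        if ast is None:
            raise RuntimeError(f"could not parse rate formula for {r.name}")
        law.setMath(ast)

    doc.setConsistencyChecks(libsbml.LIBSBML_CAT_UNITS_CONSISTENCY, False)
    doc.checkConsistency()
    errors = [
        doc.getError(i).getMessage()
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        raise RuntimeError("SBML consistency check failed:\n" + "\n".join(errors))
    libsbml.writeSBMLToFile(doc, str(path))


def read_stoichiometric_matrix(path: str | Path):
    """Re-import an SBML file and rebuild (species_ids, reaction_ids, N) over
    non-boundary species — the structural round-trip oracle."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise RuntimeError("could not parse SBML document")
    m = doc.getModel()
    variable = [
        m.getSpecies(i).getId()
        for i in range(m.getNumSpecies())
        if not m.getSpecies(i).getBoundaryCondition()
    ]
    index = {sid: i for i, sid in enumerate(variable)}
    reactions = [m.getReaction(j).getId() for j in range(m.getNumReactions())]
    N = np.zeros((len(variable), len(reactions)))
    for j in range(m.getNumReactions()):
        rx = m.getReaction(j)
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            if ref.getSpecies() in index:
                N[index[ref.getSpecies()], j] -= ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            if ref.getSpecies() in index:
                N[index[ref.getSpecies()], j] += ref.getStoichiometry()
    return variable, reactions, N
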