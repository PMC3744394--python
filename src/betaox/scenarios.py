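"""Named model variants and perturbation experiments.

Reproducible scenarios around the palmitoyl-CoA titration: the standard
model, the variant without substrate competition (dedicated enzyme
fractions), the fixed-CoASH variant (broken CoA conservation), malonyl-CoA
inhibition of CPT1 and an increased mitochondrial NAD+/NADH ratio at
constant NAD(H) sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import ParameterSet
from .network import (
    DEHYDROGENASES,
    ConfigurationError,
    ModelVariant,
    NetworkModel,
    build_network,
)
from .steadystate import (
    SteadyStateResult,
    continuation_scan,
    scan_frame,
    solve_steady_state,
)

__all__ = [
    "SCENARIO_NAMES",
    "ScenarioResult",
    "AllocationError",
    "make_no_competition_variant",
    "make_clamped_coash_variant",
    "run_named_scenario",
    "onset_of_decline",
]

SCENARIO_NAMES = (
    "standard",
    "no_competition",
    "fixed_coash",
    "malonyl_10uM",
    "nad_ratio_40",
    "custom",
)

#: Enzymes split into dedicated per-chain pools in the no-competition
#: variant: the shared catabolic machinery of the matrix.  The carnitine
#: shuttle is left untouched because its per-chain fluxes vanish at any
#: steady state (the acyl-carnitine pools are pure relay pools), which makes
#: flux-share allocation degenerate there.
DEDICATED_ENZYMES = DEHYDROGENASES + ("crotonase", "MSCHAD", "MCKAT", "MTP")


class AllocationError(ConfigurationError):
    """No meaningful flux shares available to allocate dedicated fractions."""


@dataclass
class ScenarioResult:
    """Scan output of one named scenario."""

    name: str
    model: NetworkModel
    params: ParameterSet
    results: list[SteadyStateResult]
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def onset(self) -> float | None:
        return onset_of_decline(self.table)

    @property
    def max_flux(self) -> float:
        return float(self.table["flux_o2_equiv"].max())


def onset_of_decline(table: pd.DataFrame, budget: float = 1e-6) -> float | None:
    """Smallest scanned substrate value whose flux undercuts the previous
    grid point by more than the solver residual budget; None if monotone."""
    flux = table["flux_o2_equiv"].to_numpy()
    sub = table.iloc[:, 0].to_numpy()
    drops = np.where(np.diff(flux) < -budget)[0]
    if len(drops) == 0:
        return None
    return float(sub[drops[0] + 1])


def make_no_competition_variant(
    model: NetworkModel, params: ParameterSet,
    reference_substrate: float = 25.0,
) -> tuple[NetworkModel, ParameterSet]:
    """Split each shared matrix enzyme into dedicated per-chain pools.

    Pool fractions equal the enzyme's per-chain flux shares at the standard
    model's steady state at ``reference_substrate`` (uM palmitoyl-CoA), so
    that the flux distribution among parallel enzymes matches the standard
    model there.  Each dedicated pool competes only with its own substrate
    and product.
    """
    p_ref = ParameterSet(
        vmax=params.vmax, keq=params.keq, km=params.km,
        ki_malonyl=params.ki_malonyl, k1_acesink=params.k1_acesink,
        v_mat=params.v_mat, coa_total=params.coa_total,
        boundaries={**params.boundaries, "palmitoylCoA_e": reference_substrate},
        initial=params.initial,
    )
    ref = solve_steady_state(model, p_ref)

    fractions: dict[tuple[str, int], float] = {}
    for enzyme in DEDICATED_ENZYMES:
        reactions = [(j, r) for j, r in enumerate(model.reactions) if r.enzyme == enzyme]
        if not reactions:
            continue
        total = sum(ref.fluxes[j] for j, _ in reactions)
        if total <= 0:
            raise AllocationError(
                f"zero net flux through {enzyme} at {reference_substrate} uM; "
                "cannot allocate dedicated fractions"
            )
        for j, r in reactions:
            share = ref.fluxes[j] / total
            if share < 0:
                raise AllocationError(
                    f"negative flux share for {r.name} at the reference state"
                )
            fractions[(enzyme, r.chain_length)] = share

    variant = ModelVariant(
        competition=False,
        enzyme_fractions=fractions,
        malonyl_coa=model.variant.malonyl_coa,
        nad_ratio=model.variant.nad_ratio,
        clamped_species=dict(model.variant.clamped_species),
    )
    model_nc = build_network(model.specificity, variant)
    return model_nc, params


def make_clamped_coash_variant(model: NetworkModel, value: float) -> NetworkModel:
    """Clamp matrix CoASH at ``value`` uM, deliberately breaking the CoA
    moiety conservation (as if an external CoASH supply existed)."""
    if not value > 0:
        raise ConfigurationError("clamped CoASH concentration must be > 0")
    return build_network(model.specificity, model.variant.with_clamped("CoASH_m", value))


def run_named_scenario(
    name: str,
    params: ParameterSet,
    substrate_range: tuple[float, float, float] = (1.0, 100.0, 1.0),
    specificity: dict[str, tuple[int, ...]] | None = None,
    refine: bool = False,
    overrides: dict | None = None,
) -> ScenarioResult:
    """Titrate palmitoyl-CoA through a named scenario and collect the branch.

    Emits steady-state flux, CoASH and summed CoA-ester curves.  ``refine``
    adds a 0.25-uM grid around the detected flux maximum.  ``overrides`` for
    the ``custom`` scenario may set ``variant`` (a ModelVariant) and
    ``clamp_coash`` (uM).
    """
    if name not in SCENARIO_NAMES:
        raise ConfigurationError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    overrides = overrides or {}
    metadata: dict = {"scenario": name, "substrate_range": substrate_range}

    if name == "standard":
        model = build_network(specificity)
    elif name == "malonyl_10uM":
        model = build_network(specificity, ModelVariant(malonyl_coa=10.0))
    elif name == "nad_ratio_40":
        model = build_network(specificity, ModelVariant(nad_ratio=40.0))
    elif name == "no_competition":
        base = build_network(specificity)
        reference = float(overrides.get("reference_substrate", 25.0))
        model, params = make_no_competition_variant(base, params, reference)
        metadata["reference_substrate"] = reference
    elif name == "fixed_coash":
        base = build_network(specificity)
        value = overrides.get("clamp_coash")
        if value is None:
            # default: the standard model's own steady-state CoASH at 25 uM
            p25 = ParameterSet(
                vmax=params.vmax, keq=params.keq, km=params.km,
                ki_malonyl=params.ki_malonyl, k1_acesink=params.k1_acesink,
                v_mat=params.v_mat, coa_total=params.coa_total,
                boundaries={**params.boundaries, "palmitoylCoA_e": 25.0},
                initial=params.initial,
            )
            value = solve_steady_state(base, p25).coash
        model = make_clamped_coash_variant(base, float(value))
        metadata["clamped_CoASH"] = float(value)
    else:  # custom
        variant = overrides.get("variant", ModelVariant())
        model = build_network(specificity, variant)

    lo, hi, step = substrate_range
    values = np.arange(lo, hi + step / 2, step)
    results = continuation_scan(model, params, "palmitoylCoA_e", values)
    table = scan_frame(results, "palmitoylCoA_e")

    if refine and len(table) > 2:
        k = int(table["flux_o2_equiv"].idxmax())
        lo_r = max(lo, table.iloc[max(k - 1, 0), 0])
        hi_r = min(hi, table.iloc[min(k + 1, len(table) - 1), 0])
        fine = np.arange(lo_r, hi_r + 0.125, 0.25)
        fine = fine[~np.isin(np.round(fine, 6), np.round(values, 6))]
        if len(fine):
            extra = continuation_scan(model, params, "palmitoylCoA_e", fine)
            results = results + extra
            table = (
                pd.concat([table, scan_frame(extra, "palmitoylCoA_e")])
                .sort_values("palmitoylCoA_e")
                .reset_index(drop=True)
            )

    # per-class ester sums for each scanned point
    class_rows = []
    for r in results:
        row = {"palmitoylCoA_e": r.params.boundaries["palmitoylCoA_e"]}
        for cls in ("acylCoA", "enoylCoA", "hydroxyacylCoA", "ketoacylCoA"):
            row[cls] = sum(
                r.state[i]
                for i, s in enumerate(r.model.species)
                if s.species_class.value == cls and s.compartment.value == "m"
            )
        row["acetylCoA"] = (
            r.state[r.model.index["acetylCoA_m"]]
            if "acetylCoA_m" in r.model.index else 0.0
        )
        class_rows.append(row)
    ester_classes = (
        pd.DataFrame(class_rows).sort_values("palmitoylCoA_e").reset_index(drop=True)
    )
    metadata["ester_classes"] = ester_classes

    return ScenarioResult(
        name=name, model=model, params=params, results=results,
        table=table, metadata=metadata,
    )
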