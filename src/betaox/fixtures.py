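"""Synthetic inputs: substrate input profiles, pseudo-experimental
acyl-carnitine series and reduced toy parameter sets.

Everything here is generated, seeded and deterministic — stand-ins for the
measured time courses, not claims about any real measurement.  The default
input profile mimics the validation experiments: 25 uM substrate with
500 uM l-carnitine, decaying so that roughly 60% of the C16 pool is
consumed within the 24-minute sampling window.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import weighted_acylcarnitines
from .config import KEQ_CROTONASE, KEQ_MCKAT, KEQ_MSCHAD, KEQ_MTP
from .dynamics import InputProfile, integrate
from .kinetics import ParameterSet
from .network import NetworkModel

__all__ = [
    "SyntheticExperimentConfig",
    "make_input_profile",
    "make_pseudo_experiment",
    "make_toy_parameter_set",
    "TOY_SPECIFICITY",
]

#: Default sampling grid, experiment-like (minutes).
DEFAULT_SAMPLING = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0, 24.0)


@dataclass(frozen=True)
class SyntheticExperimentConfig:
    """Configuration of one synthetic incubation experiment."""

    substrate: str = "palmitoylCoA_e"          # or acylcarnitine_C16_e
    initial_concentration: float = 25.0        # uM substrate
    carnitine: float = 500.0                   # uM l-carnitine in the medium
    decay_rate: float = 0.08                   # min^-1 of the input decay
    floor_fraction: float = 0.3                # residual substrate fraction
    noise_sd: float = 0.0                      # multiplicative lognormal sd
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.initial_concentration < 0 or self.carnitine < 0:
            raise ValueError("concentrations must be >= 0")


def make_input_profile(cfg: SyntheticExperimentConfig) -> InputProfile:
    """Smooth non-negative substrate decay sampled on the experimental grid.

    c(t) = floor + (c0 - floor) exp(-k t): a single exponential with floor,
    chosen so that ~60% of the substrate is consumed by 24 min at the
    defaults (decay rate 0.08 min^-1, floor fraction 0.3).
    """
    t = np.asarray(cfg.sampling_times, dtype=float)
    c0 = cfg.initial_concentration
    floor = cfg.floor_fraction * c0
    c = floor + (c0 - floor) * np.exp(-cfg.decay_rate * t)
    return InputProfile(times=tuple(t), concentrations=tuple(c), species=cfg.substrate)


def make_pseudo_experiment(
    model: NetworkModel, params: ParameterSet, cfg: SyntheticExperimentConfig,
) -> pd.DataFrame:
    """Model-truth weighted acyl-carnitine series with seeded noise.

    Runs the 24-minute simulation driven by the synthetic input profile,
    computes the volume-weighted acyl-carnitine read-out at the sampling
    times and perturbs it with multiplicative lognormal noise.  Returned in
    the tidy schema the comparison code reads: (time, chain, concentration).
    """
    profile = make_input_profile(cfg)
    from dataclasses import replace

    p = replace(
        params,
        boundaries={**params.boundaries,
                    "carnitine_e": cfg.carnitine,
                    cfg.substrate: cfg.initial_concentration},
    )
    t_end = cfg.sampling_times[-1]
    sim = integrate(model, p, t_span=(0.0, t_end), input_profile=profile,
                    t_eval=np.asarray(cfg.sampling_times))
    wide = weighted_acylcarnitines(sim)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for col in wide.columns:
        if col == "time":
            continue
        truth = wide[col].to_numpy()
        noisy = truth * rng.lognormal(mean=0.0, sigma=cfg.noise_sd, size=len(truth)) \
            if cfg.noise_sd > 0 else truth
        for tk, ck in zip(wide["time"], noisy):
            rows.append({"time": tk, "chain": col, "concentration": ck})
    return pd.DataFrame(rows)


def write_pseudo_experiment(df: pd.DataFrame, path: str | Path,
                            cfg: SyntheticExperimentConfig) -> None:
    """CSV output plus a sidecar JSON echoing the seed and config."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".provenance.json")
    sidecar.write_text(json.dumps(asdict(cfg), indent=2, sort_keys=True))


#: Reduced two-cycle network: C4/C6 only, crotonase branch + shuttle,
#: hexanoyl-carnitine supplied from the extramitochondrial side.
TOY_SPECIFICITY: dict[str, tuple[int, ...]] = {
    "CACT": (4, 6),
    "CPT2": (4, 6),
    "SCAD": (4, 6),
    "crotonase": (4, 6),
    "MSCHAD": (4, 6),
    "MCKAT": (4, 6),
}


def make_toy_parameter_set(n_chains: int = 2):
    """Thermodynamically consistent miniature parameter set for fast tests.

    Returns ``(specificity, params, variant)`` for a C4..C(2+2n) sub-network
    using only the crotonase branch and the shuttle; the substrate enters as
    a clamped extramitochondrial acyl-carnitine of the longest chain (the
    ``variant`` carries that clamp).  Passes the same validators as the full
    configuration.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    chains = tuple(4 + 2 * i for i in range(n_chains))
    top = chains[-1]
    specificity = {
        "CACT": chains,
        "CPT2": chains,
        "SCAD": chains if top <= 6 else (4, 6),
        "MCAD": tuple(n for n in chains if n >= 6),
        "crotonase": chains,
        "MSCHAD": chains,
        "MCKAT": chains,
    }
    specificity = {e: c for e, c in specificity.items() if c}

    vmax = {"CACT": 4.0, "CPT2": 3.0, "SCAD": 1.5, "MCAD": 1.5,
            "crotonase": 6.0, "MSCHAD": 4.0, "MCKAT": 6.0}
    keq: dict[tuple[str, int], float] = {}
    km: dict[tuple[str, int | None, str], float] = {}
    for n in chains:
        keq[("CACT", n)] = 1.0
        keq[("CPT2", n)] = 1.0
        keq[("crotonase", n)] = KEQ_CROTONASE
        keq[("MSCHAD", n)] = KEQ_MSCHAD
        keq[("MCKAT", n)] = KEQ_MCKAT
        km[("CACT", n, f"acylcarnitine_C{n}_e")] = 15.0
        km[("CACT", n, f"acylcarnitine_C{n}_m")] = 15.0
        km[("CACT", n, "carnitine_m")] = 400.0
        km[("CACT", n, "carnitine_e")] = 400.0
        km[("CPT2", n, f"acylcarnitine_C{n}_m")] = 25.0
        km[("CPT2", n, f"acylCoA_C{n}_m")] = 30.0
        km[("CPT2", n, "CoASH_m")] = 300.0
        km[("CPT2", n, "carnitine_m")] = 350.0
        km[("crotonase", n, f"enoylCoA_C{n}_m")] = 30.0
        km[("crotonase", n, f"hydroxyacylCoA_C{n}_m")] = 45.0
        km[("MSCHAD", n, f"hydroxyacylCoA_C{n}_m")] = 5.0
        km[("MSCHAD", n, f"ketoacylCoA_C{n}_m")] = 15.0
        km[("MSCHAD", n, "NAD_m")] = 60.0
        km[("MSCHAD", n, "NADH_m")] = 30.0
        km[("MCKAT", n, f"ketoacylCoA_C{n}_m")] = 1.0
        km[("MCKAT", n, "CoASH_m")] = 300.0
        if n > 4:
            km[("MCKAT", n, f"acylCoA_C{n - 2}_m")] = 25.0
    for n in specificity.get("SCAD", ()):
        keq[("SCAD", n)] = 3.0
        km[("SCAD", n, f"acylCoA_C{n}_m")] = 10.0
        km[("SCAD", n, f"enoylCoA_C{n}_m")] = 20.0
    for n in specificity.get("MCAD", ()):
        keq[("MCAD", n)] = 3.0
        km[("MCAD", n, f"acylCoA_C{n}_m")] = 6.0
        km[("MCAD", n, f"enoylCoA_C{n}_m")] = 12.0

    params = ParameterSet(
        vmax={e: v for e, v in vmax.items() if e in specificity},
        keq=keq, km=km,
        ki_malonyl=5.0, k1_acesink=100.0,
        v_mat=5.0e-4, coa_total=800.0,
        boundaries={
            f"acylcarnitine_C{top}_e": 25.0,
            "carnitine_e": 500.0,
            "NAD_m": 2812.5,
            "NADH_m": 187.5,
        },
        initial={"carnitine_m": 500.0},
    )
    from .network import ModelVariant

    variant = ModelVariant(clamped_species={f"acylcarnitine_C{top}_e": 25.0})
    return specificity, params, variant
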