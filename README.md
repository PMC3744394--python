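# betaox — kinetic modelling of mitochondrial fatty-acid β-oxidation

`betaox` is a kinetic model of the mitochondrial β-oxidation of saturated,
even-chain fatty acids in rat liver, built for studying **substrate
overload**: the counter-intuitive regime in which *raising* the fatty-acid
supply *lowers* the steady-state oxidation flux.

The pathway is cyclic — each turn shortens an acyl-CoA by two carbons — and
its intermediates of different chain lengths (C4–C16) share a small set of
enzymes with overlapping specificity: the carnitine shuttle (CPT1, CACT,
CPT2), four acyl-CoA dehydrogenases (VLCAD, LCAD, MCAD, SCAD), and two
parallel routes for enoyl-CoA conversion — the free-intermediate crotonase
branch (crotonase, M/SCHAD, MCKAT) and the channelled, lumped mitochondrial
trifunctional protein (MTP). Because every ester competes for these shared
enzymes, an upstream load propagates *forward*: the more palmitoyl-CoA
enters, the fewer enzyme molecules remain for the shorter downstream esters.
Their accumulation sequesters the conserved CoA pool; past a critical
substrate concentration free CoA (CoASH) collapses and the flux drops
steeply but smoothly. The package exists to assemble this network, locate
its steady states, and dissect that emergent behaviour.

## The model

The standard configuration has **45 variable species, 56 reactions and 234
parameters**. Concentrations are in µM (per litre of each species' own
compartment), time in minutes; rates are expressed per litre of total assay
volume, so for species *x* in compartment volume fraction *V(x)*:

```
d[x]/dt = ( Σ_j  N_xj · v_j ) / V(x)
```

Every enzymatic rate is reversible, saturable, and zero exactly at its
equilibrium. Enzymes accepting several chain lengths carry one shared
competitive denominator, e.g. for a uni-uni step at chain length *n*:

```
v_n = Vmax · ( S_n − P_n/Keq ) / ( Km_S,n · (1 + Σ_i S_i/Km_S,i + Σ_i P_i/Km_P,i) )
```

with the Σ running over **all** substrates and products the enzyme binds —
the term that couples the parallel reactions and generates the feedforward
competitive inhibition. Redox- and CoA-coupled steps (M/SCHAD, MCKAT, MTP,
the shuttle) carry their cofactor couples in the mass-action numerator and
a separate binding factor; CPT1 carries a competitive malonyl-CoA term;
FAD is enzyme-bound and folded into the dehydrogenase Vmax values.

Pathway stoichiometry conserves the matrix CoA moiety (CoASH + all matrix
CoA esters + acetyl-CoA) and the matrix carnitine moiety; NAD⁺/NADH is
clamped at a configurable ratio (default 15) and fixed sum. Microscopic
reversibility ties the two enoyl-CoA routes together: the product of the
crotonase-branch equilibrium constants (crotonase × M/SCHAD × MCKAT, with
Keq(M/SCHAD) = 2.2·10⁻⁴ and Keq(MCKAT) = 1.1·10³) equals the lumped MTP
constant of 0.7 for every shared chain length — validated at load time.

Steady states are found by root-finding on the right-hand side (damped
Newton in log-concentration space, seeded from a time-simulation endpoint),
with conserved-moiety rows replaced by their conservation constraints; a
converged state satisfies max |d/dt| < 10⁻¹¹ µM·min⁻¹.

## Worked example

```python
from betaox import build_network, load_config, solve_steady_state

params, spec, variant = load_config()      # shipped 234-parameter set
model = build_network(spec, variant)       # 45 species, 56 reactions
ss = solve_steady_state(model, params)     # 25 uM palmitoyl-CoA

print(f"max |d/dt| = {ss.residual:.2e} uM/min")
print(f"O2-equivalent flux = {ss.beta_ox_flux:.3f} uM/min")
print(f"CoASH = {ss.coash:.1f} uM; CoA esters = {ss.total_coa_esters:.1f} uM")
```

```
max |d/dt| = 5.33e-15 uM/min
O2-equivalent flux = 3.351 uM/min
CoASH = 1308.2 uM; CoA esters = 191.8 uM
```

The flux is the oxygen-equivalent rate (NADH + FADH₂ production halved,
since one O₂ oxidizes two reducing equivalents); at steady state it equals
7× the palmitoyl-CoA uptake rate (seven cycles per C16). At 25 µM substrate
the pathway is healthy: CoASH holds ~87% of the conserved CoA pool.

Titrating the substrate exposes the overload phenotype:

```bash
betaox scan --scenario standard --from 40 --to 60 --step 1 --out scanout
# max flux 4.1262 uM/min; onset of decline: 50.0
```

Above 50 µM palmitoyl-CoA the steady-state flux declines while CoA esters
accumulate and CoASH is depleted. The scenario suite isolates the cause:

| scenario | behaviour |
|---|---|
| `standard` | flux rises, peaks, declines above 50 µM |
| `no_competition` (dedicated enzyme fractions) | monotone rise to saturation |
| `fixed_coash` (conservation broken) | monotone rise despite extreme ester accumulation |
| `malonyl_10uM` (CPT1 inhibited) | same maximum, decline shifted to higher substrate |
| `nad_ratio_40` (M/SCHAD pushed forward) | no decline on the scanned range |

Together these show the decline is caused by CoASH depletion, which in turn
requires the competition between chain lengths for shared enzymes.

Other entry points: `betaox simulate` (time courses, tidy CSV),
`betaox steady`, `betaox sensitivity` (1% response coefficients of CoASH),
`betaox variant` (dedicated-fraction allocation), `betaox export-sbml`
(SBML Level 3), `betaox fixtures` (seeded synthetic inputs).

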