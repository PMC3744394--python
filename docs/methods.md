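# Methods

This note documents the model, its numerical machinery, the shipped
parameter set and the design decisions behind both — in enough detail that
a user can judge what the package's results do and do not show.

## Network

The model covers mitochondrial β-oxidation of saturated, even-chain acyl
esters (C4–C16) in two compartments, the mitochondrial matrix and the
extramitochondrial space. The standard configuration enumerates 45 variable
species:

- matrix acyl-, enoyl-, 3-hydroxyacyl- and 3-ketoacyl-CoA esters, one per
  chain length (4 × 7);
- acyl-carnitines of every chain length in both compartments (2 × 7);
- acetyl-CoA, free CoA (CoASH) and free carnitine in the matrix.

Clamped (boundary) species: extramitochondrial palmitoyl-CoA (the titrated
substrate), extramitochondrial carnitine and CoASH, malonyl-CoA, and the
matrix NAD⁺/NADH couple. FAD is treated as enzyme-bound; its redox state is
folded into the dehydrogenase Vmax values and never varied.

Chain-length specificity (even chains only): CPT1 {16}; CACT and CPT2
{4–16}; VLCAD {12–16}; LCAD {8–16}; MCAD {6–12}; SCAD {4, 6}; crotonase,
M/SCHAD and MCKAT {4–16}; MTP {8–16}. C4 and C6 enoyl esters are uniquely
handled by the crotonase branch. This enumeration yields exactly 56
reaction instances: CPT1 (1) + CACT (7) + CPT2 (7) + dehydrogenases (14) +
crotonase branch (21) + MTP (5) + the acetyl-CoA sink (1). The terminal
C4 thiolysis produces two acetyl-CoA (no explicit C2 acyl-CoA species).

The acetyl-CoA sink is a first-order drain (K1acesink, min⁻¹) regenerating
CoASH stoichiometrically; it stands for citrate synthase plus malate
dehydrogenase, which regenerate CoASH in the isolated-mitochondria assays
the model mirrors. Its exported C2 units are tracked for the carbon
balance.

### Conserved moieties

Two moieties are conserved by the stoichiometry over the variable species
and are verified to lie in the left null space of N exactly:

- **CoA**: CoASH + all matrix CoA esters + acetyl-CoA = `CoA_total`.
- **matrix carnitine**: free matrix carnitine + matrix acyl-carnitines.
  CACT is a strict 1:1 antiport, so the matrix total is invariant even
  though the extramitochondrial free carnitine is clamped. The
  *whole-system* carnitine total is not a dynamical invariant in this model
  precisely because the external pool is buffered; only the matrix moiety
  is, and that is what `conserved_moieties()` and the tests check.

The NAD (and FAD) couples are clamped-boundary identities, reported as such.
The fixed-CoASH variant deliberately breaks the CoA conservation and is
flagged `broken`.

## Rate laws

All enzymatic steps are reversible and vanish exactly at their
thermodynamic equilibrium. Competition enters through one shared
denominator per enzyme summing the occupancy of every ester substrate and
product the enzyme binds, at every chain length (cofactors are excluded
from this sum and sit in separate binding factors). The forms:

- dehydrogenases, crotonase (uni-uni):
  `v = Vmax (S − P/Keq) / (Km_S · D)`;
- M/SCHAD: `v = Vmax (S·NAD − P·NADH/Keq) / (Km_S Km_NAD · D · D_NAD)` with
  `D_NAD = 1 + NAD/Km_NAD + NADH/Km_NADH`;
- MCKAT: `v = Vmax (K·CoASH − A·Ace/Keq) / (Km_K Km_CoASH · D · D_CoA)`;
  at C4 the product term is Ace²/Keq. Acetyl-CoA occupancy of MCKAT is
  neglected (no Km);
- MTP (lumped hydratase + dehydrogenase + thiolase): single reversible law
  over enoyl-CoA + NAD⁺ + CoASH ⇌ acyl-CoA(n−2) + acetyl-CoA + NADH. Its
  internal hydroxy/keto intermediates are channelled between active sites:
  they appear in no denominator and no state variable;
- CPT1: reversible transesterification with a competitive malonyl-CoA term
  ([malonyl-CoA]/Ki added to the acyl-site denominator); reduces exactly to
  the uninhibited law at zero malonyl-CoA;
- CACT: reversible antiport with the acyl-carnitines of all chain lengths
  competing and a separate carnitine-site factor;
- sink: `v = K1acesink · [acetyl-CoA] · V_MAT` (assay-volume units).

With the `(S − P/Keq)` parameterization the Haldane relation between
forward/reverse capacities holds by construction for any positive Km set;
load-time validation therefore checks positivity, completeness of the Km
bindings, and microscopic reversibility: for every chain length served by
both enoyl-CoA routes, Keq(crotonase)·Keq(M/SCHAD)·Keq(MCKAT) must equal
the lumped Keq(MTP) within a configurable tolerance (default 1%). The
shipped set fixes Keq(M/SCHAD) = 2.2·10⁻⁴, Keq(MCKAT) = 1.1·10³ and
Keq(MTP) = 0.7, which forces Keq(crotonase) = 0.7/(2.2·10⁻⁴·1.1·10³)
≈ 2.8926.

## Units and volumes

Concentrations are µM in each species' own compartment; time is minutes.
Reaction rates are expressed per litre of total assay volume, and the ODE
divides by the compartment volume fraction: d[x]/dt = (N v)/V(x), with
V_MAT = 5·10⁻⁴ (0.5 mg mitochondrial protein per ml at ~1 µl matrix per
mg) and V_extra = 1 − V_MAT.

## Numerics

**Integration.** Stiff BDF (`scipy.integrate.solve_ivp`) in linear space,
default rtol 10⁻⁸ / atol 10⁻⁹, output grid 0–24 min at 0.1 min. Linear
multistep methods preserve the linear conservation laws to round-off; the
moiety drift over 24 min is ~10⁻¹⁴ relative. Concentrations marginally
below zero (> −10⁻⁹ µM) are clipped on reporting; anything larger raises.

**Steady states.** Root-finding on the RHS with each conserved-moiety row
replaced by its conservation constraint (CoASH row ← CoA total, carnitine
row ← matrix carnitine total; the CoA total is the `CoA_total` parameter,
the carnitine total comes from the seed/initial condition — without these
rows the fixed points form a two-parameter family and the Jacobian is
singular). The polish is a damped Newton iteration in log-concentration
space: steady-state pools span ~8 orders of magnitude (the M/SCHAD
equilibrium keeps ketoacyl pools in the nM range next to µM–mM partners),
and log coordinates both preserve positivity and equilibrate the scales.
`scipy.optimize.root` (hybr) is a fallback when the polish stalls.

Seeding follows the endpoint-of-a-time-simulation idea with one
modification: the seed integration runs the *volume-equalized* system
dy/dt = N v ("false transient"). Fixed points satisfy N v = 0 and are
independent of compartment volumes, but the physical transient relaxes the
extramitochondrial pools a factor V_extra/V_MAT ≈ 2000 more slowly than
the matrix — reaching steady state physically takes ~10⁵ model-minutes,
whereas the false transient arrives in a few hundred pseudo-minutes. The
default seed horizon is 200 pseudo-minutes, with one 5× longer retry
before failing loudly.

**Convergence criterion.** max |d/dt| < 10⁻¹¹ µM·min⁻¹ over all variable
species, with the derivative taken of each species' assay-volume
concentration, d(c·V)/dt = (N v). This is the volume-free reading of the
criterion: the per-compartment derivative is the same quantity divided by
V(x), and for matrix species that division amplifies double-precision
cancellation noise in the rate sums (~rate·ε/V_MAT ≈ 10⁻¹¹) above the
criterion itself. Converged solutions typically reach ~10⁻¹⁴. The
convergence metric also includes the conservation-constraint violation
(10⁻⁵ µM counts like 10⁻¹¹ µM·min⁻¹), since the dynamical residual alone
cannot pin the moiety totals.

**Continuation.** Titration scans solve each boundary value seeded by the
previous solution (natural-parameter continuation); forward and backward
scans agree point for point (no hysteresis detected on the default range;
a sign change of the constrained Jacobian determinant would be flagged).
The decline-onset detector reports the smallest scanned substrate value
whose flux undercuts the previous grid point by more than a residual
budget (10⁻⁶ µM·min⁻¹) on the default 1-µM grid, with optional 0.25-µM
refinement around the maximum.

**Sensitivity.** Response coefficients R = (ΔCoASH/CoASH)/(Δp/p) use
one-sided 1% multiplicative perturbations with the steady state re-solved
per parameter (seeded from the reference fixed point), not linearized
Jacobian algebra. Zero-valued parameters have no multiplicative
perturbation and report R = 0; non-converging perturbations report NaN. A
0.1% central-difference oracle and a halved-step Richardson check guard
the approximation.

## The shipped parameter set

The reference values are a **reconstruction**, not a transcription: the
equilibrium constants above, the NAD⁺/NADH ratio (15), the scenario levers
(malonyl-CoA 0/10 µM, NAD ratio 15/40 at constant sum) and the assay
conditions (25 µM substrate, 500 µM carnitine) are fixed by the documented
numbers; the remaining Km/Vmax values are literature-plausible magnitudes
for rat-liver enzymes, calibrated once so that the standard model
reproduces the documented overload phenotype — decline onset at 50 µM
palmitoyl-CoA on a 1-µM grid — while the no-competition variant saturates
monotonically. Two choices carry that asymmetry and deserve emphasis:

- MCKAT binds ketoacyl-CoAs very tightly (Km 0.1 µM) and its acyl-CoA
  products appreciably (Km 2.55 µM). In the standard model the
  equilibrium-poised long-chain branch intermediates and the flux-carrying
  acyl-CoA pools therefore crowd the thiolysis of the C4/C6 esters — the
  step all flux must pass. A dedicated C4 pool sees neither (its products
  are two acetyl-CoA), which is what lets the no-competition variant rise
  to saturation while the standard model collapses.
- Extramitochondrial CoASH is clamped low (0.5 µM): with palmitoyl-CoA the
  only added substrate the medium holds almost no free CoA, which makes
  CPT1 nearly irreversible and lets substrate pressure reach the matrix.

`CoA_total` = 1500 µM (matrix), matrix carnitine total 1000 µM, NAD(H) sum
3000 µM. The parameter file exposes exactly 234 scalars: 11 Vmax, 55 Keq,
164 Km, Ki(malonyl-CoA), K1acesink, V_MAT and CoA_total. Boundary
concentrations and initial conditions are experimental conditions, not
counted parameters.

Because the parameter set is a reconstruction, the *quantitative* flux and
concentration values (e.g. 3.35 µM·min⁻¹ at 25 µM substrate) characterize
this parameterization, not rat liver; the *structural* results — the
overload decline and its dependence on competition, CoA conservation,
CPT1 activity and the NAD⁺/NADH ratio — are the model's reproducible
content.

## Variants

- **No competition**: each matrix catabolic enzyme (the four
  dehydrogenases, crotonase, M/SCHAD, MCKAT, MTP) is split into dedicated
  per-chain pools whose Vmax fractions equal the enzyme's per-chain flux
  shares at the standard 25 µM steady state (so the flux distribution
  among parallel enzymes matches there; the variant's 25 µM flux agrees
  with the standard model within 2%). Each pool's denominator contains
  only its own substrate/product pair. The carnitine shuttle keeps its
  shared kinetics: per-chain shuttle fluxes vanish identically at any
  steady state (the acyl-carnitine pools are relay pools), so flux-share
  allocation is degenerate there and zero-capacity dedicated pools would
  disconnect state variables.
- **Fixed CoASH**: matrix CoASH becomes a clamped boundary (default: the
  standard model's own 25 µM steady-state value), breaking CoA
  conservation — the esters accumulate freely while the flux saturates.
- **Malonyl-CoA / NAD ratio**: boundary overrides; the NAD⁺/NADH ratio is
  changed at constant sum.

## Synthetic data

The fixtures module generates all inputs needed to exercise the tool
offline. The substrate input profile is a single exponential with floor
(defaults: decay 0.08 min⁻¹, floor 30% of the initial 25 µM), chosen so
~60% of the C16 pool is consumed by 24 min — a stand-in with the right
shape and scale, **not** a claim about any measured curve. Pseudo-
experimental acyl-carnitine series are model-truth volume-weighted
read-outs under seeded multiplicative lognormal noise. Consequently the
comparison plots exercise the pipeline and the qualitative phenotype (C16
decline, C4/C6 accumulation); they cannot validate the model against real
measurements, and nothing in the test suite claims otherwise. All fixtures
are byte-deterministic under a fixed seed. A reduced C4/C6 toy
configuration (crotonase branch + shuttle, clamped hexanoyl-carnitine
substrate) passes every validator and solves in well under a second; it
backs the fast unit tests.

## Known limitations

- Saturated, even-chain substrates only; no peroxisomal β-oxidation; no
  coupling to the TCA cycle, respiration or ketogenesis beyond the
  acetyl-CoA sink.
- The FAD redox state is frozen inside the dehydrogenase Vmax values;
  dehydrogenase–ETF coupling is not modelled mechanistically, nor is the
  shuttle given a bi-bi mechanism.
- Steady-state uniqueness is verified empirically (different initial
  conditions, forward/backward continuation) on the scanned range only;
  no global claim is made.
- The 45-state stiffness (V_MAT = 5·10⁻⁴) makes the *physical* approach to
  steady state extremely slow; reported steady states come from
  root-finding, and transient read-outs (24-min trajectories) are the only
  quantities whose timescales should be interpreted physically.
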