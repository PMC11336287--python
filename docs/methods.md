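# Methods

This note documents the models, numerical choices and known limitations of
`sludgeopt`. It is the reference for *why* the defaults are what they are;
the README shows *how* to run things.

## Plant model

### Biokinetics (ASM2d)

Each bioreactor is a completely mixed tank carrying the 19 components of
Activated Sludge Model No. 2d — 9 soluble (SO2, SF, SA, SNH4, SNO3, SPO4,
SI, SALK, SN2) and 10 particulate (XI, XS, XH, XPAO, XPP, XPHA, XAUT, XTSS,
XMeOH, XMeP) — reacting through the standard 21 processes: hydrolysis under
three electron-acceptor regimes, heterotrophic growth on fermentable and
fermentation-product COD (aerobic and anoxic), fermentation, biological
phosphorus removal (PHA storage, poly-P storage, PAO growth, three lysis
routes), nitrification, lysis, and a chemical P precipitation pair that is
**off by default** (`include_chemical_p=False`) because the modelled train
is purely biological.

The stoichiometric matrix is not transcribed: only the independent
coefficients (yields, inert fractions, the Fe(OH)3/FePO4 mass couple) are
specified, and the dependent entries are *solved* per process from the
conservation equations — nitrogen → SNH4, phosphorus → SPO4, COD → SO2 (or
an SNO3→SN2 swap carrying 40/14 g COD per g N for anoxic processes), charge
→ SALK, solids → XTSS. Continuity therefore closes to machine precision by
construction, and the test suite asserts < 1e-8 for all five balances.

The 42 kinetic parameters default to the published typical values at 20 °C;
rate constants carry an Arrhenius-type base `theta` fitted to the published
10/20 °C pairs, so `value(T) = value20 · theta^(T−20)`. Half-saturation
constants are temperature-independent. Each parameter stores a
`[low, high]` admissible range (half-to-double around the default,
efficiencies capped at 1) used as the calibration search box. Simulations
default to 20 °C.

Saturation terms in stored-fraction ratios (XS/XH, XPP/XPAO, XPHA/XPAO and
the poly-P headroom `K_MAX·XPAO − XPP`) are evaluated in the
division-safe form `num/(K·den + num)` so rates stay finite as biomass
vanishes.

### Secondary settler (Takács)

A one-dimensional ten-layer settler with the double-exponential settling
velocity `v_s = min(v0_max, v0·(e^{−r_h·X*} − e^{−r_p·X*}))`,
`X* = max(X − f_ns·X_feed, 0)`. Gravity flux between layers follows the
threshold rule: in the thickening zone (below the feed layer) the flux is
the minimum of the sending and receiving layers' capabilities; in the
clarification zone the receiving layer limits only when it exceeds the
3000 g/m³ threshold. Bulk flow moves upward above the feed layer (to the
effluent, layer 1) and downward below it (to the underflow, layer 10);
feed enters layer 5. All 9 soluble components advect ideally (the settler
is non-reactive). Settling parameters default to the benchmark-simulation
values (v0 = 474 m/d, v0_max = 250 m/d, r_h = 5.76e-4, r_p = 2.86e-3,
f_ns = 2.28e-3 m³/g).

The site's settler geometry is not public; the default area (1500 m²,
4 m deep) gives a surface overflow rate of ~23 m/d at the design flow,
inside the conventional 16–28 m/d window. Both are plain configuration.

Particulate composition is assumed homogeneous: underflow and effluent
particulates are the feed composition rescaled by the layer-to-feed TSS
ratio. TSS and every soluble are exactly conserved across the settler
(flux-form identity, asserted to 1e-8); individual particulate species are
conserved in proportion.

### Flowsheet and flows

Train: pre-anoxic T0 (1113 m³) → anaerobic T1 (1825) → anoxic T2 (5518) →
aerobic T3 (7461) → deoxygenation T4 (472) → post-anoxic T5 (1433) →
post-aerobic T6 (945) → settler; 18,767 m³ of biological volume. The
internal recycle (Ql = 320 % of influent flow) is drawn after T4 — the
deoxygenation tank exists precisely to strip dissolved oxygen before the
return — into T2; return sludge (Qs = 100 %) re-enters T0; wastage
(Qw = 1 %) leaves from the settler underflow. All routing is configurable;
flow balance at every node is closed by construction and asserted to
1e-10. KLa defaults: 248 d⁻¹ on T3, 60 d⁻¹ on T6 (the operating report
gives 248 for "the nitrification reservoir"; the post-aerobic value is an
assumption). Oxygen saturation defaults to 8 g/m³.

### Integration

The coupled system (7×19 tank states + 10 TSS + 10×9 soluble settler
states = 233) is stiff: BDF with a hand-built block Jacobian sparsity
pattern is the default solver (`rtol 1e-6 / atol 1e-8`). The right-hand
side is duplicated as a numba-compiled kernel (~9 µs/call vs ~470 µs for
the vectorized NumPy reference); both paths are kept and an equivalence
test pins them together at machine precision. States are clipped to zero
inside the RHS; the clip is inactive at converged tolerances.

Steady states come from a 200-day constant-influent spin-up polished by a
Newton solve. Because the settler's threshold flux rule is non-smooth, the
polish can stall near 1e-6-relative residuals; the acceptance threshold is
1e-5 relative, far below any biological time constant of interest.

Mass-balance verification uses quadrature states integrated *with* the
plant (cumulative tracer in/out), not post-hoc trapezoid sums, so closure
is limited only by integrator tolerance; the 40-day tracer balance closes
to ~1e-14 at the test tolerances (asserted < 1e-6). SI is the natural
tracer: with the default zero inert-production fraction its stoichiometric
column is identically zero.

## Influent

### Fractionation

Measured indicators map to model components through a COD fraction set
(default SF 0.20, SA 0.08, SI 0.07, XI 0.12, XS 0.43, XH 0.10 — a typical
municipal characterization; the site-specific values are not public).
Nitrogen: SNH4 takes the measured NH4-N, organically bound N follows the
component N contents, and the remainder enters as SNO3. Phosphorus
analogously with SPO4 as the remainder. SALK is fixed at 5 mol/m³, XPAO
and XAUT are zero (negligible in raw sewage), and all otherwise-unspecified
components sit at a 0.02 g/m³ floor, interpreted as a concentration. One
floored component (XPHA) carries COD; its floor is debited from the largest
COD fraction (XS) so that measured COD, TN and TP are conserved exactly
(1e-9), and COD-bearing floors scale to zero for a zero-COD record.

### Synthetic generator

The generator emulates the study's 40-day dynamic influent: per indicator,
base level + diurnal sinusoid + AR(1) noise (coefficient 0.9), with
Poisson-timed rain events (0.15/d, ~0.3 d long) that raise flow ×1.8 and
dilute concentrations ×0.55 — variability attributed to precipitation and
sewage flow. Defaults are set so 40-day statistics land on the printed
anchors: COD clipped to [98, 422] mg/L (base 260, amplitude 110, noise SD
30) and sample SDs of TP/NH4-N/TN near 5.83/5.99/1.87 mg/L (amplitude and
noise chosen so amplitude/√2 and the AR noise compose to the target; the
suite asserts within 20 %). Flow: 35,000 m³/d ± 5,000 diurnal. The series
is bit-reproducible for a fixed seed.

What the generator does **not** emulate: weekly/seasonal cycles, serially
correlated storm clusters, sensor dropout, and any correlation structure
between indicators beyond the shared diurnal phase. Tests passing on this
influent show internal consistency of the pipeline, not predictive skill
on the (undeposited) plant data.

A consequence worth stating plainly: carrying the printed TP standard
deviation (5.83 mg/L) without zero-clipping forces a mean influent TP near
9 mg/L, which at COD ≈ 260 mg/L starves enhanced biological P removal of
VFA — net PAO growth averages ≈0.197/d against a 0.2/d decay, so the PAO
population settles at a trace level and the simulated plant removes P by
assimilation only (effluent TP ≈ 8 mg/L, above the default 0.5 g/m³
limit). We regard this as the physically consistent reading of the printed
statistics rather than a defect to tune away; feasibility machinery and the
optimization are unaffected (constraint handling, below).

## Objectives

- **MQE** = mean over indicators × time of `(C_ref − C_sim)/C_ref`; may be
  negative. In optimization on synthetic data the default plant's effluent
  is the reference, so MQE measures improvement over baseline.
- **EP** = `0.04/T · ∫(Qh + Qw + Qs) dt` (trapezoidal), flows being the
  internal recirculation, wastage and sludge return streams.
- **EA** is implemented *exactly as printed*, including two oddities kept
  deliberately: the integrand divides by the influent flow and multiplies
  by a volume ratio `T_i/Tref`. The expression is dimensionally
  inconsistent as published; we treat it as the cost-index component it is
  (a monotone function of KLa and tank size) rather than a physical energy
  model. `Tref` defaults to 7461 m³, so the main aerobic tank's ratio is 1
  at baseline. The sum runs over the configured aerated tanks (two by
  default, T3 and T6).
- **Solids inventories** use 0.75 × the particulate-COD group sum (the
  ASM1-style ZI/ZS/ZP/ZBH/ZBA naming maps onto ASM2d as XI / XS /
  XPHA+XPP / XH / XAUT+XPAO). The reactor sum covers all seven tanks by
  default (`n_tanks=3` reproduces the printed three-tank reading, which
  would ignore most of the plant's inventory). **SG** adds the inventory
  change to the 0.75-scaled wasted-solids integral, per day.
- **TCI = EA + EP + 5·SG**; **OV** is the plain sum of the seven tank
  volumes.

### Decision variables and constraints

Twelve variables: Ql, Qs, Qw, KLa1 (→ aerobic tank), KLa2 (→ post-aerobic
tank), and the seven volumes. The published list names eleven and the
count "12"; wastage Qw is the natural twelfth since the reported optimum
changes the sludge-removal rate. Bounds form a box around the baseline
(volumes 0.45–2× baseline, KLa1 80–400 d⁻¹, ratios 1–5 / 0.5–1.5 /
0.003–0.03).

Effluent limits default to COD 50, TN 15, NH4-N 5, TP 0.5 g/m³ (the
site's actual limits are not public). Constraint handling adds a large
multiple (1e4) of the total violation fraction to every objective — a
smooth surrogate of feasibility-first domination that pushes violating
solutions behind feasible ones of comparable cost while still ranking
violators among themselves. Candidate simulations that fail outright score
worst-case.

## Optimizers

### SMA and ISMA

The base slime mould algorithm follows the published update: adaptive
weights `W = 1 ± r·log10((FO − C)/(FO − wO) + 1)` (elite half +, mean half
−; weight exactly 1 when all fitnesses coincide), position update with
probability z = 0.03 of a uniform re-draw, otherwise the food-approach move
`yb + kb·(W·yD − yE)` (when `tanh|C − DO| > r`) or the contraction `kc·y`.
`kb ~ U(−a, a)` with `a = arctanh(1 − t/t_max)` (the printed schedule with
its typographical corruption repaired; capped at 0 for t = t_max) and
`kc ~ U(−b, b)`, b decaying linearly 1 → 0. Partners yD, yE are drawn
uniformly, distinct from the mover. ISMA draws per individual per
iteration: SMA move (0.9), opposition-based learning `UB + LB − y` (0.05),
or a Lévy flight around the best (0.05), each kept only if it improves that
individual, so the best-so-far curve is non-increasing.

Lévy steps use the Mantegna construction, `s·σ·u/|v|^{1/β}` with β = 1.5,
s = 0.01, σ = 0.6966 (the printed σ formula is corrupted; the standard
closed form is used and pinned by test). The printed update is
multiplicative (`yb × Levy`); an additive variant is available because the
multiplicative form cannot leave the origin.

### CRFSMA

Multi-objective extension built from three pieces:

1. **Scalarization for the SMA machinery**: individuals are ranked
   lexicographically by (front rank, niche count) and C(i) is the rank
   index; the guiding best is a fresh uniformly random first-front member
   per mover (spread preservation).
2. **Logistic-chaos single-dimension perturbation**: the map
   `M ← 4M(1 − M)` (seeds on the short periodic orbits rejected) drives
   one shared stream; each generation *every* parent contributes a copy
   with one chaotically re-drawn coordinate to the selection pool
   (`chaos_mode="pool"`, the reading that matches "perturbs each
   individual"; the alternative `"redraw"` mode replaces the z-probability
   uniform re-draw instead, and is measurably weaker on the rugged
   three-objective problems).
3. **Reference-point survival**: parents + SMA offspring + chaotic copies
   are reduced to N by fast non-dominated sorting and NSGA-III-style niche
   selection — ideal-point/extreme-intercept normalization (max-range
   fallback on degenerate intercepts), association by perpendicular
   distance to Das-Dennis directions (H = N−1 for two objectives, H = 12
   for three), least-crowded niches filled first, the closest candidate
   seeding an empty niche and a seeded-random pick otherwise.

Populations default to 100 (two objectives) and 91 (= C(14,2), the H = 12
reference-point count) for three. Every optimizer is bit-reproducible
under a fixed seed; bounds are handled by clamping.

### What the benchmarks show — and do not

On UF1/UF3 the implementation reaches mean IGD at or below the published
CRFSMA values. On the ZDT family it converges fully (distance-function
residual ~1e-4) and lands ~10 % above the published means — the residual
is the *placement* floor of direction-uniform niche selection against a
front sampled uniformly in f1, the same floor visible in the published
NSGA-III rows. On DTLZ1 it reaches ~3e-2: the SMA operators lack a
coordinate-preserving crossover, and the multimodal separable distance
function of DTLZ1 rewards exactly that; we do not claim the published
8.2e-3 is reachable with the operators as described. The benchmark suite
asserts the published Min–Max bands as-is, so these show up as honest
failures rather than adjusted tolerances.

## Benchmark problems

Standard published formulas for UF1–3, ZDT1–3, DTLZ1/2/3/7 at the study
configuration (D = 30, M = 2 for the bi-objective set; D = 10, M = 3 for
DTLZ), 1000-generation budgets, vectorized and pinned point-wise (1e-10)
to an independent plain-Python implementation in the tests. The tabulated
bounds for UF1–3 ([−1,1] throughout) and ZDT2 (x_i ∈ [−5,5]) break the
problems as printed — square roots of negative x1, unbounded-below g — so
the defaults use the standard published domains on which the analytic
fronts exist; `printed_bounds=True` reproduces the table exactly for
anyone who wants it.

True fronts: uniform-in-f1 sampling for the f2 = 1−√f1 and 1−f1² families,
per-segment sampling of ZDT3's five disconnected arcs, simplex lattice
(×0.5) for DTLZ1, normalized lattice on the unit sphere for DTLZ2/3, and a
non-dominated filtered grid for DTLZ7. Reference sizes: 1000 (M = 2) /
5000 (M = 3). IGD is the plain mean nearest-neighbour distance from
reference to solutions; 20 independent runs is the default protocol
(the acceptance script trims to 12 to fit a single-CPU session — the
estimator is the same mean either way).

## Calibration

Sensitivity is the summed absolute elasticity
`|((Y1−Y0)/Y0)/((P1−P0)/P0)|` over output samples, one-at-a-time +10 %
perturbation (a central-difference option exists). Outputs are the daily
effluent composites (COD, TN, NH4-N, TP). Selection keeps the top-k by
total sensitivity (k = 8 by default, name-order tie-break); the fit
minimizes ARD = mean|x−y|/x with ISMA inside each parameter's admissible
range, scoring failed simulations worst and never returning a value worse
than the baseline. The acceptance experiment perturbs the top-2 parameters
by +10 %, regenerates "observed" data, and requires recovery within 5 %
with final ARD < 1 % — with a 2-day constant-influent window, which keeps
the ~250-simulation search affordable while leaving the parameters
identifiable.

## Problem sizes used in the shipped checks

The default test suite runs the benchmark reproduction at 3 seeds per
problem (full 1000-generation budgets), the tracer balance over the full
40-day synthetic influent, the calibration loop on a 2-day window with a
2-parameter fit, and the tri-objective demonstration at 6 individuals ×
3 generations on a 2-day scenario. The acceptance script runs 12 seeds per
benchmark problem at full budget. These sizes are the package's own
choices for a single-CPU run; all are plain arguments, and the 20-run /
larger-scenario protocol is available by passing different values.

## Known limitations

- The settler tracks total solids per layer with feed-proportional
  composition, not per-species layer inventories (standard practice, but a
  limitation for strongly time-varying feed composition).
- The EA expression is the printed cost surrogate, not a physical aeration
  energy model; absolute TCI values are index numbers, comparable within a
  study but not across plants.
- The EBPR pathway is fully implemented but inactive at the default
  synthetic loads (see Influent above); scenarios with higher COD:P ratios
  activate it.
- Single-threaded throughout; a 40-day dynamic simulation takes ~30 s and
  a full benchmark run (1000 generations, N = 100) ~8 s on one CPU.
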