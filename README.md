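# sludgeopt

Mechanistic modelling and multi-objective optimization of a modified-A²O
(anaerobic–anoxic–oxic) activated-sludge wastewater treatment train, for
process engineers and researchers who want to ask: *given a plant of this
shape, what combination of recycle rates, aeration intensity and tank
sizing best trades effluent quality against energy cost and built volume?*

The package couples:

- **ASM2d biokinetics** — the 19-component, 21-process IWA model covering
  COD oxidation, nitrification, denitrification and biological phosphorus
  removal, with the stoichiometric matrix assembled from elemental
  conservation (COD/N/P/charge/solids continuity closes to machine
  precision);
- **a ten-layer Takács settler** — double-exponential settling velocity
  with threshold-limited inter-layer flux;
- **a seven-reactor flowsheet** (pre-anoxic → anaerobic → anoxic → aerobic
  → deoxygenation → post-anoxic → post-aerobic → settler, 18,767 m³) with
  internal recycle, sludge return and wastage, integrated as one stiff
  233-state ODE system;
- **slime-mould optimizers** — single-objective SMA/ISMA (opposition-based
  learning + Lévy flight) for kinetic-parameter calibration, and the
  multi-objective CRFSMA (logistic-chaos perturbation + reference-point
  non-dominated sorting) for the design problem;
- **analytic benchmarks** — ZDT/DTLZ/UF test problems with closed-form
  Pareto fronts and IGD scoring, used to validate the optimizer.

The three design objectives are the **mean quality of effluent**
(MQE — average relative improvement over the baseline plant's effluent),
the **total cost index** (TCI = aeration energy + pumping energy +
5 × sludge production) and the **overall volume** (OV = Σ tank volumes),
minimized as (−MQE, TCI, OV) over 12 decision variables subject to
effluent limits.

## Worked example

```python
from sludgeopt.influent import InfluentRecord, generate_synthetic_series
from sludgeopt.plant import PlantConfig, build_flowsheet, simulate, steady_state

model = build_flowsheet(PlantConfig())
rec = InfluentRecord(time=0, flow=35000, COD=260, TN=42, TP=9, NH4N=26, SS=180)
init = steady_state(model, rec)                      # 200-day spin-up + Newton polish
records = generate_synthetic_series(days=5.0, seed=42)
traj = simulate(model, records, init=init)
for k in ("COD", "TN", "NH4N", "TP"):
    print(k, round(float(traj.effluent[k].mean()), 2))
```

prints (g/m³):

```
COD 43.12
TN 10.27
NH4N 0.83
TP 8.41
```

COD, TN and ammonia comply with typical discharge limits (50 / 15 /
5 g/m³) for most of the period; effluent TP stays high because the
synthetic influent — matched to the study period's printed statistics —
carries more phosphorus than the biology can bind into wasted sludge (see
`docs/methods.md` for why that is the physically consistent outcome).

The `examples/` directory holds one short narrative script per capability:
plant simulation, influent synthesis/fractionation, kinetic calibration,
optimizer benchmarking, and tri-objective plant optimization. A thin CLI
mirrors them:

```bash
sludgeopt simulate --days 5 --seed 42 --out sim_out
sludgeopt benchmark --problem ZDT1 --runs 3 --seed 1 --out table.csv
sludgeopt optimize --seed 1 --out opt_out
```

## Layout

| Module | Contents |
| --- | --- |
| `sludgeopt.asm2d` | components, kinetics, conservation-built stoichiometry, composites |
| `sludgeopt.settler` | Takács layered settler |
| `sludgeopt.influent` | fractionation, synthetic generator, CSV I/O |
| `sludgeopt.plant` | flowsheet assembly, stiff integration, steady states, mass balances |
| `sludgeopt.objectives` | MQE, energy terms, solids accounting, TCI, decision evaluation |
| `sludgeopt.optimizers` | SMA, ISMA, CRFSMA |
| `sludgeopt.nds` | non-dominated sorting, Das–Dennis points, niche selection |
| `sludgeopt.benchmarks` | ZDT/DTLZ/UF problems, true fronts, IGD, run harness |
| `sludgeopt.calibration` | sensitivity screening, ARD, ISMA fitting |
| `sludgeopt.moo_plant` | tri-objective plant optimization wrapper |
| `sludgeopt.cli` | `sludgeopt` command-line entry point |

`docs/methods.md` documents the model assumptions, parameter defaults,
numerical choices and the honest limits of what the benchmark and
synthetic-data checks demonstrate.
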