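"""Optimization objectives: effluent-quality improvement (MQE), total cost
index (TCI) and overall volume (OV).

MQE averages the relative deviation of a simulated effluent series from a
reference ("actual") series over all indicators and sampling instants; in
synthetic optimization studies the default-plant effluent plays the role of
the reference, so positive MQE means the candidate improves on the
baseline.  TCI aggregates pumping energy, aeration energy and five times
the sludge production; OV is the summed bioreactor volume.  The printed
aeration-energy expression is kept exactly as published (including its
dimensionally odd volume/temperature ratio); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .asm2d import IDX
from .plant import (
    DEFAULT_EFFLUENT_LIMITS,
    PlantConfig,
    PlantModel,
    PlantTrajectory,
    TankSpec,
    build_flowsheet,
    effluent_limits_check,
    simulate,
)

__all__ = [
    "DecisionVector",
    "ObjectiveTriple",
    "EnergyBreakdown",
    "DecisionBounds",
    "mqe",
    "pumping_energy",
    "aeration_energy",
    "reactor_tss_inventory",
    "settler_tss_series",
    "sludge_production",
    "total_cost_index",
    "OptimizationScenario",
    "evaluate_decision",
]

# ASM1-style Z-groups of the printed solids formulas mapped onto ASM2d
# particulates (documented constant): inerts, substrate, stored products,
# heterotrophs, autotrophs+PAOs.
Z_GROUP_COMPONENTS = ("XI", "XS", "XPHA", "XPP", "XH", "XAUT", "XPAO")
_Z_IDX = np.array([IDX[c] for c in Z_GROUP_COMPONENTS])


@dataclass
class DecisionVector:
    """The 12 operational/design variables of the tri-objective problem.

    Flow ratios (of influent flow): internal recirculation Ql, sludge
    return Qs, wastage Qw; oxygen transfer coefficients of the two aerated
    tanks; and the seven bioreactor volumes T1..T7 (mapped onto the train's
    tanks in order).
    """

    Ql: float
    Qs: float
    Qw: float
    KLa1: float
    KLa2: float
    volumes: tuple  # 7 volumes, m^3

    def __post_init__(self):
        if len(self.volumes) != 7:
            raise ValueError("need exactly 7 tank volumes")

    @classmethod
    def from_array(cls, x) -> "DecisionVector":
        x = np.asarray(x, dtype=float)
        if x.shape != (12,):
            raise ValueError("decision vector has 12 entries")
        return cls(Ql=x[0], Qs=x[1], Qw=x[2], KLa1=x[3], KLa2=x[4], volumes=tuple(x[5:]))

    def to_array(self) -> np.ndarray:
        return np.array([self.Ql, self.Qs, self.Qw, self.KLa1, self.KLa2, *self.volumes])


@dataclass
class DecisionBounds:
    """Box bounds around the baseline operating point."""

    lower: np.ndarray = field(
        default_factory=lambda: np.array(
            [1.0, 0.5, 0.003, 80.0, 20.0, 500.0, 900.0, 2700.0, 3700.0, 200.0, 700.0, 450.0]
        )
    )
    upper: np.ndarray = field(
        default_factory=lambda: np.array(
            [5.0, 1.5, 0.03, 400.0, 150.0, 2300.0, 3700.0, 11000.0, 15000.0, 1000.0, 2900.0, 1900.0]
        )
    )

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower - 1e-12) and np.all(x <= self.upper + 1e-12))


@dataclass
class ObjectiveTriple:
    """(-MQE, TCI, OV) minimization triple with feasibility bookkeeping."""

    mqe: float
    tci: float
    ov: float
    feasible: bool
    violations: dict = field(default_factory=dict)

    def as_min_array(self) -> np.ndarray:
        return np.array([-self.mqe, self.tci, self.ov])

    @property
    def total_violation(self) -> float:
        return float(sum(self.violations.values()))


@dataclass
class EnergyBreakdown:
    EP: float            # pumping, kWh d^-1
    EA: float            # aeration, kWh d^-1 (printed-form units)
    SG: float            # sludge production, kgSS d^-1
    TSS_first: float     # kg
    TSS_final: float     # kg

    def __post_init__(self):
        for name in ("EP", "EA", "TSS_first", "TSS_final"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# elementary formulas


def mqe(actual: dict | np.ndarray, simulated: dict | np.ndarray, on_zero: str = "skip") -> float:
    """Mean relative deviation of simulated from actual effluent quality.

    MQE = mean over indicator x time of (C_actual - C_sim)/C_actual;
    positive when the simulation undercuts the reference, and it may be
    negative.  Zero reference values are skipped with a warning
    (``on_zero="skip"``) or raise (``on_zero="error"``).
    """
    if isinstance(actual, dict):
        keys = sorted(actual)
        if sorted(simulated) != keys:
            raise ValueError("indicator sets differ")
        a = np.concatenate([np.atleast_1d(np.asarray(actual[k], dtype=float)) for k in keys])
        s = np.concatenate([np.atleast_1d(np.asarray(simulated[k], dtype=float)) for k in keys])
    else:
        a = np.asarray(actual, dtype=float).ravel()
        s = np.asarray(simulated, dtype=float).ravel()
    if a.shape != s.shape:
        raise ValueError("series are not aligned")
    mask = a != 0.0
    if not mask.all():
        if on_zero == "error":
            raise ValueError("zero reference concentration in MQE")
        import warnings

        warnings.warn("MQE: skipping zero reference concentrations", stacklevel=2)
    if not mask.any():
        raise ValueError("no usable points for MQE")
    return float(np.mean((a[mask] - s[mask]) / a[mask]))


def pumping_energy(t: np.ndarray, Qh: np.ndarray, Qw: np.ndarray, Qs: np.ndarray) -> float:
    """EP = 0.04/T * integral of (Qh + Qw + Qs) dt, trapezoidal (kWh d^-1)."""
    t = np.asarray(t, dtype=float)
    if len(t) < 2 or t[-1] <= t[0]:
        raise ValueError("need an increasing time grid")
    total = np.asarray(Qh, dtype=float) + np.asarray(Qw, dtype=float) + np.asarray(Qs, dtype=float)
    if np.any(total < 0):
        raise ValueError("negative flow")
    T = t[-1] - t[0]
    return float(0.04 * np.trapezoid(total, t) / T)


def aeration_energy(
    t: np.ndarray,
    Qin: np.ndarray,
    kla: np.ndarray,
    volumes: np.ndarray,
    Tref: float = 7461.0,
) -> float:
    """Aeration energy exactly as printed (kWh d^-1 nominal).

    EA = 24/(t2-t1) * integral of Qin^-1 * sum_i [0.3267 KLa_i + 0.0007
    KLa_i^2] * (T_i/Tref) dt over the configured aerated tanks.  The
    volume-over-reference ratio T_i/Tref is applied literally; Tref
    defaults to the baseline main-aerobic volume so its term is 1 there.
    """
    t = np.asarray(t, dtype=float)
    Qin = np.asarray(Qin, dtype=float)
    if np.any(Qin <= 0):
        raise ValueError("Qin must be positive at every quadrature point")
    kla = np.atleast_2d(np.asarray(kla, dtype=float))     # (n_aerated, nt) or (n_aerated, 1)
    volumes = np.asarray(volumes, dtype=float)
    if np.any(kla < 0):
        raise ValueError("KLa must be non-negative")
    if Tref <= 0:
        raise ValueError("Tref must be positive")
    per_tank = (0.3267 * kla + 0.0007 * kla**2) * (volumes[:, None] / Tref)
    integrand = per_tank.sum(axis=0) / Qin
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("need an increasing time grid")
    return float(np.trapezoid(integrand, t) * 24.0 / span)


def reactor_tss_inventory(tank_states: np.ndarray, volumes: np.ndarray, n_tanks: int | None = None) -> float:
    """Reactor solids inventory, kg: 0.75 * sum_j V_j * (particulate sum)_j.

    Sums the ASM1-style Z groups over all seven bioreactors by default
    (``n_tanks`` restricts to the first n, e.g. 3 for the printed reading).
    """
    S = np.atleast_2d(np.asarray(tank_states, dtype=float))
    V = np.asarray(volumes, dtype=float)
    if n_tanks is not None:
        S, V = S[:n_tanks], V[:n_tanks]
    zsum = S[:, _Z_IDX].sum(axis=1)
    return float(0.75 * (V * zsum).sum() / 1000.0)  # g -> kg


def settler_tss_series(settler_X: np.ndarray, area: float, layer_height: float) -> np.ndarray:
    """Settler solids inventory per time step, kg (0.75-scaled)."""
    X = np.atleast_2d(np.asarray(settler_X, dtype=float))
    return 0.75 * area * layer_height * X.sum(axis=1) / 1000.0


def sludge_production(
    TSS_first: float,
    TSS_final: float,
    t: np.ndarray,
    wastage_z_sum: np.ndarray,
    Qw: np.ndarray,
) -> float:
    """SG = (dTSS + 0.75 * integral of Z_w * Qw dt) / T, kgSS d^-1."""
    t = np.asarray(t, dtype=float)
    T = t[-1] - t[0]
    if T <= 0:
        raise ValueError("need a positive time span")
    wasted = 0.75 * np.trapezoid(np.asarray(wastage_z_sum, dtype=float) * np.asarray(Qw, dtype=float), t) / 1000.0
    return float((TSS_final - TSS_first + wasted) / T)


def total_cost_index(EA: float, EP: float, SG: float) -> float:
    """TCI = EA + EP + 5 * SG."""
    if min(EA, EP) < 0:
        raise ValueError("energy terms must be non-negative")
    return float(EA + EP + 5.0 * SG)


# ---------------------------------------------------------------------------
# decision evaluation


@dataclass
class OptimizationScenario:
    """Frozen evaluation context: influent, baseline effluent, limits.

    The baseline effluent (default plant on the same influent) is the MQE
    reference; candidate plants all start from the supplied initial state
    (typically the baseline steady state).
    """

    records: list
    baseline_effluent: dict
    init: np.ndarray
    base_config: PlantConfig
    limits: dict = field(default_factory=lambda: dict(DEFAULT_EFFLUENT_LIMITS))
    indicators: tuple = ("COD", "TN", "NH4N", "TP")
    rtol: float = 1e-5
    atol: float = 1e-7
    n_out: int = 49
    tci_tref: float = 7461.0
    params: object = None
    scheme: object = None


def scenario_from_baseline(
    records,
    base_config: PlantConfig | None = None,
    init: np.ndarray | None = None,
    params=None,
    scheme=None,
    **kw,
) -> OptimizationScenario:
    """Simulate the default plant over the influent to fix the MQE reference."""
    cfg = base_config or PlantConfig()
    model = build_flowsheet(cfg, params, scheme)
    if init is None:
        from .plant import steady_state, replace_time

        mid = records[len(records) // 2]
        init = steady_state(model, replace_time(mid, 0.0))
    traj = simulate(model, records, init=init, **{k: kw[k] for k in ("rtol", "atol", "n_out") if k in kw})
    scen = OptimizationScenario(
        records=records,
        baseline_effluent={k: traj.effluent[k] for k in ("COD", "TN", "NH4N", "TP")},
        init=init,
        base_config=cfg,
        params=params,
        scheme=scheme,
        **kw,
    )
    return scen


def plant_config_from_decision(x: DecisionVector, base: PlantConfig) -> PlantConfig:
    """Baseline configuration with the decision variables substituted.

    KLa1 maps to the main aerobic tank, KLa2 to the post-aerobic tank.
    """
    tanks = []
    for spec, V in zip(base.tanks, x.volumes):
        kla = spec.kla
        if spec.role == "aerobic":
            kla = x.KLa1
        elif spec.role == "post-aerobic":
            kla = x.KLa2
        tanks.append(TankSpec(spec.name, spec.role, float(V), kla))
    return dc_replace(base, tanks=tanks, Ql=float(x.Ql), Qs=float(x.Qs), Qw=float(x.Qw))


def evaluate_decision(
    x: DecisionVector | np.ndarray,
    scenario: OptimizationScenario,
    bounds: DecisionBounds | None = None,
) -> ObjectiveTriple:
    """Simulate a candidate operating/design point and score it.

    Returns the (-MQE, TCI, OV) triple with feasibility against the
    effluent limits; a failed simulation marks the candidate infeasible
    with worst-case objectives.
    """
    if not isinstance(x, DecisionVector):
        x = DecisionVector.from_array(x)
    if bounds is not None and not bounds.contains(x.to_array()):
        raise ValueError("decision vector out of bounds")

    cfg = plant_config_from_decision(x, scenario.base_config)
    ov = float(sum(x.volumes))
    try:
        model = build_flowsheet(cfg, scenario.params, scenario.scheme)
        traj = simulate(
            model,
            scenario.records,
            init=scenario.init,
            rtol=scenario.rtol,
            atol=scenario.atol,
            n_out=scenario.n_out,
        )
    except Exception:
        return ObjectiveTriple(
            mqe=-np.inf, tci=np.inf, ov=ov, feasible=False,
            violations={k: 1.0 for k in scenario.limits},
        )

    sim_eff = {k: traj.effluent[k] for k in scenario.indicators}
    ref_eff = {k: np.interp(traj.t, traj.t, scenario.baseline_effluent[k])
               if len(scenario.baseline_effluent[k]) == len(traj.t)
               else np.interp(
                   traj.t,
                   np.linspace(traj.t[0], traj.t[-1], len(scenario.baseline_effluent[k])),
                   scenario.baseline_effluent[k],
               )
               for k in scenario.indicators}
    q = mqe(ref_eff, sim_eff)

    tci = tci_from_trajectory(traj, model, tref=scenario.tci_tref)
    check = effluent_limits_check(traj, scenario.limits)
    return ObjectiveTriple(
        mqe=q,
        tci=tci,
        ov=ov,
        feasible=check["feasible"],
        violations={k: v for k, v in check["violations"].items() if v > 0},
    )


def tci_from_trajectory(traj: PlantTrajectory, model: PlantModel, tref: float = 7461.0) -> float:
    """Assemble EA + EP + 5 SG from a simulated trajectory."""
    cfg = model.cfg
    t = traj.t
    nt = len(t)
    Qin = traj.influent_flow
    if Qin is None:
        raise ValueError("trajectory lacks the influent flow series")
    Qh = cfg.Ql * Qin
    Qs = cfg.Qs * Qin
    Qw = cfg.Qw * Qin

    EP = pumping_energy(t, Qh, Qw, Qs)
    aerated = [(i, tk) for i, tk in enumerate(cfg.tanks) if tk.kla > 0]
    if aerated:
        kla = np.array([[tk.kla] * nt for _, tk in aerated])
        vols = np.array([tk.volume for _, tk in aerated])
        EA = aeration_energy(t, Qin, kla, vols, Tref=tref)
    else:
        EA = 0.0

    s = cfg.settler
    tss_settler = settler_tss_series(traj.settler_X, s.area, s.layer_height)
    vols7 = np.array([tk.volume for tk in cfg.tanks])
    tss_react = np.array([reactor_tss_inventory(traj.tank_states[i], vols7) for i in range(nt)])
    total = tss_settler + tss_react
    # wastage composition = settler underflow particulates
    feed_z = traj.tank_states[:, 6, :][:, _Z_IDX].sum(axis=1)
    feed_tss = np.maximum(np.array([model._tss_of(traj.tank_states[i, 6][None, :])[0] for i in range(nt)]), 1e-9)
    under_z = feed_z / feed_tss * traj.settler_X[:, -1]
    SG = sludge_production(total[0], total[-1], t, under_z, Qw)
    SG = max(SG, 0.0)
    return total_cost_index(EA, EP, SG)
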