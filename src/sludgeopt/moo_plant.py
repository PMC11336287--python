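"""Tri-objective plant optimization: CRFSMA over the 12 decision variables.

Wires the plant simulator and the (-MQE, TCI, OV) objectives into the
multi-objective optimizer.  Effluent-limit constraints are handled by a
violation penalty added to every objective (a smooth stand-in for
feasibility-first domination: any violating solution is pushed behind all
feasible ones of comparable cost).
"""

from __future__ import annotations

import numpy as np

from .benchmarks import igd  # noqa: F401  (re-export convenience)
from .influent import generate_synthetic_series
from .objectives import (
    DecisionBounds,
    ObjectiveTriple,
    evaluate_decision,
    scenario_from_baseline,
)
from .optimizers import ParetoArchive, SmaConfig, crfsma_optimize
from .plant import PlantConfig

__all__ = ["plant_objective", "optimize_plant"]

_PENALTY = 1e4


def plant_objective(scenario, bounds: DecisionBounds, cache: dict | None = None):
    """(n, 12) decision matrix -> (n, 3) penalized minimization objectives."""

    def fn(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        out = np.empty((len(X), 3))
        for i, row in enumerate(X):
            key = tuple(np.round(row, 9)) if cache is not None else None
            if key is not None and key in cache:
                trip = cache[key]
            else:
                trip = evaluate_decision(row, scenario)
                if key is not None:
                    cache[key] = trip
            f = trip.as_min_array()
            if not np.all(np.isfinite(f)):
                f = np.array([1.0, 1e9, 1e9])
            if not trip.feasible:
                f = f + _PENALTY * trip.total_violation
            out[i] = f
        return out

    return fn


def optimize_plant(
    days: float = 3.0,
    n_pop: int = 8,
    generations: int = 5,
    seed: int = 0,
    base_config: PlantConfig | None = None,
    records=None,
    bounds: DecisionBounds | None = None,
    scenario_kw: dict | None = None,
) -> tuple[ParetoArchive, list[ObjectiveTriple]]:
    """Run CRFSMA on a synthetic (or supplied) scenario.

    Returns the final archive (decision vectors + penalized objectives)
    and the unpenalized ObjectiveTriple of each front member.  Small
    populations and few generations keep a single run affordable; each
    objective evaluation is a full plant simulation.
    """
    if records is None:
        records = generate_synthetic_series(days=days, seed=seed)
    bounds = bounds or DecisionBounds()
    scenario = scenario_from_baseline(records, base_config, **(scenario_kw or {}))

    cache: dict = {}
    fn = plant_objective(scenario, bounds, cache)
    cfg = SmaConfig(
        n_pop=n_pop,
        max_iter=generations,
        lower=bounds.lower,
        upper=bounds.upper,
        seed=seed,
    )
    archive = crfsma_optimize(fn, dim=12, n_obj=3, cfg=cfg, ref_divisions=4)
    triples = [evaluate_decision(x, scenario) for x in archive.X]
    return archive, triples
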