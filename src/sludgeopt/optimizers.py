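"""Slime-mould optimizers: SMA, ISMA and the multi-objective CRFSMA.

The base slime mould algorithm (SMA) moves a population with an adaptive
weight vector built from the sorted fitness ranking.  ISMA augments it with
opposition-based learning (OBL) and Levy-flight restarts at fixed branch
probabilities (0.9 / 0.05 / 0.05).  CRFSMA extends SMA to multiple
objectives with a one-dimensional logistic-chaos perturbation in place of
the uniform random re-draw and an elitist reference-point non-dominated
sorting survival step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nds import (
    FrontPartition,
    ReferencePointSet,
    associate,
    fast_nondominated_sort,
    niche_counts,
    niche_select,
    normalize_objectives,
    reference_points,
)

__all__ = [
    "SmaConfig",
    "LevyConfig",
    "ParetoArchive",
    "sma_weights",
    "sma_move",
    "obl_opposite",
    "mantegna_sigma",
    "levy_step",
    "logistic_chaos_sequence",
    "chaos_perturb",
    "isma_minimize",
    "crfsma_optimize",
]


@dataclass
class SmaConfig:
    """Shared SMA run settings.

    z is the probability of the global random re-draw (0.03 in the source
    algorithm); bounds are per-dimension arrays (broadcastable scalars OK).
    """

    n_pop: int = 30
    max_iter: int = 200
    z: float = 0.03
    lower: np.ndarray | float = 0.0
    upper: np.ndarray | float = 1.0
    seed: int | None = None
    log_base10: bool = True

    def __post_init__(self) -> None:
        if self.n_pop < 4:
            raise ValueError("population size must be >= 4")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.z <= 1.0:
            raise ValueError("z must lie in [0, 1]")

    def bounds_arrays(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        lb = np.broadcast_to(np.asarray(self.lower, dtype=float), (dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.upper, dtype=float), (dim,)).copy()
        if np.any(ub <= lb):
            raise ValueError("upper bounds must exceed lower bounds")
        return lb, ub


@dataclass
class LevyConfig:
    """Levy-flight constants: stability index beta and step scale s."""

    beta: float = 1.5
    s: float = 0.01
    additive: bool = False  # multiplicative form as printed by default

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 2.0:
            raise ValueError("beta must lie in (0, 2]")
        if self.s < 0.0:
            raise ValueError("s must be >= 0")


@dataclass
class ParetoArchive:
    """Final non-dominated set of a multi-objective run."""

    X: np.ndarray                      # (n, D) decision vectors
    F: np.ndarray                      # (n, M) objective vectors
    config: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "history": self.history,
            "front_X": self.X.tolist(),
            "front_F": self.F.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        d = self.X.shape[1]
        m = self.F.shape[1]
        cols = [f"x{i + 1}" for i in range(d)] + [f"f{i + 1}" for i in range(m)]
        pd.DataFrame(np.hstack([self.X, self.F]), columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary SMA operators


def sma_weights(
    C: np.ndarray,
    rng: np.random.Generator,
    dim: int = 1,
    log_base10: bool = True,
) -> np.ndarray:
    """Adaptive weight per individual (shape (N, dim)), minimization.

    The better (elite) half of the sorted population receives
    1 + r*log10((FO - C)/(FO - wO) + 1) and the mean half
    1 - r*log10(...); when every fitness coincides the weight degenerates
    to exactly 1.
    """
    C = np.asarray(C, dtype=float)
    n = len(C)
    if n == 0:
        raise ValueError("empty population")
    FO = C.min()
    wO = C.max()
    r = rng.random((n, dim))
    if FO == wO:
        return np.ones((n, dim))
    frac = (FO - C) / (FO - wO) + 1.0  # in [1, 2]
    logf = np.log10(frac) if log_base10 else np.log(frac)
    order = np.argsort(C, kind="stable")
    elite = np.zeros(n, dtype=bool)
    elite[order[: (n + 1) // 2]] = True
    sign = np.where(elite, 1.0, -1.0)[:, None]
    return 1.0 + sign * r * logf[:, None]


def sma_move(
    Y: np.ndarray,
    C: np.ndarray,
    yb: np.ndarray,
    W: np.ndarray,
    t: int,
    cfg: SmaConfig,
    rng: np.random.Generator,
    DO: float | None = None,
    redraw: bool = True,
) -> np.ndarray:
    """One SMA position update for the whole population.

    Branches per individual: with probability z a uniform re-draw in the box
    (suppressed when ``redraw`` is False, leaving the row for the caller to
    perturb); otherwise the food-approach move
    y* = yb + kb*(W*yD - yE) when p > r, else the contraction y* = kc*y.
    kb ~ U(-a, a) with a = arctanh(1 - t/t_max); kc ~ U(-b, b) with b
    decaying linearly from 1 to 0.  ``yb`` may be a single guiding position
    or one row per individual; yD and yE are random population members
    distinct from the mover.
    """
    if t > cfg.max_iter:
        raise ValueError("iteration beyond max_iter")
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    lb, ub = cfg.bounds_arrays(d)
    C = np.asarray(C, dtype=float)
    if DO is None:
        DO = float(C.min())

    a = math.atanh(max(1.0 - t / cfg.max_iter, 0.0)) if t < cfg.max_iter else 0.0
    b = max(1.0 - t / cfg.max_iter, 0.0)

    out = Y.copy()
    u = rng.random(n)
    redraw_mask = u < cfg.z
    p = np.tanh(np.abs(C - DO))
    approach = (~redraw_mask) & (p > rng.random(n))
    contract = ~(redraw_mask | approach)

    if redraw_mask.any() and redraw:
        k = int(redraw_mask.sum())
        out[redraw_mask] = lb + (ub - lb) * rng.random((k, d))

    if approach.any():
        idx = np.flatnonzero(approach)
        yb_rows = np.atleast_2d(np.asarray(yb, dtype=float))
        yb_sel = yb_rows[0] if len(yb_rows) == 1 else yb_rows[idx]
        if n >= 3:  # partners distinct from the mover
            iD = (idx + 1 + rng.integers(n - 1, size=idx.size)) % n
            iE = (idx + 1 + rng.integers(n - 1, size=idx.size)) % n
        else:
            iD = rng.integers(n, size=idx.size)
            iE = rng.integers(n, size=idx.size)
        kb = rng.uniform(-a, a, size=(idx.size, d))
        out[idx] = yb_sel + kb * (W[idx] * Y[iD] - Y[iE])

    if contract.any():
        idx = np.flatnonzero(contract)
        kc = rng.uniform(-b, b, size=(idx.size, d))
        out[idx] = Y[idx] * kc

    np.clip(out, lb, ub, out=out)
    # report which rows were flagged for re-draw so CRFSMA can chaos-perturb
    out_mask = redraw_mask if not redraw else None
    return (out, out_mask) if not redraw else out


def obl_opposite(y: np.ndarray, upper: np.ndarray, lower: np.ndarray) -> np.ndarray:
    """Boundary-reflected opposite point y' = UB + LB - y (an involution)."""
    return np.asarray(upper) + np.asarray(lower) - np.asarray(y)


def mantegna_sigma(beta: float) -> float:
    """Mantegna scale constant for Levy-stable step generation."""
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(
    yb: np.ndarray,
    dim: int,
    cfg: LevyConfig,
    rng: np.random.Generator,
    lower: np.ndarray | float = 0.0,
    upper: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Levy-flight proposal around the best position.

    Per dimension the step is s*sigma*u/|v|^(1/beta) with u, v standard
    normal; the printed form multiplies yb by the step, the additive
    variant (cfg.additive) adds it so a zero best position can still move.
    """
    sigma = mantegna_sigma(cfg.beta)
    u = rng.standard_normal(dim)
    v = rng.standard_normal(dim)
    step = cfg.s * sigma * u / np.abs(v) ** (1.0 / cfg.beta)
    y = yb + step if cfg.additive else yb * step
    lb = np.broadcast_to(np.asarray(lower, dtype=float), (dim,))
    ub = np.broadcast_to(np.asarray(upper, dtype=float), (dim,))
    return np.clip(y, lb, ub)


_FORBIDDEN_CHAOS_SEEDS = (0.0, 0.25, 0.5, 0.75, 1.0)


def logistic_chaos_sequence(m0: float, length: int) -> np.ndarray:
    """Logistic-map sequence M(t+1) = 4*M(t)*(1 - M(t)).

    Seeds on the short periodic orbits (0, 0.25, 0.5, 0.75, 1) are rejected:
    0.75 is a fixed point and the others collapse onto it or onto 0.
    """
    if not 0.0 < m0 < 1.0 or any(abs(m0 - f) < 1e-12 for f in _FORBIDDEN_CHAOS_SEEDS):
        raise ValueError("chaos seed must be in (0,1) excluding {0.25, 0.5, 0.75}")
    seq = np.empty(length)
    m = m0
    for i in range(length):
        seq[i] = m
        m = 4.0 * m * (1.0 - m)
    return seq


class _ChaosStream:
    """Shared logistic-map stream yielding one chaotic number per call."""

    def __init__(self, m0: float):
        if not 0.0 < m0 < 1.0 or any(abs(m0 - f) < 1e-12 for f in _FORBIDDEN_CHAOS_SEEDS):
            raise ValueError("chaos seed must be in (0,1) excluding {0.25, 0.5, 0.75}")
        self.m = m0

    def next(self) -> float:
        out = self.m
        self.m = 4.0 * self.m * (1.0 - self.m)
        return out


def chaos_perturb(
    y: np.ndarray,
    j: int,
    m: float,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Replace dimension j by the chaotic point lb_j + m*(ub_j - lb_j)."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("chaotic value must lie in [0, 1]")
    out = np.array(y, dtype=float, copy=True)
    out[j] = lower[j] + m * (upper[j] - lower[j])
    return out


# ---------------------------------------------------------------------------
# single-objective ISMA


def isma_minimize(
    objective,
    dim: int,
    cfg: SmaConfig,
    levy: LevyConfig | None = None,
    callback=None,
) -> dict:
    """Minimize a scalar objective with the improved slime mould algorithm.

    Per individual per iteration one of three proposals is drawn -- the SMA
    move (p=0.9), opposition-based learning (p=0.05) or a Levy flight around
    the best (p=0.05) -- and kept only if it improves that individual
    (greedy elitism), so the best-so-far curve is non-increasing.  The
    objective may be vectorized (accepting an (n, D) array); scalar
    callables are wrapped.

    Returns dict with best_x, best_f, history (best-so-far per iteration),
    n_evals.
    """
    levy = levy or LevyConfig()
    rng = np.random.default_rng(cfg.seed)
    lb, ub = cfg.bounds_arrays(dim)

    def evaluate(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        try:
            vals = np.asarray(objective(X), dtype=float).reshape(-1)
            if vals.shape[0] != X.shape[0]:
                raise ValueError
        except Exception:
            vals = np.array([float(objective(x)) for x in X])
        return np.where(np.isnan(vals), np.inf, vals)

    Y = lb + (ub - lb) * rng.random((cfg.n_pop, dim))
    C = evaluate(Y)
    n_evals = cfg.n_pop
    best_i = int(C.argmin())
    best_x, best_f = Y[best_i].copy(), float(C[best_i])
    history = [best_f]

    for t in range(1, cfg.max_iter + 1):
        W = sma_weights(C, rng, dim=dim, log_base10=cfg.log_base10)
        branch = rng.random(cfg.n_pop)
        second = rng.random(cfg.n_pop)
        proposals = np.empty_like(Y)

        sma_mask = branch < 0.9
        obl_mask = (~sma_mask) & (second <= 0.5)
        levy_mask = (~sma_mask) & (~obl_mask)

        if sma_mask.any():
            moved = sma_move(Y, C, best_x, W, t, cfg, rng, DO=best_f)
            proposals[sma_mask] = moved[sma_mask]
        if obl_mask.any():
            proposals[obl_mask] = obl_opposite(Y[obl_mask], ub, lb)
        for i in np.flatnonzero(levy_mask):
            proposals[i] = levy_step(best_x, dim, levy, rng, lb, ub)

        np.clip(proposals, lb, ub, out=proposals)
        Cp = evaluate(proposals)
        n_evals += cfg.n_pop
        improved = Cp < C
        Y[improved] = proposals[improved]
        C[improved] = Cp[improved]

        i = int(C.argmin())
        if C[i] < best_f:
            best_f = float(C[i])
            best_x = Y[i].copy()
        history.append(best_f)
        if callback is not None:
            callback(t, best_x, best_f)

    return {
        "best_x": best_x,
        "best_f": best_f,
        "history": np.asarray(history),
        "n_evals": n_evals,
    }


# ---------------------------------------------------------------------------
# multi-objective CRFSMA


def _rank_indices(F: np.ndarray, refs: ReferencePointSet) -> tuple[np.ndarray, FrontPartition]:
    """Scalar surrogate fitness: lexicographic (front rank, niche count).

    Returns C with C[i] = position of solution i in that ordering, so the
    SMA weight/branch machinery sees rank 0 as the finest objective value.
    """
    part = fast_nondominated_sort(F)
    counts = niche_counts(F, part, refs)
    order = np.lexsort((counts, part.rank))
    C = np.empty(len(F), dtype=float)
    C[order] = np.arange(len(F), dtype=float)
    return C, part


def crfsma_optimize(
    problem,
    dim: int,
    n_obj: int,
    cfg: SmaConfig,
    ref_divisions: int | None = None,
    chaos_seed: float = 0.7,
    chaos_mode: str = "pool",
    history_every: int = 0,
    history_fn=None,
) -> ParetoArchive:
    """Multi-objective slime mould optimization (CRFSMA).

    Each generation the population is ranked by (front rank, niche count)
    to drive the scalar SMA machinery and moved by the SMA update with a
    random first-front member as the guiding best.  The logistic-chaos
    single-dimension perturbation is applied to every individual: a copy
    of each parent with one chaotically re-drawn coordinate joins the
    selection pool (``chaos_mode="pool"``, the default, matching "perturbs
    each individual"); the alternative ``"redraw"`` mode instead replaces
    the z-probability uniform re-draw inside the SMA move.  The pooled
    parents and proposals are reduced back to N by fast non-dominated
    sorting with reference-point niche selection, and the final first
    front is returned.

    ``problem`` must map an (n, D) array to an (n, M) array.
    """
    if chaos_mode not in ("pool", "redraw"):
        raise ValueError("chaos_mode must be 'pool' or 'redraw'")
    if n_obj < 2:
        raise ValueError("need at least two objectives")
    rng = np.random.default_rng(cfg.seed)
    lb, ub = cfg.bounds_arrays(dim)
    if ref_divisions is None:
        # match reference-point count to the population for M=3 (H=12 -> 91),
        # dense line for M=2
        ref_divisions = cfg.n_pop - 1 if n_obj == 2 else 12
    refs = reference_points(n_obj, ref_divisions)
    chaos = _ChaosStream(chaos_seed)

    def evaluate(X: np.ndarray) -> np.ndarray:
        F = np.asarray(problem(np.atleast_2d(X)), dtype=float)
        return np.where(np.isnan(F), np.inf, F)

    Y = lb + (ub - lb) * rng.random((cfg.n_pop, dim))
    F = evaluate(Y)
    history: list = []

    for t in range(1, cfg.max_iter + 1):
        C, part = _rank_indices(F, refs)
        W = sma_weights(C, rng, dim=dim, log_base10=cfg.log_base10)
        f1 = part.fronts[0]
        # a fresh random first-front guide per mover preserves spread
        yb = Y[f1[rng.integers(len(f1), size=cfg.n_pop)]]

        if chaos_mode == "pool":
            prop = sma_move(Y, C, yb, W, t, cfg, rng, DO=0.0)
            # one-dimension chaotic copy of every parent joins the pool
            js = rng.integers(dim, size=cfg.n_pop)
            ms = np.array([chaos.next() for _ in range(cfg.n_pop)])
            chaotic = Y.copy()
            chaotic[np.arange(cfg.n_pop), js] = lb[js] + ms * (ub[js] - lb[js])
            poolY = np.vstack([Y, prop, chaotic])
            poolF = np.vstack([F, evaluate(prop), evaluate(chaotic)])
        else:
            prop, redraw_mask = sma_move(Y, C, yb, W, t, cfg, rng, DO=0.0, redraw=False)
            for i in np.flatnonzero(redraw_mask):
                j = int(rng.integers(dim))
                prop[i] = chaos_perturb(Y[i], j, chaos.next(), lb, ub)
            poolY = np.vstack([Y, prop])
            poolF = np.vstack([F, evaluate(prop)])

        pool_part = fast_nondominated_sort(poolF)
        keep = niche_select(poolF, pool_part, refs, cfg.n_pop, rng)
        Y, F = poolY[keep], poolF[keep]

        if history_every and (t % history_every == 0 or t == cfg.max_iter):
            front = fast_nondominated_sort(F).fronts[0]
            entry = {"iteration": t}
            if history_fn is not None:
                entry["metric"] = float(history_fn(F[front]))
            history.append(entry)

    final = fast_nondominated_sort(F).fronts[0]
    # drop duplicate objective rows for a clean front
    Ff = F[final]
    _, uniq = np.unique(np.round(Ff, 12), axis=0, return_index=True)
    final = final[np.sort(uniq)]
    return ParetoArchive(
        X=Y[final],
        F=F[final],
        config={
            "n_pop": cfg.n_pop,
            "max_iter": cfg.max_iter,
            "z": cfg.z,
            "seed": cfg.seed,
            "ref_divisions": ref_divisions,
            "chaos_seed": chaos_seed,
            "chaos_mode": chaos_mode,
        },
        history=history,
    )
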