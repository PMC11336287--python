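"""Pareto machinery: non-dominated sorting, reference points, niche selection.

Selection follows the reference-point scheme of NSGA-III: after fast
non-dominated sorting, the last admitted front is thinned by associating each
candidate with the nearest reference direction on the normalized unit
hyperplane and filling the least crowded niches first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = [
    "FrontPartition",
    "ReferencePointSet",
    "dominance_matrix",
    "fast_nondominated_sort",
    "reference_points",
    "normalize_objectives",
    "associate",
    "niche_select",
]


@dataclass
class FrontPartition:
    """Ordered Pareto fronts plus per-solution bookkeeping."""

    fronts: list[np.ndarray]          # index arrays, F1 first
    rank: np.ndarray                  # front rank per solution, 0-based
    domination_count: np.ndarray      # n_p: how many solutions dominate p

    @property
    def n_fronts(self) -> int:
        return len(self.fronts)


@dataclass
class ReferencePointSet:
    """Das-Dennis simplex-lattice directions on the unit hyperplane."""

    points: np.ndarray                # (R, M), rows sum to 1
    divisions: int
    niche_count: np.ndarray = field(default=None)  # filled during selection

    def __len__(self) -> int:
        return len(self.points)


def dominance_matrix(F: np.ndarray) -> np.ndarray:
    """Boolean matrix D with D[i, j] True iff solution i Pareto-dominates j.

    Minimization convention: i dominates j when i is no worse in every
    objective and strictly better in at least one.
    """
    F = np.asarray(F, dtype=float)
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    return le & lt


def fast_nondominated_sort(F: np.ndarray) -> FrontPartition:
    """Partition objective vectors (N x M, minimization) into Pareto fronts.

    Iterative peeling: F1 holds every solution with domination count
    n_p = 0; removing a front decrements the counts of the solutions it
    dominates, and those reaching zero form the next front.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n = len(F)
    if n == 0:
        raise ValueError("empty objective set")
    dom = dominance_matrix(F)
    n_p = dom.sum(axis=0).astype(np.int64)
    rank = np.full(n, -1, dtype=np.int64)
    n_p0 = n_p.copy()

    fronts: list[np.ndarray] = []
    current = np.flatnonzero(n_p == 0)
    level = 0
    while current.size:
        rank[current] = level
        fronts.append(current)
        # solutions dominated by the current front lose one dominator each
        n_p -= dom[current].sum(axis=0)
        n_p[current] = -1  # never re-admitted
        current = np.flatnonzero(n_p == 0)
        level += 1
    return FrontPartition(fronts=fronts, rank=rank, domination_count=n_p0)


def reference_points(M: int, divisions: int) -> ReferencePointSet:
    """Evenly spaced points on the M-dimensional unit simplex.

    The Das-Dennis construction with H divisions yields C(H+M-1, M-1)
    points whose coordinates are multiples of 1/H summing to 1.
    """
    if M < 2:
        raise ValueError("need at least two objectives")
    if divisions < 1:
        raise ValueError("divisions must be >= 1")

    out: list[list[float]] = []

    def recurse(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            out.append(prefix + [remaining])
            return
        for v in range(remaining + 1):
            recurse(prefix + [v], remaining - v, slots - 1)

    recurse([], divisions, M)
    pts = np.asarray(out, dtype=float) / divisions
    assert len(pts) == comb(divisions + M - 1, M - 1)
    return ReferencePointSet(points=pts, divisions=divisions)


def normalize_objectives(F: np.ndarray) -> np.ndarray:
    """Map objectives onto [0, 1]-ish via ideal point and extreme intercepts.

    The ideal point is the per-objective minimum; intercepts come from the
    M extreme points minimizing the achievement scalarizing function along
    each axis.  Degenerate intercept systems (singular, non-positive, or
    wildly scaled) fall back to the per-objective range.
    """
    F = np.asarray(F, dtype=float)
    ideal = F.min(axis=0)
    Fp = F - ideal
    M = F.shape[1]

    # extreme point per axis via ASF with near-axis weights
    eps = 1e-6
    asf_w = np.full((M, M), eps)
    np.fill_diagonal(asf_w, 1.0)
    # asf[i, k] = max_m Fp[k, m] / w[i, m]
    asf = (Fp[None, :, :] / asf_w[:, None, :]).max(axis=2)
    extremes = Fp[asf.argmin(axis=1)]  # (M, M)

    intercepts = None
    try:
        b = np.linalg.solve(extremes, np.ones(M))
        with np.errstate(divide="ignore", over="ignore"):
            cand = 1.0 / b
        if np.all(np.isfinite(cand)) and np.all(cand > 1e-12):
            intercepts = cand
    except np.linalg.LinAlgError:
        pass
    if intercepts is None:
        intercepts = Fp.max(axis=0)
    intercepts = np.where(intercepts > 1e-12, intercepts, 1.0)
    return Fp / intercepts


def associate(Fn: np.ndarray, refs: ReferencePointSet) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference direction per solution (index, perpendicular distance)."""
    Z = refs.points
    w = Z / np.linalg.norm(Z, axis=1, keepdims=True)  # unit directions (R, M)
    proj = Fn @ w.T                                   # (N, R) scalar projections
    # squared perpendicular distance ||f||^2 - proj^2
    d2 = np.maximum((Fn * Fn).sum(axis=1)[:, None] - proj**2, 0.0)
    idx = d2.argmin(axis=1)
    return idx, np.sqrt(d2[np.arange(len(Fn)), idx])


def niche_select(
    F: np.ndarray,
    partition: FrontPartition,
    refs: ReferencePointSet,
    n_select: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Choose ``n_select`` survivors from a pooled population.

    Whole fronts are admitted until the next front overflows; the overflow
    front is thinned by ascending niche count with seeded random tie-breaks
    (the least represented reference directions are filled first, the
    closest candidate seeding an empty niche).
    Returns the selected indices into ``F``.
    """
    F = np.asarray(F, dtype=float)
    if not 0 < n_select <= len(F):
        raise ValueError("n_select out of range")

    chosen: list[np.ndarray] = []
    total = 0
    last = None
    for front in partition.fronts:
        if total + len(front) <= n_select:
            chosen.append(front)
            total += len(front)
            if total == n_select:
                refs.niche_count = None
                return np.concatenate(chosen)
        else:
            last = front
            break
    assert last is not None
    T = n_select - total

    pool = np.concatenate(chosen + [last]) if chosen else last
    Fn = normalize_objectives(F[pool])
    ref_idx, dist = associate(Fn, refs)
    n_kept = total  # first n_kept entries of pool are already selected
    R = len(refs)
    niche = np.bincount(ref_idx[:n_kept], minlength=R)

    cand_ref = ref_idx[n_kept:]
    cand_dist = dist[n_kept:]
    cand_ids = last.copy()
    alive = np.ones(len(cand_ids), dtype=bool)

    picked: list[int] = []
    active_refs = set(np.unique(cand_ref).tolist())
    while len(picked) < T:
        # reference direction with minimal niche count among those that
        # still have living candidates; random tie-break
        act = np.fromiter(active_refs, dtype=np.int64)
        counts = niche[act]
        minval = counts.min()
        ties = act[counts == minval]
        j = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
        members = np.flatnonzero(alive & (cand_ref == j))
        if members.size == 0:
            active_refs.discard(int(j))
            continue
        if niche[j] == 0:
            k = members[cand_dist[members].argmin()]
        else:
            k = members[rng.integers(members.size)]
        picked.append(int(cand_ids[k]))
        alive[k] = False
        niche[j] += 1
        if not (alive & (cand_ref == j)).any():
            active_refs.discard(int(j))

    refs.niche_count = niche
    return np.concatenate(chosen + [np.asarray(picked, dtype=np.int64)]) if chosen else np.asarray(picked, dtype=np.int64)


def niche_counts(F: np.ndarray, partition: FrontPartition, refs: ReferencePointSet) -> np.ndarray:
    """Per-solution niche count of the reference direction each associates with."""
    Fn = normalize_objectives(np.asarray(F, dtype=float))
    ref_idx, _ = associate(Fn, refs)
    per_ref = np.bincount(ref_idx, minlength=len(refs))
    return per_ref[ref_idx]
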