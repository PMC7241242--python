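"""Independent brute-force oracles used by the test suite.

Nothing here calls the package's solvers: linear programs are checked by
basic-feasible-point enumeration, the min-norm QP by a closed-form KKT
solve, quantiles by manual sort-and-interpolate, and clustering by a
naive O(n^3) agglomeration straight from the average-linkage definition.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np


def enumerate_vertices(
    S: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    extra_eq: Optional[Tuple[np.ndarray, float]] = None,
) -> List[np.ndarray]:
    """All basic feasible points of {A v = b, l <= v <= u} by enumeration.

    Only for tiny systems (n <= ~10). ``extra_eq`` appends one equality
    row (row, rhs).
    """
    if extra_eq is None:
        A = np.asarray(S, dtype=float)
        b = np.zeros(A.shape[0])
    else:
        row, rhs = extra_eq
        A = np.vstack([S, np.asarray(row, dtype=float)])
        b = np.concatenate([np.zeros(S.shape[0]), [rhs]])
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    k = n - rank
    vertices: List[np.ndarray] = []
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        for pattern in itertools.product((0, 1), repeat=k):
            x = np.zeros(n)
            feasible = True
            for j, side in zip(fixed, pattern):
                val = lower[j] if side == 0 else upper[j]
                if not np.isfinite(val):
                    feasible = False
                    break
                x[j] = val
            if not feasible:
                continue
            rhs = b - A[:, list(fixed)] @ x[list(fixed)]
            sol, *_ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
            x[free] = sol
            if np.max(np.abs(A @ x - b), initial=0.0) > 1e-8:
                continue
            if np.any(x < lower - 1e-9) or np.any(x > upper + 1e-9):
                continue
            vertices.append(np.clip(x, lower, upper))
    return vertices


def lp_max_oracle(S, lower, upper, c) -> Tuple[Optional[float], List[np.ndarray]]:
    """Maximum of c'v over the flux polytope, with the optimal vertices."""
    vertices = enumerate_vertices(S, lower, upper)
    if not vertices:
        return None, []
    values = [float(np.dot(c, v)) for v in vertices]
    best = max(values)
    optima = [v for v, z in zip(vertices, values) if z > best - 1e-9]
    return best, optima


def qp_min_norm_oracle(S, c, z_target) -> np.ndarray:
    """argmin ||v||^2 s.t. S v = 0, c'v = z_target (no active bounds).

    Closed form: v = A' (A A')^+ b for A = [S; c'].
    """
    A = np.vstack([S, np.asarray(c, dtype=float)[None, :]])
    b = np.concatenate([np.zeros(S.shape[0]), [z_target]])
    lam, *_ = np.linalg.lstsq(A @ A.T, b, rcond=None)
    return A.T @ lam


def gimme_penalty_oracle(S, lower, upper, c, weights, target) -> float:
    """Minimum of sum(w |v|) over {S v = 0, bounds, c'v >= target}.

    The minimum of a concave-free piecewise-linear objective over a
    polytope is attained at a vertex; with non-negative lower bounds
    (irreversible toys) |v| = v and the objective is linear, so it
    suffices to scan vertices of the region -- both those where the
    biomass inequality is slack (vertices of the base polytope) and
    those where it is active (extra equality row).
    """
    assert np.all(lower >= 0), "oracle assumes irreversible (|v| = v) toys"
    w = np.asarray(weights, dtype=float)
    candidates = [
        v for v in enumerate_vertices(S, lower, upper)
        if np.dot(c, v) >= target - 1e-9
    ]
    candidates += enumerate_vertices(S, lower, upper, extra_eq=(c, target))
    assert candidates, "oracle found no feasible point"
    return min(float(np.dot(w, v)) for v in candidates)


def quantile_oracle(values: Sequence[float], q: float) -> float:
    """Sorted-array linear interpolation, written out longhand."""
    xs = sorted(values)
    if not xs:
        raise ValueError("empty")
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def agglomerate_oracle(profiles: Dict[str, np.ndarray], cut: float) -> Set[frozenset]:
    """Average-linkage agglomeration on 1 - Pearson r, from the definition.

    Cluster-cluster distance is the mean of original pairwise distances;
    merging proceeds greedily while the closest pair is within ``cut``.
    """
    ids = sorted(profiles)

    def dist(a: str, b: str) -> float:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(profiles[a], profiles[b])[0, 1]
        return 1.0 - (r if np.isfinite(r) else -1.0)

    base = {(a, b): dist(a, b) for a, b in itertools.combinations(ids, 2)}

    def pair_dist(a: str, b: str) -> float:
        return base[(a, b) if (a, b) in base else (b, a)]

    clusters: List[Set[str]] = [{i} for i in ids]
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            avg = float(np.mean([
                pair_dist(a, b) for a in clusters[i] for b in clusters[j]
            ]))
            if best is None or avg < best[0] - 1e-12:
                best = (avg, i, j)
        if best[0] > cut:
            break
        _, i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return {frozenset(group) for group in clusters}
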