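"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(n²) loops, closed forms,
exhaustive enumeration — and shares no code with the package internals it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_nn(ref_xy: np.ndarray, tgt_xy: np.ndarray, same=None) -> np.ndarray:
    """All-pairs nearest-neighbor distances; ``same[i]`` optionally gives
    the target row that is the same physical cell as ref i (excluded)."""
    out = []
    for i, p in enumerate(ref_xy):
        best = math.inf
        for j, q in enumerate(tgt_xy):
            if same is not None and same[i] == j:
                continue
            d = math.hypot(p[0] - q[0], p[1] - q[1])
            best = min(best, d)
        if math.isfinite(best):
            out.append(best)
    return np.array(out)


def hex_assign_by_center(xy: np.ndarray, origin: np.ndarray, side: float) -> list[tuple[int, int]]:
    """Assign points to pointy-top hexagons by scanning for the nearest
    hexagon center — independent of cube-coordinate rounding."""
    pts = xy - origin
    labels = []
    for p in pts:
        # candidate axial coords around the point
        r_guess = int(round(p[1] / (1.5 * side)))
        q_guess = int(round(p[0] / (math.sqrt(3) * side)))
        best, best_key = math.inf, None
        for q in range(q_guess - 3, q_guess + 4):
            for r in range(r_guess - 3, r_guess + 4):
                cx = side * math.sqrt(3) * (q + r / 2.0)
                cy = side * 1.5 * r
                d = math.hypot(p[0] - cx, p[1] - cy)
                if d < best:
                    best, best_key = d, (q, r)
        labels.append(best_key)
    return labels


def morisita_horn_direct(a: np.ndarray, b: np.ndarray) -> float:
    """MH index by direct loop evaluation of the defining formula."""
    A = float(sum(a))
    B = float(sum(b))
    num = 2.0 * sum(x * y for x, y in zip(a, b))
    da = sum(x * x for x in a) / (A * A)
    db = sum(y * y for y in b) / (B * B)
    return num / ((da + db) * A * B)


def sps_numeric(distances: np.ndarray, r_max: float = 20.0, n_grid: int = 200001) -> float:
    """SPS by trapezoid-free Riemann integration of the empirical CDF on a
    dense grid (converges to the exact step-function area)."""
    d = np.sort(np.asarray(distances, dtype=float))
    r = np.linspace(0.0, r_max, n_grid)
    g = np.searchsorted(d, r, side="right") / len(d)
    return float(np.trapezoid(g, r))


def logrank_brute(time_a, event_a, time_b, event_b) -> float:
    """Two-group log-rank chi-square from an explicit risk table."""
    times = sorted(
        set(t for t, e in zip(list(time_a) + list(time_b), list(event_a) + list(event_b)) if e)
    )
    O1 = E1 = V = 0.0
    for t in times:
        n1 = sum(1 for x in time_a if x >= t)
        n2 = sum(1 for x in time_b if x >= t)
        d1 = sum(1 for x, e in zip(time_a, event_a) if e and x == t)
        d2 = sum(1 for x, e in zip(time_b, event_b) if e and x == t)
        n = n1 + n2
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V if V > 0 else 0.0


def wilcoxon_exact_enum(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration of all
    group assignments of the pooled (tie-free) values."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    nx = len(x)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in x) - nx * (nx + 1) / 2.0
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        u = sum(i + 1 for i in combo) - nx * (nx + 1) / 2.0
        us.append(u)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, written out longhand."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p value
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return adj
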