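"""Independent reference implementations used only to check the package.

Each oracle is deliberately written with a different algorithm from the code
it validates: exhaustive enumeration of alignments, a plain-Python Gotoh DP,
quaternion-based superposition, all-shortest-paths betweenness counting,
Monte-Carlo surface sampling, and brute-force single-label hypothesis
testing.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

# --- alignment -------------------------------------------------------------

GAP_OPEN = 11
GAP_EXTEND = 1


@lru_cache(maxsize=1)
def blosum62_x0():
    m = substitution_matrices.load("BLOSUM62")
    scores = {}
    for a in m.alphabet:
        for b in m.alphabet:
            scores[(a, b)] = 0.0 if "X" in (a, b) else float(m[a, b])
    return scores


def enumerate_global(a: str, b: str) -> float:
    """Best global affine-gap score by exhaustive recursion over all
    alignments (gap of length k costs GAP_OPEN + k*GAP_EXTEND).

    State: (i, j, last) with last in {M, I, D} tracking whether the previous
    column was a gap (affine accounting).  Memoised on state, which still
    enumerates every alignment path implicitly.
    """
    sub = blosum62_x0()
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def go(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            best = max(best, sub[(a[i], b[j])] + go(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = GAP_EXTEND + (0 if last == "D" else GAP_OPEN)
            best = max(best, -cost + go(i + 1, j, "D"))
        if j < len(b):  # gap in a
            cost = GAP_EXTEND + (0 if last == "I" else GAP_OPEN)
            best = max(best, -cost + go(i, j + 1, "I"))
        return best

    result = go(0, 0, "M")
    go.cache_clear()
    return result


def enumerate_local(a: str, b: str) -> float:
    """Best local score: max over all substring pairs of the global score,
    with the empty alignment scoring 0."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, enumerate_global(a[i1:i2], b[j1:j2]))
    return best


def gotoh_local(a: str, b: str) -> float:
    """Plain-Python Smith–Waterman–Gotoh, affine gaps (cost 11 + k)."""
    sub = blosum62_x0()
    W = GAP_OPEN + GAP_EXTEND
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - W, E[i][j - 1] - GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] - W, F[i - 1][j] - GAP_EXTEND)
            H[i][j] = max(0.0,
                          H[i - 1][j - 1] + sub[(a[i - 1], b[j - 1])],
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def gotoh_profile_local(columns: np.ndarray, seq_idx: np.ndarray,
                        gap_open: float, gap_extend: float) -> float:
    """Plain-Python local profile-vs-sequence Gotoh (scores in profile
    units); reference for the vectorised row-scan implementation."""
    W = gap_open + gap_extend
    L, n = columns.shape[0], len(seq_idx)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(L + 1)]
    E = [[NEG] * (n + 1) for _ in range(L + 1)]
    F = [[NEG] * (n + 1) for _ in range(L + 1)]
    best = 0.0
    for i in range(1, L + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - W, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - W, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0,
                          H[i - 1][j - 1] + columns[i - 1][seq_idx[j - 1]],
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# --- graph centrality ------------------------------------------------------

def brute_betweenness(nodes, edges) -> dict:
    """Unnormalised betweenness by explicit enumeration of all shortest
    paths between every node pair (BFS layering + path expansion)."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_shortest_paths(s, t):
        if s == t:
            return []
        # BFS distances from s
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in adj[u]:
                if dist.get(v) == dist[u] + 1:
                    path.append(v)
                    extend(path)
                    path.pop()

        extend([s])
        return paths

    nodes = list(nodes)
    bet = {n: 0.0 for n in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for p in paths:
                for mid in p[1:-1]:
                    bet[mid] += 1.0 / len(paths)
    return bet


# --- superposition ---------------------------------------------------------

def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Optimal-superposition RMSD via the Horn quaternion eigen-method."""
    P = np.asarray(P, float) - np.mean(P, axis=0)
    Q = np.asarray(Q, float) - np.mean(Q, axis=0)
    Sxx, Sxy, Sxz = (P[:, 0] @ Q[:, 0]), (P[:, 0] @ Q[:, 1]), (P[:, 0] @ Q[:, 2])
    Syx, Syy, Syz = (P[:, 1] @ Q[:, 0]), (P[:, 1] @ Q[:, 1]), (P[:, 1] @ Q[:, 2])
    Szx, Szy, Szz = (P[:, 2] @ Q[:, 0]), (P[:, 2] @ Q[:, 1]), (P[:, 2] @ Q[:, 2])
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.max(np.linalg.eigvalsh(K))
    msd = (np.sum(P * P) + np.sum(Q * Q) - 2.0 * lam_max) / len(P)
    return float(np.sqrt(max(msd, 0.0)))


# --- SASA ------------------------------------------------------------------

def monte_carlo_sasa(coords: np.ndarray, radii: np.ndarray,
                     probe: float, n_points: int, seed: int = 0) -> float:
    """Total SASA by random-direction sampling (independent of the
    deterministic lattice sampler)."""
    rng = np.random.default_rng(seed)
    total = 0.0
    r = radii + probe
    for i in range(len(coords)):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        shell = coords[i] + r[i] * v
        ok = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((shell - coords[j]) ** 2).sum(axis=1)
            ok &= d2 >= r[j] ** 2
        total += ok.mean() * 4.0 * np.pi * r[i] ** 2
    return total


# --- label inference -------------------------------------------------------

def brute_force_label_positions(fragments, observations) -> frozenset:
    """Feasible single-label carbons by testing each of the 6 hypotheses
    against every observation's predicted shift."""
    cov = {f.label: f.carbon_coverage for f in fragments}
    feasible = set()
    for c in range(1, 7):
        ok = True
        for obs in observations:
            coverage = cov[obs.fragment_label]
            loss = obs.loss_atoms or frozenset()
            predicted = 1 if (c in coverage and c not in loss) else 0
            if predicted != obs.delta_mz:
                ok = False
                break
        if ok:
            feasible.add(c)
    return frozenset(feasible)
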